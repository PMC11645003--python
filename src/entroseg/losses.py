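"""Loss functions of the dual-network semi-supervised objective.

Each subnetwork minimises

    L_sub = L_ce + L_dice + α·L_ex  +  λ1·(L_sh1 + L_sh2)

where L_ex is a masked mean-squared error over the hard region on labeled
data, L_sh1 regresses a network's low-quality unlabeled voxels onto the other
network's *detached* predictions, and L_sh2 is a mutual MSE on high-quality
voxels.  λ1 follows a Gaussian warm-up ramp reaching 0.1 at the final
iteration.

All masked MSEs sum the squared error over class channels at each selected
voxel and normalise by the number of selected voxels; an empty mask
contributes exactly 0.  Every function accepts either plain numpy arrays
(returning a float) or autodiff :class:`~entroseg.autodiff.Tensor` inputs
(returning a scalar Tensor through which gradients flow).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, log_softmax_channels
from .entropy_masks import InvalidConfigError, InvalidInputError

_DICE_EPS = 1e-5
_LOG_EPS = 1e-12


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _data(x) -> np.ndarray:
    return x.data if _is_tensor(x) else np.asarray(x)


def scalar(x) -> float:
    """Plain float value of a loss term (Tensor or number)."""
    return float(_data(x))


def _check_spatial(pred, mask) -> None:
    pd, md = _data(pred), _data(mask)
    if pd.shape[-3:] != md.shape[-3:] or (pd.ndim == 5) != (md.ndim == 4):
        raise InvalidInputError(
            f"prediction shape {pd.shape} incompatible with mask shape {md.shape}"
        )


def _expand_mask(mask: np.ndarray, pred_ndim: int) -> np.ndarray:
    # insert the channel axis: (H,W,D)->(1,H,W,D), (N,H,W,D)->(N,1,H,W,D)
    return np.expand_dims(np.asarray(mask, dtype=np.float32), axis=pred_ndim - 4)


def masked_mse(a, b, mask):
    """Σ_mask ‖a − b‖² / Σ mask, squared error summed over class channels."""
    _check_spatial(a, mask)
    count = float(np.asarray(mask, dtype=np.float64).sum())
    if count == 0:
        return Tensor(0.0) if (_is_tensor(a) or _is_tensor(b)) else 0.0
    m = _expand_mask(mask, _data(a).ndim)
    if _is_tensor(a) or _is_tensor(b):
        a = a if _is_tensor(a) else Tensor(a)
        b = b if _is_tensor(b) else Tensor(b)
        diff = a - b
        return (diff * diff * Tensor(m)).sum() / count
    diff = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    return float((diff * diff * m).sum() / count)


def hard_region_exploration_loss(pred, gt_onehot, mex):
    """L_ex: masked MSE between predicted probabilities and one-hot truth."""
    if _data(pred).shape != _data(gt_onehot).shape:
        raise InvalidInputError("pred and gt_onehot must share shape")
    return masked_mse(pred, gt_onehot, mex)


def pseudo_label_sharing_directed(p_low_quality, p_high_quality_detached, md):
    """L_sh1 contribution: learner regresses onto the detached confident target.

    The target must carry no gradient linkage (pass ``tensor.detach()`` or a
    plain array); gradients flow only into the low-quality learner branch.
    """
    if _is_tensor(p_high_quality_detached) and p_high_quality_detached.requires_grad:
        raise InvalidInputError("pseudo-label target must be detached")
    return masked_mse(p_low_quality, p_high_quality_detached, md)


def mutual_high_quality_loss(pv, ph, mh):
    """L_sh2: mutual MSE on high-quality voxels; gradients reach both networks."""
    return masked_mse(pv, ph, mh)


def one_hot(labels: np.ndarray, class_count: int) -> np.ndarray:
    """One-hot encode an integer label field, channel-first."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= class_count:
        raise InvalidInputError(
            f"labels must lie in [0, {class_count - 1}], got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    eye = np.eye(class_count, dtype=np.float32)
    oh = eye[labels]  # (..., C)
    axis = labels.ndim - 3  # channel goes where spatial dims start
    return np.moveaxis(oh, -1, axis)


def cross_entropy_loss(pred, gt: np.ndarray, logits=None):
    """Mean per-voxel negative log-likelihood of the true class.

    When ``logits`` is given the numerically fused log-softmax path is used;
    otherwise the probabilities themselves are clamped and logged.
    """
    c = _data(pred).shape[_data(pred).ndim - 4]
    oh = one_hot(gt, c)
    nvox = int(np.asarray(gt).size)
    if logits is not None:
        ls = log_softmax_channels(logits)
        return -(ls * Tensor(oh)).sum() / float(nvox)
    if _is_tensor(pred):
        return -((pred + _LOG_EPS).log() * Tensor(oh)).sum() / float(nvox)
    p = np.clip(np.asarray(pred, dtype=np.float64), _LOG_EPS, None)
    return float(-(np.log(p) * oh).sum() / nvox)


def dice_loss(pred, gt: np.ndarray):
    """Soft Dice loss averaged over non-background classes.

    1 − (2Σ p·g + ε)/(Σ p + Σ g + ε) per foreground class, sums taken over
    the whole (batch and) volume, ε = 1e-5.
    """
    pd = _data(pred)
    ndim = pd.ndim
    cax = ndim - 4
    c = pd.shape[cax]
    oh = one_hot(gt, c)
    sum_axes = tuple(i for i in range(ndim) if i != cax)
    if _is_tensor(pred):
        inter = (pred * Tensor(oh)).sum(axis=sum_axes)
        totals = pred.sum(axis=sum_axes) + Tensor(oh.sum(axis=sum_axes))
        dice_c = (2.0 * inter + _DICE_EPS) / (totals + _DICE_EPS)
        fg = np.zeros(c, dtype=np.float32)
        fg[1:] = 1.0 / (c - 1)
        return 1.0 - (dice_c * Tensor(fg)).sum()
    inter = (pd.astype(np.float64) * oh).sum(axis=sum_axes)
    totals = pd.astype(np.float64).sum(axis=sum_axes) + oh.sum(axis=sum_axes)
    dice_c = (2.0 * inter + _DICE_EPS) / (totals + _DICE_EPS)
    return float(1.0 - dice_c[1:].mean())


@dataclass
class SupervisedTerms:
    """Components of the supervised objective for one subnetwork."""

    l_ce: object
    l_dice: object
    l_ex: object
    alpha: float

    @property
    def l_sup(self):
        return self.l_ce + self.l_dice + self.alpha * self.l_ex


def supervised_loss(pred, gt: np.ndarray, mex, alpha: float = 0.5,
                    logits=None) -> SupervisedTerms:
    """L_sup = L_ce + L_dice + α·L_ex on a labeled batch.

    With α = 0 the exploration term is skipped entirely (reported as 0), so
    the objective reduces exactly to the plain CE + Dice baseline.
    """
    if alpha < 0:
        raise InvalidConfigError(f"alpha must be >= 0, got {alpha}")
    ce = cross_entropy_loss(pred, gt, logits=logits)
    dl = dice_loss(pred, gt)
    if alpha > 0:
        c = _data(pred).shape[_data(pred).ndim - 4]
        lex = hard_region_exploration_loss(pred, one_hot(gt, c), mex)
    else:
        lex = Tensor(0.0) if _is_tensor(pred) else 0.0
    return SupervisedTerms(ce, dl, lex, float(alpha))


@dataclass
class LossBundle:
    """All scalar loss components of one subnetwork at one iteration."""

    l_ce: float
    l_dice: float
    l_ex: float
    l_sh1: float
    l_sh2: float
    l_sup: float
    l_sub: float

    def validate(self, alpha: float, lambda1: float, atol: float = 1e-6) -> None:
        for name in ("l_ce", "l_dice", "l_ex", "l_sh1", "l_sh2", "l_sup", "l_sub"):
            if getattr(self, name) < -atol:
                raise InvalidInputError(f"{name} must be non-negative")
        if not math.isclose(self.l_sup, self.l_ce + self.l_dice + alpha * self.l_ex,
                            abs_tol=atol):
            raise InvalidInputError("l_sup != l_ce + l_dice + alpha*l_ex")
        if not math.isclose(self.l_sub, self.l_sup + lambda1 * (self.l_sh1 + self.l_sh2),
                            abs_tol=atol):
            raise InvalidInputError("l_sub != l_sup + lambda1*(l_sh1 + l_sh2)")


def total_loss(sup: SupervisedTerms, l_sh1, l_sh2, lambda1: float):
    """Assemble L_sub = L_sup + λ1·(L_sh1 + L_sh2).

    Returns ``(bundle, objective)`` where the bundle carries plain floats for
    logging and the objective is the differentiable scalar (when the inputs
    are Tensors).  With λ1 = 0 the sharing terms are excluded from the
    objective so the step reduces exactly to supervised training.
    """
    if lambda1 < 0:
        raise InvalidConfigError(f"lambda1 must be >= 0, got {lambda1}")
    objective = sup.l_sup
    if lambda1 > 0:
        objective = objective + lambda1 * (l_sh1 + l_sh2)
    bundle = LossBundle(
        l_ce=scalar(sup.l_ce),
        l_dice=scalar(sup.l_dice),
        l_ex=scalar(sup.l_ex),
        l_sh1=scalar(l_sh1),
        l_sh2=scalar(l_sh2),
        l_sup=scalar(sup.l_sup),
        l_sub=scalar(sup.l_sup) + lambda1 * (scalar(l_sh1) + scalar(l_sh2)),
    )
    return bundle, objective


@dataclass
class WarmupSchedule:
    """Gaussian ramp for the unsupervised weight λ1.

    λ(t) = peak · exp(−ramp_coefficient · (1 − t/t_max)²)  (squared form);
    the unsquared exponent is available via ``squared=False``.  The weight is
    non-decreasing on [0, t_max] and equals ``peak`` at t_max.
    """

    t_max: int
    peak: float = 0.1
    ramp_coefficient: float = 5.0
    squared: bool = True

    def __post_init__(self):
        if self.t_max <= 0:
            raise InvalidConfigError("t_max must be positive")


def warmup_weight(t: int, schedule: WarmupSchedule) -> float:
    """λ1 at iteration ``t`` of the Gaussian warm-up ramp."""
    if t < 0 or t > schedule.t_max:
        raise InvalidInputError(f"t={t} outside [0, {schedule.t_max}]")
    x = 1.0 - t / schedule.t_max
    if schedule.squared:
        x = x * x
    return schedule.peak * math.exp(-schedule.ramp_coefficient * x)
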