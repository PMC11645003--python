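"""Per-voxel prediction entropy and the binary masks driving both loss modules.

The dual-network framework selects voxels by comparing the two networks'
softmax outputs — their hard labels, their Shannon entropies, and (on labeled
data) the ground truth.  Three anomaly masks plus an entropy-divergence mask
are unioned into the *hard region* used by the supervised exploration loss;
on unlabeled data an entropy-difference mask picks low-quality voxels that
should learn from the other network's confident predictions, and a
high-quality mask picks very-low-entropy voxels for mutual agreement.

Array conventions: probability maps are channel-first, ``(C, H, W, D)`` or
batched ``(N, C, H, W, D)``; entropy maps, hard-label maps and masks drop the
channel axis.  All comparisons are strict, so ties yield 0.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


class InvalidInputError(ValueError):
    """Raised when array arguments violate an operation's contract."""


class InvalidConfigError(ValueError):
    """Raised when a threshold or other configuration value is out of range."""


def _channel_axis(p: np.ndarray) -> int:
    if p.ndim == 4:
        return 0
    if p.ndim == 5:
        return 1
    raise InvalidInputError(
        f"probability map must be (C,H,W,D) or (N,C,H,W,D), got shape {p.shape}"
    )


def validate_probability_map(p: np.ndarray, atol: float = 1e-5) -> None:
    """Check the probability-map contract: C>=2, entries in [0,1], voxel sums 1."""
    ax = _channel_axis(p)
    if p.shape[ax] < 2:
        raise InvalidInputError(f"need at least 2 classes, got C={p.shape[ax]}")
    if np.any(p < -atol) or np.any(p > 1 + atol):
        raise InvalidInputError("probability entries must lie in [0, 1]")
    sums = p.sum(axis=ax)
    if not np.allclose(sums, 1.0, atol=atol):
        raise InvalidInputError("per-voxel class probabilities must sum to 1")


def compute_entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy ``−Σ_c p_c ln p_c`` per voxel, in nats.

    The convention ``0·ln 0 = 0`` is realised by clamping probabilities at
    1e-12 before the logarithm; the result lies in ``[0, ln C]``.
    """
    p = np.asarray(p, dtype=np.float64)
    ax = _channel_axis(p)
    if p.shape[ax] < 2:
        raise InvalidInputError(f"need at least 2 classes, got C={p.shape[ax]}")
    pc = np.clip(p, _EPS, None)
    return -(p * np.log(pc)).sum(axis=ax)


def hard_labels(p: np.ndarray) -> np.ndarray:
    """Argmax class per voxel; ties resolve to the lowest class index."""
    return np.argmax(p, axis=_channel_axis(p)).astype(np.int64)


def _check_same_shape(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise InvalidInputError(f"shape mismatch among inputs: {sorted(shapes)}")


def mask_consensus_error(yv: np.ndarray, yh: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """M1: both networks agree on a class that contradicts the ground truth."""
    _check_same_shape(yv, yh, gt)
    return ((yv == yh) & (yv != gt)).astype(np.uint8)


def mask_entropy_mismatch(
    ev: np.ndarray, eh: np.ndarray, yv: np.ndarray, yh: np.ndarray, gt: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """M2/M3: the less-certain network is right while the more-certain one is wrong.

    M2 flags voxels where the first network has strictly lower entropy yet its
    label misses the ground truth the second network hits; M3 is the mirror.
    The two conditions are mutually exclusive by construction.
    """
    _check_same_shape(ev, eh, yv, yh, gt)
    m2 = ((ev < eh) & (yv != gt) & (yh == gt)).astype(np.uint8)
    m3 = ((ev > eh) & (yh != gt) & (yv == gt)).astype(np.uint8)
    return m2, m3


def mask_entropy_divergence(ea: np.ndarray, eb: np.ndarray, tau1: float = 0.3) -> np.ndarray:
    """M4: the two networks' entropies differ by strictly more than ``tau1``."""
    if tau1 <= 0:
        raise InvalidConfigError(f"tau1 must be positive, got {tau1}")
    _check_same_shape(ea, eb)
    return (np.abs(ea - eb) > tau1).astype(np.uint8)


def combine_hard_region(
    m1: np.ndarray, m2: np.ndarray, m3: np.ndarray, m4: np.ndarray
) -> np.ndarray:
    """Mex: elementwise union of the four anomaly masks."""
    _check_same_shape(m1, m2, m3, m4)
    return ((m1 > 0) | (m2 > 0) | (m3 > 0) | (m4 > 0)).astype(np.uint8)


def mask_entropy_difference(
    e_self: np.ndarray, e_other: np.ndarray, beta: float = 0.2, tau2: float = 0.05
) -> np.ndarray:
    """Md: low-quality voxels of the calling network on unlabeled data.

    A voxel qualifies when the network's own entropy exceeds ``beta`` (it is
    itself uncertain) and the cross-network entropy gap exceeds ``tau2`` (the
    other network perceives the voxel differently).  Each network computes its
    own Md with its own entropy as ``e_self``.
    """
    if beta <= 0:
        raise InvalidConfigError(f"beta must be positive, got {beta}")
    if tau2 <= 0:
        raise InvalidConfigError(f"tau2 must be positive, got {tau2}")
    _check_same_shape(e_self, e_other)
    return ((e_self > beta) & (np.abs(e_self - e_other) > tau2)).astype(np.uint8)


def mask_high_quality(e: np.ndarray, beta: float = 0.2) -> np.ndarray:
    """Mh: very-small-entropy voxels, ``0 < E < beta`` with strict bounds."""
    if beta <= 0:
        raise InvalidConfigError(f"beta must be positive, got {beta}")
    e = np.asarray(e)
    return ((e > 0) & (e < beta)).astype(np.uint8)
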