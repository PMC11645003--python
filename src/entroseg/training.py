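"""Semi-supervised co-training loop for the dual-network framework.

Every iteration assembles a batch of two labeled and two unlabeled patches,
runs both networks on both, derives the entropy masks, assembles each
subnetwork's objective

    L_sub = L_ce + L_dice + α·L_ex + λ1(t)·(L_sh1 + L_sh2)

and updates both networks simultaneously, each with its own optimizer.  The
unsupervised weight λ1 follows the Gaussian warm-up ramp; the learning rate
starts at 0.01 and is divided by 10 every 2500 steps.

Randomness is fanned out from one root seed into independent streams
(network initialisation, labeled sampling, unlabeled sampling), so ablations
that disable loss terms see identical data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import yaml

from . import autodiff as ad
from . import entropy_masks as em
from . import losses as L
from .autodiff import Tensor
from .data_io import VolumeSample, augment, random_crop
from .entropy_masks import InvalidConfigError
from .networks import NetworkConfig, SegmentationNetwork, build_network


@dataclass
class TrainConfig:
    """All thresholds, weights and schedule settings of a training run."""

    tau1: float = 0.3
    tau2: float = 0.05
    beta: float = 0.2
    alpha: float = 0.5
    t_max: int = 6000
    batch_labeled: int = 2
    batch_unlabeled: int = 2
    lr0: float = 0.01
    lr_decay_every: int = 2500
    lr_decay_factor: float = 10.0
    optimizer: str = "sgd"
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0
    crop_size: tuple[int, int, int] = (32, 32, 32)
    class_count: int = 2
    base_channels: int = 16
    depth: int = 4
    augment_policy: str = "random_rot"
    use_hre: bool = True
    use_ps: bool = True
    m4_source: str = "labeled"
    warmup_peak: float = 0.1
    warmup_coefficient: float = 5.0
    warmup_squared: bool = True
    checkpoint_every: int = 1000

    def __post_init__(self):
        if min(self.tau1, self.tau2, self.beta) <= 0:
            raise InvalidConfigError("thresholds tau1, tau2, beta must be positive")
        if self.alpha < 0:
            raise InvalidConfigError("alpha must be >= 0")
        if self.optimizer not in ("sgd", "adam"):
            raise InvalidConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.m4_source not in ("labeled", "unlabeled"):
            raise InvalidConfigError(f"m4_source must be labeled|unlabeled")
        self.crop_size = tuple(int(c) for c in self.crop_size)

    @property
    def batch_size(self) -> int:
        return self.batch_labeled + self.batch_unlabeled

    def warmup_schedule(self) -> L.WarmupSchedule:
        return L.WarmupSchedule(t_max=self.t_max, peak=self.warmup_peak,
                                ramp_coefficient=self.warmup_coefficient,
                                squared=self.warmup_squared)

    def network_config(self, variant: str) -> NetworkConfig:
        return NetworkConfig(class_count=self.class_count, base_channels=self.base_channels,
                             depth=self.depth, variant=variant)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["crop_size"] = list(self.crop_size)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        return cls(**yaml.safe_load(text))


def learning_rate(t: int, config: TrainConfig) -> float:
    """Step-decayed learning rate: lr0 / factor**floor(t / decay_every)."""
    return config.lr0 / config.lr_decay_factor ** (t // config.lr_decay_every)


class SGD:
    """SGD with classical momentum and decoupled L2 weight decay."""

    def __init__(self, params: Sequence[Tensor], momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= (lr * v).astype(np.float32)

    def state_dict(self) -> dict:
        return {f"v{i}": v for i, v in enumerate(self.velocity)}

    def load_state_dict(self, state: dict) -> None:
        self.velocity = [np.asarray(state[f"v{i}"], dtype=np.float32).copy()
                         for i in range(len(self.params))]


class Adam:
    def __init__(self, params: Sequence[Tensor], beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def state_dict(self) -> dict:
        out = {f"m{i}": m for i, m in enumerate(self.m)}
        out.update({f"v{i}": v for i, v in enumerate(self.v)})
        out["t"] = np.asarray(self.t)
        return out

    def load_state_dict(self, state: dict) -> None:
        self.m = [np.asarray(state[f"m{i}"], dtype=np.float32).copy()
                  for i in range(len(self.params))]
        self.v = [np.asarray(state[f"v{i}"], dtype=np.float32).copy()
                  for i in range(len(self.params))]
        self.t = int(state["t"])


def _make_optimizer(net: SegmentationNetwork, config: TrainConfig):
    if config.optimizer == "sgd":
        return SGD(net.parameters(), momentum=config.momentum,
                   weight_decay=config.weight_decay)
    return Adam(net.parameters(), weight_decay=config.weight_decay)


@dataclass
class TrainState:
    """Mutable state of a run: both networks, optimizers, iteration, RNG streams."""

    net_v: SegmentationNetwork
    net_h: SegmentationNetwork
    opt_v: object
    opt_h: object
    rng_labeled: np.random.Generator
    rng_unlabeled: np.random.Generator
    iteration: int = 0


def init_train_state(config: TrainConfig) -> TrainState:
    """Build both networks and RNG streams from the root seed."""
    ss = np.random.SeedSequence(config.seed)
    seed_v, seed_h, seed_lab, seed_unlab = (int(s) for s in ss.generate_state(4) % (2 ** 31))
    net_v = build_network(config.network_config("vnet"), seed=seed_v)
    net_h = build_network(config.network_config("hvnet"), seed=seed_h)
    return TrainState(
        net_v=net_v, net_h=net_h,
        opt_v=_make_optimizer(net_v, config),
        opt_h=_make_optimizer(net_h, config),
        rng_labeled=np.random.default_rng(seed_lab),
        rng_unlabeled=np.random.default_rng(seed_unlab),
    )


def sample_batch(volumes: Sequence[VolumeSample], batch: int,
                 config: TrainConfig, rng: np.random.Generator,
                 with_labels: bool) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw `batch` random augmented crops; stack into (N,1,H,W,D) arrays."""
    imgs, labs = [], []
    for _ in range(batch):
        vol = volumes[int(rng.integers(0, len(volumes)))]
        patch = random_crop(vol, config.crop_size, rng)
        patch = augment(patch, rng, policy=config.augment_policy)
        imgs.append(patch.image)
        if with_labels:
            labs.append(patch.label)
    x = np.stack(imgs)[:, None].astype(np.float32)
    y = np.stack(labs).astype(np.int64) if with_labels else None
    return x, y


def _check_finite(bundle: L.LossBundle, network: str) -> None:
    for name, value in asdict(bundle).items():
        if not np.isfinite(value):
            raise RuntimeError(f"non-finite loss component {name}={value} in {network}")


def train_step(state: TrainState, labeled_batch, unlabeled_batch,
               config: TrainConfig) -> tuple[L.LossBundle, L.LossBundle, dict]:
    """One simultaneous update of both networks; returns per-network loss
    bundles and a diagnostics dict with mask voxel counts.

    With ``use_hre=False`` (α→0) and ``use_ps=False`` (λ1→0) the step reduces
    exactly to two independently supervised CE+Dice networks.
    """
    t = state.iteration + 1
    alpha = config.alpha if config.use_hre else 0.0
    lam = (L.warmup_weight(min(t, config.t_max), config.warmup_schedule())
           if config.use_ps else 0.0)
    x_l, y_l = labeled_batch
    net_v, net_h = state.net_v, state.net_h
    net_v.train(), net_h.train()

    logits_v = net_v.forward_logits(x_l)
    logits_h = net_h.forward_logits(x_l)
    pv = ad.softmax_channels(logits_v)
    ph = ad.softmax_channels(logits_h)
    pvd, phd = pv.data, ph.data

    counts = {"n_mex": 0, "n_md_v": 0, "n_md_h": 0, "n_mh_v": 0, "n_mh_h": 0}
    mex = None
    ev_u = eh_u = pv_u = ph_u = None
    if config.use_ps or config.m4_source == "unlabeled":
        x_u, _ = unlabeled_batch
        logits_vu = net_v.forward_logits(x_u)
        logits_hu = net_h.forward_logits(x_u)
        pv_u = ad.softmax_channels(logits_vu)
        ph_u = ad.softmax_channels(logits_hu)
        ev_u = em.compute_entropy(pv_u.data)
        eh_u = em.compute_entropy(ph_u.data)

    if alpha > 0:
        ev_l = em.compute_entropy(pvd)
        eh_l = em.compute_entropy(phd)
        yv, yh = em.hard_labels(pvd), em.hard_labels(phd)
        m1 = em.mask_consensus_error(yv, yh, y_l)
        m2, m3 = em.mask_entropy_mismatch(ev_l, eh_l, yv, yh, y_l)
        if config.m4_source == "labeled":
            m4 = em.mask_entropy_divergence(ev_l, eh_l, config.tau1)
        else:
            m4 = em.mask_entropy_divergence(ev_u, eh_u, config.tau1)
        mex = em.combine_hard_region(m1, m2, m3, m4)
        counts["n_mex"] = int(mex.sum())

    sup_v = L.supervised_loss(pv, y_l, mex, alpha, logits=logits_v)
    sup_h = L.supervised_loss(ph, y_l, mex, alpha, logits=logits_h)

    if config.use_ps:
        md_v = em.mask_entropy_difference(ev_u, eh_u, config.beta, config.tau2)
        md_h = em.mask_entropy_difference(eh_u, ev_u, config.beta, config.tau2)
        mh_v = em.mask_high_quality(ev_u, config.beta)
        mh_h = em.mask_high_quality(eh_u, config.beta)
        counts.update(n_md_v=int(md_v.sum()), n_md_h=int(md_h.sum()),
                      n_mh_v=int(mh_v.sum()), n_mh_h=int(mh_h.sum()))
        lsh1_v = L.pseudo_label_sharing_directed(pv_u, ph_u.detach(), md_v)
        lsh1_h = L.pseudo_label_sharing_directed(ph_u, pv_u.detach(), md_h)
        lsh2_v = L.mutual_high_quality_loss(pv_u, ph_u, mh_v)
        lsh2_h = L.mutual_high_quality_loss(pv_u, ph_u, mh_h)
    else:
        zero = Tensor(0.0)
        lsh1_v = lsh1_h = lsh2_v = lsh2_h = zero

    bundle_v, obj_v = L.total_loss(sup_v, lsh1_v, lsh2_v, lam)
    bundle_h, obj_h = L.total_loss(sup_h, lsh1_h, lsh2_h, lam)
    _check_finite(bundle_v, "vnet")
    _check_finite(bundle_h, "hvnet")

    net_v.zero_grad()
    net_h.zero_grad()
    total = obj_v + obj_h
    total.backward()
    lr = learning_rate(t, config)
    state.opt_v.step(lr)
    state.opt_h.step(lr)
    state.iteration = t
    counts["lr"] = lr
    counts["lambda1"] = lam
    return bundle_v, bundle_h, counts


def train_step_supervised(state: TrainState, labeled_batch,
                          config: TrainConfig) -> tuple[L.LossBundle, L.LossBundle, dict]:
    """Reference step: plain CE+Dice co-training with no coupling terms."""
    t = state.iteration + 1
    x_l, y_l = labeled_batch
    state.net_v.train(), state.net_h.train()
    out = []
    objs = []
    for net in (state.net_v, state.net_h):
        logits = net.forward_logits(x_l)
        p = ad.softmax_channels(logits)
        sup = L.supervised_loss(p, y_l, None, 0.0, logits=logits)
        bundle, obj = L.total_loss(sup, Tensor(0.0), Tensor(0.0), 0.0)
        out.append(bundle)
        objs.append(obj)
    state.net_v.zero_grad()
    state.net_h.zero_grad()
    (objs[0] + objs[1]).backward()
    lr = learning_rate(t, config)
    state.opt_v.step(lr)
    state.opt_h.step(lr)
    state.iteration = t
    return out[0], out[1], {"lr": lr, "lambda1": 0.0}


def train_loop(labeled: Sequence[VolumeSample], unlabeled: Sequence[VolumeSample],
               config: TrainConfig, state: TrainState | None = None,
               out_dir=None, log_every: int = 1, supervised_only: bool = False,
               stop_after: int | None = None, eval_every: int = 0,
               eval_samples: Sequence[VolumeSample] = ()) -> tuple[TrainState, list[dict]]:
    """Run iterations ``state.iteration+1 … t_max``; returns state and log.

    The log records, per iteration, every loss component of both networks,
    the learning rate, λ1 and the mask voxel counts (|Mex|, |Md|, |Mh|).
    Checkpoints are written to ``out_dir`` every ``checkpoint_every``
    iterations when a directory is given.
    """
    if len(labeled) == 0:
        raise InvalidConfigError("training requires at least one labeled volume")
    if not supervised_only and config.use_ps and len(unlabeled) == 0:
        raise InvalidConfigError("pseudo-label sharing requires unlabeled volumes")
    if state is None:
        state = init_train_state(config)
    log: list[dict] = []
    last = config.t_max if stop_after is None else min(config.t_max, stop_after)
    while state.iteration < last:
        lb = sample_batch(labeled, config.batch_labeled, config,
                          state.rng_labeled, with_labels=True)
        if supervised_only:
            bv, bh, info = train_step_supervised(state, lb, config)
        else:
            ub = (sample_batch(unlabeled, config.batch_unlabeled, config,
                               state.rng_unlabeled, with_labels=False)
                  if (config.use_ps or config.m4_source == "unlabeled") else (None, None))
            bv, bh, info = train_step(state, lb, ub, config)
        if state.iteration % log_every == 0 or state.iteration == config.t_max:
            entry = {"iteration": state.iteration}
            entry.update({f"v_{k}": v for k, v in asdict(bv).items()})
            entry.update({f"h_{k}": v for k, v in asdict(bh).items()})
            entry.update(info)
            if eval_every and eval_samples and state.iteration % eval_every == 0:
                from .evaluation import dice_jaccard, infer_volume
                dices = []
                for s in eval_samples:
                    pred = infer_volume([state.net_v, state.net_h], s, config.crop_size)
                    dices.append(dice_jaccard(pred > 0, s.label > 0)[0])
                entry["eval_dice"] = float(np.mean(dices))
            log.append(entry)
        if out_dir is not None and state.iteration % config.checkpoint_every == 0:
            save_checkpoint(state, config,
                            f"{out_dir}/checkpoint_{state.iteration:06d}.npz")
    if out_dir is not None:
        save_checkpoint(state, config, f"{out_dir}/checkpoint_final.npz")
    return state, log


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(state: TrainState, config: TrainConfig, path) -> None:
    """Single-file archive: parameters, optimizer state, iteration, RNG streams."""
    arrays = {}
    for prefix, net in (("net_v", state.net_v), ("net_h", state.net_h)):
        for k, v in net.state_dict().items():
            arrays[f"{prefix}/{k}"] = v
    for prefix, opt in (("opt_v", state.opt_v), ("opt_h", state.opt_h)):
        for k, v in opt.state_dict().items():
            arrays[f"{prefix}/{k}"] = v
    meta = {
        "iteration": state.iteration,
        "config": config.to_yaml(),
        "rng_labeled": state.rng_labeled.bit_generator.state,
        "rng_unlabeled": state.rng_unlabeled.bit_generator.state,
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as f:
        np.savez(f, **arrays)


def load_checkpoint(path) -> tuple[TrainState, TrainConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = TrainConfig.from_yaml(meta["config"])
        state = init_train_state(config)
        for prefix, net in (("net_v", state.net_v), ("net_h", state.net_h)):
            net.load_state_dict({k.split("/", 1)[1]: data[k] for k in data.files
                                 if k.startswith(prefix + "/")})
        for prefix, opt in (("opt_v", state.opt_v), ("opt_h", state.opt_h)):
            opt.load_state_dict({k.split("/", 1)[1]: data[k] for k in data.files
                                 if k.startswith(prefix + "/")})
        state.iteration = int(meta["iteration"])
        state.rng_labeled.bit_generator.state = meta["rng_labeled"]
        state.rng_unlabeled.bit_generator.state = meta["rng_unlabeled"]
    return state, config
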