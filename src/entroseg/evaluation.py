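"""Segmentation metrics (Dice, Jaccard, 95HD, ASD) and whole-volume inference.

Surface distances use the boundary-voxel definition: a foreground voxel is on
the boundary if 6-connected erosion removes it.  Directed nearest-neighbour
distances from each boundary set to the other are pooled; the 95th-percentile
(linear interpolation between order statistics) gives 95HD and the mean gives
ASD.  Distances are in voxel units by default; passing a spacing scales each
axis to millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import autodiff as ad
from .data_io import VolumeSample
from .entropy_masks import InvalidInputError
from .networks import SegmentationNetwork


@dataclass
class MetricReport:
    dice: float
    jaccard: float
    hd95: float
    asd: float
    units: str = "voxel"


def dice_jaccard(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    """Overlap ratios 2|A∩B|/(|A|+|B|) and |A∩B|/|A∪B|; both-empty → (1, 1)."""
    pred, gt = np.asarray(pred).astype(bool), np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise InvalidInputError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    inter = np.logical_and(pred, gt).sum()
    a, b = pred.sum(), gt.sum()
    if a + b == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / (a + b)
    union = a + b - inter
    return float(dice), float(inter / union)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of foreground voxels removed by 6-connected erosion."""
    mask = np.asarray(mask).astype(bool)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~eroded)


def surface_distances(pred: np.ndarray, gt: np.ndarray,
                      spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                      pooled: bool = True) -> tuple[float, float]:
    """(95HD, ASD) between two nonempty binary masks.

    Pooled definition by default: both directed nearest-neighbour distance
    sets are concatenated before taking the 95th percentile / mean.  With
    ``pooled=False`` 95HD is the max of the two directed 95th percentiles and
    ASD the mean of the two directed means.  Either mask empty → (nan, nan)
    with a warning, so missing structures are never silently scored 0.
    """
    pred, gt = np.asarray(pred).astype(bool), np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise InvalidInputError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if pred.sum() == 0 or gt.sum() == 0:
        warnings.warn("empty mask in surface_distances; returning nan", stacklevel=2)
        return float("nan"), float("nan")
    sp = np.asarray(spacing, dtype=float)
    sa = boundary_voxels(pred) * sp
    sb = boundary_voxels(gt) * sp
    d_ab = cKDTree(sb).query(sa)[0]
    d_ba = cKDTree(sa).query(sb)[0]
    if pooled:
        pool = np.concatenate([d_ab, d_ba])
        return float(np.percentile(pool, 95)), float(pool.mean())
    hd95 = max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))
    return float(hd95), float((d_ab.mean() + d_ba.mean()) / 2.0)


def evaluate_masks(pred: np.ndarray, gt: np.ndarray,
                   spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                   voxel_units: bool = True) -> MetricReport:
    """All four metrics for one predicted/reference mask pair."""
    dice, jac = dice_jaccard(pred, gt)
    sp = (1.0, 1.0, 1.0) if voxel_units else spacing
    hd95, asd = surface_distances(pred, gt, spacing=sp)
    return MetricReport(dice, jac, hd95, asd, units="voxel" if voxel_units else "mm")


def infer_volume(nets: list[SegmentationNetwork], sample: VolumeSample,
                 patch: tuple[int, int, int], stride: tuple[int, int, int] | None = None,
                 mode: str = "average") -> np.ndarray:
    """Sliding-window prediction → integer label volume.

    Patches are predicted by each network in evaluation mode, probabilities
    combined per ``mode`` (``average`` of the two networks, or ``vnet`` /
    ``hvnet`` alone), overlap-averaged across windows, then argmaxed.
    Volumes smaller than the patch are mirror-padded with a warning.
    """
    if mode == "average":
        active = list(nets)
    elif mode in ("vnet", "hvnet"):
        active = [n for n in nets if n.config.variant == mode]
        if not active:
            raise InvalidInputError(f"no network of variant {mode!r} given")
    else:
        raise InvalidInputError(f"unknown inference mode {mode!r}")
    patch = tuple(int(p) for p in patch)
    stride = patch if stride is None else tuple(int(s) for s in stride)
    image = sample.image
    orig_shape = image.shape
    pads = [(0, max(0, p - s)) for p, s in zip(patch, orig_shape)]
    if any(p[1] for p in pads):
        warnings.warn("volume smaller than patch; mirror-padding", stacklevel=2)
        image = np.pad(image, pads, mode="reflect")
    shape = image.shape
    c = active[0].config.class_count
    prob_sum = np.zeros((c, *shape), dtype=np.float32)
    count = np.zeros(shape, dtype=np.float32)

    def starts(dim: int, p: int, s: int) -> list[int]:
        if dim <= p:
            return [0]
        pos = list(range(0, dim - p, s))
        pos.append(dim - p)
        return sorted(set(pos))

    was_training = [n.training for n in active]
    for n in active:
        n.eval()
    try:
        with ad.no_grad():
            for i in starts(shape[0], patch[0], stride[0]):
                for j in starts(shape[1], patch[1], stride[1]):
                    for k in starts(shape[2], patch[2], stride[2]):
                        sl = (slice(i, i + patch[0]), slice(j, j + patch[1]),
                              slice(k, k + patch[2]))
                        x = image[sl][None, None]
                        p = np.zeros((c, *patch), dtype=np.float32)
                        for net in active:
                            logits = net.forward_logits(x)
                            p += ad.softmax_channels(logits).data[0]
                        p /= len(active)
                        prob_sum[(slice(None),) + sl] += p
                        count[sl] += 1.0
    finally:
        for n, t in zip(active, was_training):
            n.train(t)
    probs = prob_sum / count[None]
    labels = np.argmax(probs, axis=0).astype(np.int64)
    return labels[tuple(slice(0, s) for s in orig_shape)]
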