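"""Shared fixtures and independent per-voxel oracle implementations.

The oracles deliberately use plain Python loops over voxels so they share no
code path with the vectorised implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_prob_map(rng: np.random.Generator, c: int, shape=(4, 4, 4)) -> np.ndarray:
    """Random valid probability field (C, H, W, D) via Dirichlet sampling."""
    p = rng.dirichlet(np.ones(c), size=shape)  # (H, W, D, C)
    return np.moveaxis(p, -1, 0).astype(np.float64)


# ---------------------------------------------------------------------------
# scalar-loop oracles


def oracle_entropy(p: np.ndarray) -> np.ndarray:
    c, h, w, d = p.shape
    out = np.zeros((h, w, d))
    for i in range(h):
        for j in range(w):
            for k in range(d):
                e = 0.0
                for cc in range(c):
                    v = float(p[cc, i, j, k])
                    if v > 0:
                        e -= v * math.log(v)
                out[i, j, k] = e
    return out


def oracle_masks(ev, eh, yv, yh, gt, tau1, tau2, beta):
    """All seven masks from scalar per-voxel rules."""
    shape = ev.shape
    m1 = np.zeros(shape, np.uint8)
    m2 = np.zeros(shape, np.uint8)
    m3 = np.zeros(shape, np.uint8)
    m4 = np.zeros(shape, np.uint8)
    md_v = np.zeros(shape, np.uint8)
    md_h = np.zeros(shape, np.uint8)
    mh_v = np.zeros(shape, np.uint8)
    for idx in np.ndindex(*shape):
        m1[idx] = 1 if (yv[idx] == yh[idx] and yv[idx] != gt[idx]) else 0
        m2[idx] = 1 if (ev[idx] < eh[idx] and yv[idx] != gt[idx] and yh[idx] == gt[idx]) else 0
        m3[idx] = 1 if (ev[idx] > eh[idx] and yh[idx] != gt[idx] and yv[idx] == gt[idx]) else 0
        m4[idx] = 1 if abs(ev[idx] - eh[idx]) > tau1 else 0
        md_v[idx] = 1 if (ev[idx] > beta and abs(ev[idx] - eh[idx]) > tau2) else 0
        md_h[idx] = 1 if (eh[idx] > beta and abs(eh[idx] - ev[idx]) > tau2) else 0
        mh_v[idx] = 1 if (0 < ev[idx] < beta) else 0
    mex = np.zeros(shape, np.uint8)
    for idx in np.ndindex(*shape):
        mex[idx] = 1 if (m1[idx] or m2[idx] or m3[idx] or m4[idx]) else 0
    return dict(m1=m1, m2=m2, m3=m3, m4=m4, mex=mex, md_v=md_v, md_h=md_h, mh_v=mh_v)


def oracle_masked_mse(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Σ_mask ‖a−b‖² / Σ mask by scalar loops; channel-first inputs."""
    c = a.shape[0]
    total, count = 0.0, 0
    for idx in np.ndindex(*mask.shape):
        if mask[idx]:
            count += 1
            for cc in range(c):
                diff = float(a[(cc,) + idx]) - float(b[(cc,) + idx])
                total += diff * diff
    return total / count if count else 0.0


def oracle_ce_dice(p: np.ndarray, gt: np.ndarray, eps: float = 1e-5):
    """Cross-entropy and soft-Dice loss by scalar loops (channel-first)."""
    c = p.shape[0]
    ce, n = 0.0, 0
    for idx in np.ndindex(*gt.shape):
        ce -= math.log(max(float(p[(int(gt[idx]),) + idx]), 1e-12))
        n += 1
    dice_terms = []
    for cc in range(1, c):
        inter = tot_p = tot_g = 0.0
        for idx in np.ndindex(*gt.shape):
            pv = float(p[(cc,) + idx])
            gv = 1.0 if gt[idx] == cc else 0.0
            inter += pv * gv
            tot_p += pv
            tot_g += gv
        dice_terms.append((2 * inter + eps) / (tot_p + tot_g + eps))
    return ce / n, 1.0 - sum(dice_terms) / len(dice_terms)


def oracle_surface_distances(pred: np.ndarray, gt: np.ndarray, spacing=(1, 1, 1)):
    """Brute-force pooled 95HD / ASD via all-pairs boundary distances."""

    def boundary(mask):
        pts = []
        h, w, d = mask.shape
        for idx in np.ndindex(h, w, d):
            if not mask[idx]:
                continue
            on_edge = False
            for ax in range(3):
                for step in (-1, 1):
                    nb = list(idx)
                    nb[ax] += step
                    if not (0 <= nb[ax] < mask.shape[ax]) or not mask[tuple(nb)]:
                        on_edge = True
            if on_edge:
                pts.append(idx)
        return np.asarray(pts, dtype=float) * np.asarray(spacing)

    sa, sb = boundary(pred.astype(bool)), boundary(gt.astype(bool))
    d_ab = [min(math.dist(a, b) for b in sb) for a in sa]
    d_ba = [min(math.dist(b, a) for a in sa) for b in sb]
    pool = np.array(d_ab + d_ba)
    return float(np.percentile(pool, 95)), float(pool.mean())
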