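"""Entropy maps and selection masks from a pair of disagreeing predictions.

Builds two synthetic softmax fields over a small volume, computes per-voxel
Shannon entropy, and derives every selection mask the framework uses: the
three labeled-data anomaly masks (consensus error, entropy/correctness
mismatch), the entropy-divergence mask, their union (the hard region), and
the unlabeled-data masks (entropy-difference and high-quality).
"""

import numpy as np

from entroseg import entropy_masks as em

rng = np.random.default_rng(0)
shape = (8, 8, 8)

# two "network outputs": noisy softmax fields over 2 classes
logits_v = rng.normal(size=(2, *shape))
logits_h = logits_v + 0.7 * rng.normal(size=(2, *shape))  # correlated but distinct
pv = np.exp(logits_v) / np.exp(logits_v).sum(axis=0)
ph = np.exp(logits_h) / np.exp(logits_h).sum(axis=0)
gt = rng.integers(0, 2, size=shape)

ev, eh = em.compute_entropy(pv), em.compute_entropy(ph)
yv, yh = em.hard_labels(pv), em.hard_labels(ph)

m1 = em.mask_consensus_error(yv, yh, gt)
m2, m3 = em.mask_entropy_mismatch(ev, eh, yv, yh, gt)
m4 = em.mask_entropy_divergence(ev, eh, tau1=0.3)
mex = em.combine_hard_region(m1, m2, m3, m4)
md_v = em.mask_entropy_difference(ev, eh, beta=0.2, tau2=0.05)
mh_v = em.mask_high_quality(ev, beta=0.2)

n = np.prod(shape)
print(f"entropy range network A: [{ev.min():.3f}, {ev.max():.3f}] nats (max ln2={np.log(2):.3f})")
print(f"M1 consensus errors:      {m1.sum():4d} / {n} voxels")
print(f"M2/M3 entropy mismatches: {m2.sum():4d} / {m3.sum():4d}")
print(f"M4 entropy divergence:    {m4.sum():4d}")
print(f"Mex hard region (union):  {mex.sum():4d}")
print(f"Md low-quality (A side):  {md_v.sum():4d}   Mh high-quality: {mh_v.sum():4d}")
print()
print("Mex is the voxel set the supervised exploration loss focuses on;")
print("Md voxels learn from the other network, Mh voxels learn mutually.")
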