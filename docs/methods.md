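# Methods

## The model

`entroseg` trains two heterogeneous volumetric segmentation networks jointly
from a small labeled set D_L and a larger unlabeled set D_U.  Network A is a
V-Net-style encoder–decoder; network B (HV-Net) shares the decoder design but
replaces each encoder stage with a pre-activation residual block.  Both emit
per-voxel softmax distributions p ∈ R^C, from which per-voxel Shannon entropy
E = −Σ_c p_c ln p_c (nats, range [0, ln C]) is computed.  Entropy is the
organizing quantity: low entropy is read as confidence ("high-quality"
voxels), high entropy as uncertainty ("low-quality" voxels).

### Supervised pass: hard-region exploration (HRE)

On a labeled batch, with hard labels y_V, y_H (argmax; ties resolve to the
lowest class index) and ground truth y, four binary masks select anomalous
voxels:

- **M1** (consensus error): y_V = y_H but both ≠ y.
- **M2 / M3** (entropy–correctness mismatch): the *more confident* network is
  wrong while the less confident one is right (M2: E_V < E_H, y_V ≠ y,
  y_H = y; M3 is the mirror).
- **M4** (entropy divergence): |E_V − E_H| > τ1, τ1 = 0.3.

Their union Mex is the *hard region*.  The exploration loss is a masked MSE
between predicted probabilities and the one-hot truth,
L_ex = Σ_Mex‖p − onehot(y)‖² / Σ Mex, added to standard cross-entropy and
soft Dice: L_sup = L_ce + L_dice + α·L_ex.

### Unsupervised pass: pseudo-label sharing (PS)

On an unlabeled batch, each network k derives from *its own* entropy map:

- **Md_k** = [E_k > β and |E_V − E_H| > τ2] (β = 0.2, τ2 = 0.05): voxels
  where the network is itself uncertain and the two networks perceive the
  voxel differently.  There the network regresses onto the *detached* output
  of its peer (L_sh1); gradients flow only into the learner.
- **Mh_k** = [0 < E_k < β]: very confident voxels, on which the two networks
  pull toward each other by a mutual masked MSE (L_sh2, gradients into both).

All masked MSEs sum squared error over class channels at each selected voxel
and normalise by the selected-voxel count; an empty mask contributes exactly
0 (the 0/0 limit is resolved to "no selected pixels → no loss").

### Objective and schedules

Each subnetwork minimises L_sub = L_sup + λ1·(L_sh1 + L_sh2).  λ1 follows a
Gaussian ramp λ1(t) = 0.1·exp(−5·(1 − t/t_max)²), non-decreasing with
λ1(t_max) = 0.1, so the unsupervised terms phase in as the networks become
trustworthy.  Both networks are updated simultaneously, each by its own SGD
optimizer (momentum 0.9, weight decay 1e-4; Adam is selectable), with
learning rate 0.01 divided by 10 every 2500 steps.  The default batch is
four patches: two labeled, two unlabeled.

## Interpretation decisions

Choices the loss definitions leave genuinely open, fixed here once:

- **All comparisons strict.**  Every mask uses strict inequalities exactly as
  the defining indicator functions are written; ties produce 0.
- **Directional reading of "the corresponding entropy".**  Md and Mh are
  computed per network from that network's own entropy map (E_A means "the
  entropy of the network doing the learning").  This gives two directed
  sharing losses per batch and makes explicit which side of L_sh1 is the
  learner.  The same reading is applied to Mh for consistency, so each
  network's L_sub carries its own L_sh2 term; since the mutual loss is
  symmetric in its arguments this only affects which voxels are selected.
- **M4's entropy source.**  The hard-region module operates during the
  supervised phase, so M4 defaults to labeled-batch entropies; a config
  switch (`m4_source`) selects unlabeled-batch entropies instead.
- **α = 0.5.**  The HRE weight has no canonical value; 0.5 keeps L_ex
  subordinate to L_ce + L_dice while still contributing.  It is exposed in
  `TrainConfig`.
- **Squared warm-up exponent.**  The sigmoid-style ramp
  exp(−5(1 − t/t_max)²) is the standard "Gaussian warm-up" in
  consistency-regularisation training; the unsquared form is available via
  `warmup_squared=False`.  Both agree at t = 0 and t = t_max.
- **Entropy in nats** (natural log), consistent with thresholds β = 0.2,
  τ1 = 0.3 on the [0, ln 2 ≈ 0.693] scale for C = 2.
- **λ1 is identified with the warm-up weight** (no additional scaling).
- **Soft Dice** is the V-Net-lineage form 1 − (2Σpg + ε)/(Σp + Σg + ε),
  ε = 1e-5, averaged over non-background classes with sums over the whole
  batch.

## Architecture details

The lineage reference specifies "V-Net" without internals, so the stage
layout is this package's own: a stem convolution; per level a stage
(1 convolution at the top level, 2 below — plain conv–BN–ReLU stacks for
vnet, pre-activation residual blocks with a post-norm for hvnet); stride-2
kernel-2 downsampling convs; a 2-conv bottleneck; a decoder that halves
channels by convolution *before* nearest-neighbour upsampling, adds the
encoder skip, and refines with one convolution per level; a 1³ classification
head.  Kernel 3, batch normalisation, ReLU, He initialisation.  The extra
post-norms give hvnet a (slightly) different parameter count, making the
heterogeneity visible in the parameter structure as well as the wiring.
Batch statistics are used in training mode; running averages (momentum 0.1)
at evaluation.  Input spatial dimensions must be divisible by 2^depth.

## Numerical engine

The networks run on a compact reverse-mode autodiff engine over float32
numpy arrays (`entroseg.autodiff`).  Convolution forward, weight-gradient
and input-gradient passes are register-blocked direct 3D stencils compiled
with numba; the input gradient is computed as a full correlation of the
zero-stuffed output gradient with the flipped, channel-swapped kernel.
Batch normalisation is a fused primitive with the analytic backward formula.
Gradient correctness is pinned by finite-difference tests against float64
loop references.  Other numerical conventions: 0·ln 0 = 0 via clamping
probabilities at 1e-12 before logarithms; cross-entropy computed through a
shift-stabilised log-softmax; softmax shift-invariance and probability
normalisation verified in tests.  All randomness flows from one root seed
fanned out (via `SeedSequence`) into independent streams for initialisation,
labeled sampling and unlabeled sampling, so disabling a loss term never
perturbs the data another variant sees, and runs are bitwise reproducible on
one machine.

## Synthetic phantoms

The generator emulates the two failure modes the method targets: *thin
structures* (curved tubes of ~1.5-voxel radius sprouting from an ellipsoidal
body, the analogue of fine anatomical branches) and *fuzzy boundaries*
(Gaussian blur of the object boundary, σ = 1 voxel by default, plus additive
noise and a smooth background texture, both sd 0.1 against contrast 1.0).
With blur and noise set to zero, thresholding at half contrast recovers the
label exactly; as blur grows, boundary voxels become ambiguous from
intensity alone — a property the tests verify monotonically.  Foreground
stays a minority class (roughly 5–15% of voxels).

What the phantoms do *not* emulate: anatomical shape statistics, intensity
inhomogeneity fields, anisotropic voxels, multi-organ context, or
inter-volume appearance variation of real MRI/CT.  Passing the phantom
benchmark therefore demonstrates that the training mechanics work (masks
select the intended voxels, the coupling helps under label scarcity), not
that real-data accuracy figures transfer.

## Evaluation

Dice and Jaccard are plain set overlap on binary masks (both empty → 1 by
convention).  Surface metrics extract boundary voxels as foreground removed
by 6-connected erosion, take nearest-neighbour distances in both directions
(KD-tree), pool them, and report the 95th percentile (linear interpolation)
as 95HD and the mean as ASD — the pooled convention; max-of-directed is
available via `pooled=False`.  Distances are in voxel units by default, with
a spacing-aware millimetre mode.  An empty mask yields NaN with a warning,
never a silent 0.  Whole-volume inference is sliding-window with per-patch
probability averaging of the two networks (averaging is the default
reporting mode; single-network modes are flags) and overlap averaging.

## Problem sizes

Desk-scale defaults used by the test suite and the verification script,
chosen so the full battery runs on one CPU core: 32³ phantoms and crops,
base_channels 4, depth 2, batch 2+2.  The ablation benchmark trains on
20 phantoms at 20% labeled for 300 iterations and evaluates on 4 held-out
phantoms; the reduction check runs 50 iterations at 16³.  The mask oracle
battery uses 1000 random 4³ fields over C ∈ {2, 3, 4}.

## Known limitations

- CPU-only; wall-clock is dominated by the 3D convolutions, so realistic
  112×112×80 crops at base 16 are out of desk-scale reach.
- 2D inputs are handled as D = 1 volumes, not by a dedicated fast path.
- The phantom benchmark's Dice ceiling is high (~0.97), so the
  semi-supervised margin over the supervised baseline is small in absolute
  terms; the claim verified is directional (mean over seeds), mirroring the
  structure, not the magnitude, of real-data ablations.
- MRI-style normalisation is per-volume z-scoring, a package choice; only
  CT preprocessing (HU clip to [−125, 275], 1 mm resampling) is prescribed
  by the replicated pipeline.
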