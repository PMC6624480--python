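# Methods

## Signal model and preprocessing

A perfusion series is a non-negative 4D tensor in canonical axis order
(w, h, s, f) with TR (frame interval, s), TE (echo time, s) and voxel
edge lengths attached; frame times default to k·TR. Tracer concentration
is obtained from the mono-exponential susceptibility model

    S(t) = S0 · exp(−TE · C(t))   ⇒   C = −ln(S/S0) / TE,

with S0 the per-voxel mean over the pre-bolus baseline frames. The
conversion is isolated in one operation (`signal_to_concentration`) so a
different relaxivity model can be swapped in; its inverse relationship
with the phantom's forward model makes noiseless recovery exact, which
the tests exploit. Samples with S ≤ 0 map to concentration 0 (counted in
the log); voxels with non-positive baseline are dropped from the mask.

The rest of the chain:

- **Brain masking** — Otsu threshold on the temporal mean, largest
  connected component, morphological closing (radius 1). This replaces
  surface-based skull stripping, which is out of scope; the phantom has
  no skull.
- **Motion correction** — an identity hook. The interface point exists;
  phantoms are motion-free and registration is out of scope.
- **Slice-time correction** — per-voxel linear interpolation from the
  slice's acquisition times t_k + offset back to the frame grid, ends
  clamped. Exact on signals linear in time.
- **Spatial smoothing** — per-slice, per-frame 2D Gaussian; sigma given
  in mm and converted through the in-plane voxel size; sigma 0 is the
  identity.
- **Baseline detection** — the global in-mask mean signal is tracked;
  bolus arrival is the first frame more than 3 SD below the initial
  (first-3-frame) mean, and the baseline ends one frame earlier, because
  the global dip lags the arterial rise by about a frame. Default 5
  frames when detection is not requested.
- **Drift removal** — per voxel, a straight line fitted to the baseline
  frames plus the last `tail_frames` frames is subtracted. Near-identity
  when both windows are bolus-free.

Smoothing width is a genuine trade-off for thin vessels: at the phantom's
0.43 mm in-plane resolution and 2-voxel vessel radius, a 2-voxel kernel
dilutes the arterial amplitude about threefold and blurs arterial curve
shapes into a partial-volume ring. The AIF-selection workflows therefore
smooth with 0.43 mm (1 voxel) on noisy data and not at all on noiseless
data; `preprocess` keeps a 0.86 mm default for general map computation,
where a heavier low-pass is conventional.

## Synthetic phantom

The phantom emulates a desk-scale bolus-tracking acquisition with full
ground truth. Geometry: elliptic-cylinder brain support on a 64×64×8 grid
(voxel 0.43×0.43×5.0 mm), 40 frames at 1.5 s, TE 2.6 ms; the full
clinical geometry (512×512×20×50) is reachable through the config.

- **Arterial bolus** — the gamma-variate C_a(t) = A(t−t0)^α e^{−(t−t0)/β}
  (defaults: peak 60 a.u., t0 = 6 s, α = 3, β = 1.5 s; analytic peak at
  t0 + αβ). A through-slice tube (radius 2 voxels) at a random in-brain
  position carries this curve with ±3% per-voxel amplitude jitter. An
  optional second, smaller gamma lobe models recirculation (off by
  default).
- **Tissue** — C_tis = CBF · dt·(C_a ⊛ R) with R(t) = e^{−t/MTT} shifted
  by the local bolus delay, evaluated on the frame grid. The discrete
  convolution is the left-Riemann lower-triangular Toeplitz product —
  the same quadrature the deconvolution matrix uses, so noiseless
  round-trips are exact up to SVD truncation. Baseline physiology:
  CBF 0.10 a.u. (±10% voxel jitter), MTT 4 s, delay 1.5 s.
- **Lesion** — a sphere in one hemisphere with CBF ×0.4 and +6 s delay;
  a smaller concentric core has ADC 500 against a background of 800
  (units 10⁻⁶ mm²/s, so the core threshold 620 applies verbatim).
- **Noise** — additive Gaussian on the signal, SD expressed as a
  fraction of the peak tissue signal dip (default 0.1); signal clipped
  at 0. Rician noise, partial-volume and motion are deliberately not
  modelled, so passing tests show algorithmic correctness under the
  stated kinetic model, not robustness to those clinical effects.
- **Determinism** — one RNG stream per case, seeded from
  (master seed, case index) through `numpy.random.SeedSequence`.

## Fuzzy c-means AIF selection

TDCs are n-dimensional vectors (n = frame count). Standard FCM updates —
centroids as membership^m-weighted means, memberships from inverse
squared-distance ratios to the power 1/(m−1) — run until the largest
membership change is below 1e−5 (defaults c = 5, m = 2, ≤200 iterations).
Initialization is deterministic and order-invariant: curves are ranked
by temporal center of mass and the mean curves of c equal rank bins seed
the centroids. This makes order equivariance exact and removes the need
for a random restart; the `seed` argument is accepted but inert.

Two design points matter in practice:

- **Candidate preselection.** Clustering all ~18k brain TDCs collapses:
  with noise the class structure is a small perturbation on a large
  homogeneous mass and memberships flatten toward 1/c. Selection
  therefore clusters only the top 10% of voxels by peak concentration —
  the conventional preselection in clustering-based AIF estimation.
- **Raw versus normalized curves.** Within the high-amplitude candidate
  set, the informative difference between a true arterial voxel and its
  partial-volume neighbour is *amplitude*: their shapes are nearly
  identical. Clustering therefore runs on raw TDCs by default;
  `normalize=True` restores shape-only (per-voxel min-max normalized)
  clustering for data where amplitude calibration is unreliable.

The arterial cluster is the one whose mean curve minimizes
cost = (t_peak · FWHM) / amplitude — small for curves with large
amplitude, small crest width and early, fast bolus passage; curves with
no positive maximum get infinite cost. Voxels are hard-assigned by
maximum membership (ties to the lower cluster index) and the AIF is the
arithmetic mean TDC of the winning cluster. On noiseless phantoms, a
residual limitation: smoothing-induced amplitude gradients can split the
vessel across two clusters, shrinking the ROI (the returned curve is
still arterial).

## Multi-stream 3D CNN

**Auto-labeling.** The manual AIF (mean TDC over a small annotated ROI)
seeds label expansion: brain voxels within Chebyshev radius r (default 1)
of the ROI are labeled arterial when their TDC has Pearson r ≥ 0.9 with
the manual AIF *and* peak ≥ 50% of its peak. ROI voxels are always
positive.

**Patches.** Around each labeled voxel a pair of tensors is cut
(edge-clamped at borders): spatial layout (f, s_p, wh, wh) and temporal
layout (s_p, f, wh, wh) — pure permutations of one block, mirroring the
two data arrangements the streams consume. Desk preset: wh = 8,
s_p = 4. Negatives are sampled at 3 per positive, half of them *hard*
negatives from the shell within Chebyshev distance 3 of the labels:
patches centered there still contain the vessel, and without them the
classifier learns "patch contains a vessel" rather than "the center
voxel is arterial" and over-segments a halo at inference (observed as a
~2.5× ROI inflation). Patch intensities are scaled per case by the
in-mask maximum concentration.

**Architecture.** Each stream: 8 convolutions (3×3×3, stride 1, same
padding, ReLU) with filter ladder (64,128,256,256,512,512,512,512) at
full scale, five ceil-mode max-pools interleaved as
conv-pool-conv-pool-conv-conv-pool-conv-conv-pool-conv-conv-pool, two
fully connected layers (4096 units at full scale) and a 2-way softmax
output. The leading axis of each stream layout acts as the channel axis;
convolution and pooling run over the remaining three, ordered
(w, h, last) with *last* = slices (spatial stream) or frames (temporal
stream). The temporal stream's first pool kernel/stride is (2,2,1): it
halves only the in-plane axes, keeping full frame resolution through the
early layers. The desk preset is architecture-isomorphic with filters
(8,16,32,32,64,64,64,64), 64 fc units and 8-voxel patches, sized so both
streams train on a CPU in minutes; in-plane patches below 8 voxels are
rejected because the pooling pyramid degenerates.

The engine is a minimal numpy implementation: im2col + BLAS matmul
convolutions with explicit backprop, argmax-tracked ceil-mode pooling,
float32 throughout. He initialization uses the *effective* fan-in — the
number of kernel taps that actually see data at the layer's volume size —
because on late 1×1×1 volumes 26 of 27 taps fall in the zero padding and
nominal-fan-in scaling collapses activations to numerical silence.

**Training.** Mini-batch SGD with momentum on cross-entropy; full-scale
settings batch 50, 50 epochs, lr 1e−3, momentum 0.9. The desk preset
keeps batch, lr and momentum and shortens to 12 epochs, which suffices
on the cleanly separable phantom patch sets. Batch order comes from a
seeded generator, so (seed, data, config) determine the weights bitwise.

**Fusion.** A linear SVM (C = 1) on the concatenated 4-dim softmax
scores of the two streams, fitted on a held-out 20% of the training
patches so the hyperplane is not tuned on scores the streams have
already overfitted.

**Inference.** Per-voxel classification of patch pairs: stride 1 inside
a candidate region (top 5% per-voxel peak concentration, dilated by one
voxel), stride 4 on the remaining brain as a safety scan. The positive
set is reduced to its largest connected component and the AIF is the
mean TDC over the ROI. An empty result raises with advice rather than
returning silently.

## Deconvolution, maps, mismatch

The convolution matrix A is lower-triangular Toeplitz in the AIF, scaled
by dt (left-Riemann quadrature, matching the phantom). Deconvolution is
truncated SVD: singular values below λ_rel·σ_max are zeroed (λ_rel 0.2
for noisy data, the standard range in bolus-tracking; 1e−6 recovers
noiseless round-trips to <1%). The delay-sensitive (non-circulant) form
is deliberate: Tmax is read as the peak time of the plain response, so
delays must survive deconvolution.

- **Tmax** — dt · argmax of the residue, earliest frame on ties.
- **rCBF** — residue maximum (the CBF estimate) divided by the in-mask
  median, or by the mirrored-hemisphere median in `contralateral` mode;
  invariant to global concentration scaling. "Maximum slope of the
  response" is read as the response maximum — the conventional CBF
  estimator; a literal max-derivative variant would slot into the same
  operation.
- **CBV, MTT** — CBV = ∫C_tis / ∫C_a (trapezoid); MTT = CBV/CBF − dt/2.
  The dt/2 term is the trapezoid end-correction for the rectangle-rule
  excess of integrating a causal residue that peaks at time zero;
  without it MTT is biased high by half a frame (~20% at dt 1.5 s,
  MTT 4 s). Disable with `quadrature_correction=False` for the plain
  ratio.
- **Mismatch** — ischemic = {Tmax > 6 s}, core = {ADC < 620}; volumes in
  mL from the voxel size. The mismatch volume is the *difference of the
  two volumes* (clipped at 0), the convention used in penumbra triage
  reports; a voxel-wise set-difference mode is available by flag. The
  ratio divides mismatch volume by core volume and is flagged infinite
  when no core exists and undefined when neither region does.

## Evaluation metrics

Confusion metrics and Dice (2|A∩B| / (|A|+|B|)) are computed over all
voxels; empty-over-empty ratios score 1 by convention. A `mip_axial`
flag collapses both masks along the slice axis before scoring, comparing
axial maximum-intensity projections — the surface on which AIF vessel
masks are conventionally compared. Curve characteristics are amplitude
(max), center (earliest peak time) and crest width (FWHM with linear
interpolation of the half-max crossings; one-sided crossings extend to
the curve boundary and set a flag). Deltas are absolute differences. The
Fréchet distance is the discrete coupling dynamic program over points
(t_i, c_i); curves are conventionally normalized by the peak of the
reference (manual) AIF before comparison, and an optional flag also
rescales the time axis to [0, 1] for cross-TR comparability (off by
default, matching the amplitude-only convention).

## Validation scope and problem sizes

All quantitative claims are validated on the synthetic phantom at desk
scale: 50-draw deconvolution round trips, single-case FCM studies, and
an 8-train/2-test multi-stream study (the package's own sizing choice
for CPU-friendly experiments; the full-scale preset exercises the same
code path). Phantom separability — arterial curves strictly larger in
amplitude and narrower than every tissue curve — is an explicit
generator invariant, so selector scores here bound clinical performance
from above. Known limitations: no recirculation by default, no Rician
noise floor, no motion, no partial-volume mixing at vessel boundaries
beyond what smoothing induces, and FCM cluster splitting on noiseless
smoothed data as noted above.
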