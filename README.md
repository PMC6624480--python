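# perfaid

Automatic arterial input function (AIF) estimation and perfusion analysis
for dynamic susceptibility contrast (DSC) MRI.

## The problem

Quantitative bolus-tracking perfusion imaging needs an AIF — the tracer
concentration curve C_a(t) in a brain-feeding artery — as the reference
input of the deconvolution model

    C_tis(t) = CBF · (C_a ⊛ R)(t),

where R(t) is the tissue residue function. From the deconvolved,
CBF-scaled residue follow the hemodynamic maps: **Tmax** (time to maximum
of the residue), **rCBF** (normalized residue maximum), **CBV**
(∫C_tis / ∫C_a) and **MTT = CBV/CBF**. In acute stroke, the region with
Tmax > 6 s is read as ischemic and ADC < 620 ×10⁻⁶ mm²/s as infarct core;
their volume difference (the *mismatch*) estimates salvageable penumbra.

Manually picking the AIF voxels is slow and poorly reproducible. This
package provides two automatic selectors over the per-voxel time density
curves (TDCs):

- **Multi-stream 3D CNN** (`perfaid.msnet`) — the main method. Two
  architecture-identical streams of 8 conv (3×3×3) + 5 max-pool + 2 fully
  connected layers with a softmax head classify patch pairs arranged
  *frame-by-frame* (spatial stream, f×s×w×h) and *slice-by-slice*
  (temporal stream, s×f×w×h, whose first pool kernel is 2×2×1 to keep
  early frame resolution). Their softmax scores are late-fused by a
  linear SVM. Training labels are auto-expanded from a small manual ROI
  by TDC similarity. The networks are implemented in numpy with explicit
  backprop (im2col + BLAS); the desk preset trains on a CPU in minutes.
- **Fuzzy c-means** (`perfaid.aif_fcm`) — the classical comparator:
  cluster high-amplitude candidate TDCs, select the cluster whose mean
  curve minimizes the arterial-morphology cost (t_peak · FWHM) / amplitude,
  average its voxels.

Around them: NIfTI I/O and the stream tensor layouts
(`perfaid.datamodel`), preprocessing to concentration curves
(`perfaid.preprocess`), truncated-SVD deconvolution, maps and mismatch
(`perfaid.perfusion`), evaluation metrics including the discrete Fréchet
distance (`perfaid.evalmetrics`), and a fully ground-truthed synthetic 4D
phantom generator (`perfaid.phantom`) used for training and validation.

## Worked example

```python
import numpy as np
from perfaid.phantom import PhantomConfig, make_phantom
from perfaid.preprocess import preprocess
from perfaid.aif_fcm import select_aif_fcm
from perfaid.evalmetrics import segmentation_scores

case = make_phantom(PhantomConfig(noise_sd_frac=0.1), seed=7)
conc = preprocess(case.series, sigma_mm=0.43)
result = select_aif_fcm(conc, c=5)
print(segmentation_scores(result.roi, case.vessel_truth).dsc)
print(np.corrcoef(result.curve, case.aif_truth)[0, 1])
```

prints

```
0.8971962616822431
0.982...
```

— the fuzzy c-means ROI overlaps the simulated artery at Dice 0.90 and
the extracted AIF tracks the true bolus at r = 0.98. The same case run
through the trained multi-stream network (see
`examples/03_msnet_training_and_segmentation.py`) reaches Dice ≈ 0.95–1.0
fused. Each script in `examples/` demonstrates one capability end to end
and explains the numbers it prints; a thin CLI (`perfaid phantom`,
`perfaid aif-fcm`, `perfaid train`, `perfaid segment-aif`, `perfaid maps`,
`perfaid mismatch`, `perfaid evaluate`, `perfaid curve-compare`) wraps the
same functions for shell use.

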