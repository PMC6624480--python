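"""Generate a synthetic DSC-MRI phantom and convert it to concentration curves.

Builds one desk-scale case (64 x 64 x 8 voxels, 40 frames at 1.5 s), runs
the preprocessing chain, and compares the mean arterial concentration
curve against the simulated ground-truth bolus.
"""

import numpy as np

from perfaid.phantom import PhantomConfig, make_phantom
from perfaid.preprocess import preprocess

case = make_phantom(PhantomConfig(), seed=7)
print(f"series shape (w,h,s,f): {case.series.shape}")
print(f"brain voxels: {case.brain_mask.n_voxels}, "
      f"arterial voxels: {case.vessel_truth.n_voxels}")

conc = preprocess(case.series, sigma_mm=0.43)
print(f"detected pre-bolus baseline frames: {conc.baseline_frames}")

vessel = case.vessel_truth.mask > 0
extracted = conc.conc[vessel].mean(axis=0)
r = np.corrcoef(extracted, case.aif_truth)[0, 1]
print(f"mean arterial curve vs true bolus: Pearson r = {r:.4f}")
print("  (the preprocessing chain preserves the arterial curve shape; "
      "r near 1 means signal->concentration conversion and detrending "
      "are faithful)")
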