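"""Select the arterial input function by fuzzy c-means clustering.

Clusters the time density curves of a noisy phantom, picks the cluster
with the best arterial morphology (large amplitude, small width, early
peak), and scores the resulting ROI against the simulated vessel.
"""

import numpy as np

from perfaid.aif_fcm import select_aif_fcm
from perfaid.evalmetrics import segmentation_scores
from perfaid.phantom import PhantomConfig, make_phantom
from perfaid.preprocess import preprocess

case = make_phantom(PhantomConfig(noise_sd_frac=0.1), seed=7)
conc = preprocess(case.series, sigma_mm=0.43)

result = select_aif_fcm(conc, c=5)
scores = segmentation_scores(result.roi, case.vessel_truth)
r = np.corrcoef(result.curve, case.aif_truth)[0, 1]

print(f"selected ROI: {result.roi.n_voxels} voxels "
      f"(truth: {case.vessel_truth.n_voxels})")
print(f"Dice vs vessel truth: {scores.dsc:.3f}  "
      f"(1.0 would be a perfect voxel-level match)")
print(f"AIF curve vs truth:   r = {r:.3f}")
ch = result.characteristics
print(f"curve characteristics: amplitude {ch.amplitude:.1f} a.u., "
      f"peak at {ch.center_s:.1f} s, FWHM {ch.width_s:.1f} s")
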