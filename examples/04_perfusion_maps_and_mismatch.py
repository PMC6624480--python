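"""Deconvolve tissue curves and quantify the perfusion-diffusion mismatch.

Uses the true AIF of a noiseless lesion phantom to recover Tmax, rCBF and
MTT by truncated-SVD deconvolution, then applies the stroke-triage
thresholds (Tmax > 6 s ischemic, ADC < 620 infarct core) to report
mismatch volumes and ratio.
"""

import numpy as np

from perfaid.perfusion import compute_maps, mismatch
from perfaid.phantom import PhantomConfig, make_phantom
from perfaid.preprocess import preprocess

case = make_phantom(PhantomConfig(noise_sd_frac=0.0), seed=7)
conc = preprocess(case.series, sigma_mm=0.0)

maps = compute_maps(conc, case.aif_truth, lambda_rel=1e-6)
tissue = (case.brain_mask.mask > 0) & ~(case.vessel_truth.mask > 0)
tmax_err = np.abs(maps.tmax_s[tissue] - case.delay_map[tissue]).max()
mtt_err = np.median(np.abs(maps.mtt_s[tissue] - case.mtt_map[tissue])
                    / case.mtt_map[tissue])
print(f"Tmax worst error vs simulated delay: {tmax_err:.2f} s "
      f"(frame interval {conc.dt_s:.1f} s)")
print(f"MTT median relative error: {mtt_err:.3f}")

report = mismatch(maps.tmax_s, case.adc_map, case.series.voxel_mm,
                  mask=case.brain_mask.mask)
print(f"ischemic volume (Tmax > 6 s): {report.ischemic_volume_ml:.3f} mL")
print(f"infarct core (ADC < 620):     {report.core_volume_ml:.3f} mL")
print(f"mismatch volume:              {report.mismatch_volume_ml:.3f} mL")
print(f"mismatch ratio:               {report.mismatch_ratio:.2f}")
print("  (a large ratio means most ischemic tissue is still salvageable "
      "penumbra rather than infarcted core)")
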