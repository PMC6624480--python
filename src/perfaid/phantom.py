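"""Synthetic 4D DSC-MRI phantom with ground truth.

The phantom emulates a bolus-tracking perfusion acquisition: a brain-shaped
support, a small arterial tube whose voxels carry a gamma-variate bolus
curve, and tissue voxels whose concentration curves are the convolution of
that arterial input function (AIF) with an exponential residue function
scaled by local CBF and shifted by a local bolus delay.  Concentration is
mapped to signal through the mono-exponential susceptibility model
``S(t) = S0 * exp(-TE * C(t))`` and corrupted with additive Gaussian noise.

Ground truth (vessel mask, AIF curve, CBF/delay/MTT maps, ADC map) is
recorded exactly as simulated, so every downstream stage can be scored
against it.

Default geometry is a desk-scale 64 x 64 x 8 x 40 grid with a 1.5 s frame
interval; the full clinical-scale geometry (512 x 512 x 20 x 50, voxel
0.43 x 0.43 x 5.00 mm, TE 2.6 ms) is available through the config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .datamodel import PerfusionSeries, VolumeMask, write_series, write_volume

__all__ = [
    "GammaVariateParams",
    "PhantomConfig",
    "PhantomCase",
    "gamma_variate",
    "make_phantom",
    "make_dataset",
    "write_phantom_case",
]


@dataclasses.dataclass(frozen=True)
class GammaVariateParams:
    """Parameters of the gamma-variate bolus model.

    The curve is ``A * (t - t0)**alpha * exp(-(t - t0) / beta)`` for
    ``t > t0`` and 0 before arrival.  Its analytic peak sits at
    ``t0 + alpha * beta``.
    """

    amplitude_A: float
    t0_s: float
    alpha: float
    beta_s: float

    def __post_init__(self) -> None:
        if self.amplitude_A <= 0:
            raise ValueError("amplitude_A must be > 0")
        if self.alpha <= 0 or self.beta_s <= 0:
            raise ValueError("alpha and beta_s must be > 0")
        if self.t0_s < 0:
            raise ValueError("t0_s must be >= 0")

    @property
    def t_peak_s(self) -> float:
        return self.t0_s + self.alpha * self.beta_s

    @property
    def peak_value(self) -> float:
        dt = self.alpha * self.beta_s
        return self.amplitude_A * dt**self.alpha * np.exp(-self.alpha)

    @classmethod
    def from_peak(
        cls, peak: float, t0_s: float, alpha: float, beta_s: float
    ) -> "GammaVariateParams":
        """Build params whose curve attains the given peak concentration."""
        dt = alpha * beta_s
        a = peak / (dt**alpha * np.exp(-alpha))
        return cls(amplitude_A=a, t0_s=t0_s, alpha=alpha, beta_s=beta_s)


def gamma_variate(t: np.ndarray | float, p: GammaVariateParams) -> np.ndarray:
    """Evaluate the gamma-variate bolus curve at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    dt = np.maximum(t - p.t0_s, 0.0)
    out = np.zeros_like(dt)
    pos = dt > 0
    out[pos] = p.amplitude_A * dt[pos] ** p.alpha * np.exp(-dt[pos] / p.beta_s)
    return out


@dataclasses.dataclass
class PhantomConfig:
    """Geometry, physiology and noise of a synthetic case.

    CBF values are in arbitrary flow units (1/s scale), delays and MTT in
    seconds, ADC in 1e-6 mm^2/s so the conventional infarct-core threshold
    of 620 applies verbatim.  ``noise_sd_frac`` is the Gaussian noise SD
    expressed as a fraction of the peak tissue signal dip.
    """

    dims: tuple[int, int, int, int] = (64, 64, 8, 40)
    voxel_mm: tuple[float, float, float] = (0.43, 0.43, 5.0)
    dt_s: float = 1.5
    te_s: float = 0.0026
    s0: float = 100.0
    # bolus
    aif_peak: float = 60.0
    aif_t0_s: float = 6.0
    aif_alpha: float = 3.0
    aif_beta_s: float = 1.5
    arterial_jitter_frac: float = 0.03
    recirculation: bool = False
    # vessel tube through all slices
    vessel_radius_vox: float = 2.0
    # tissue physiology (uniform ranges sampled per voxel region)
    tissue_cbf: float = 0.10
    tissue_cbf_jitter_frac: float = 0.10
    tissue_mtt_s: float = 4.0
    tissue_delay_s: float = 1.5
    # perfusion lesion (sphere): prolonged delay, reduced CBF
    lesion: bool = True
    lesion_radius_frac: float = 0.22
    lesion_cbf_factor: float = 0.4
    lesion_extra_delay_s: float = 6.0
    # diffusion lesion (infarct core inside the perfusion lesion)
    adc_background: float = 800.0
    adc_core: float = 500.0
    core_radius_frac: float = 0.10
    noise_sd_frac: float = 0.1

    def frame_times(self) -> np.ndarray:
        return np.arange(self.dims[3]) * self.dt_s

    def aif_params(self) -> GammaVariateParams:
        return GammaVariateParams.from_peak(
            self.aif_peak, self.aif_t0_s, self.aif_alpha, self.aif_beta_s
        )


@dataclasses.dataclass
class PhantomCase:
    """One synthetic case: the series plus every ground-truth quantity."""

    series: PerfusionSeries
    vessel_truth: VolumeMask
    aif_truth: np.ndarray
    cbf_map: np.ndarray
    delay_map: np.ndarray
    mtt_map: np.ndarray
    adc_map: np.ndarray
    brain_mask: VolumeMask
    concentration_truth: np.ndarray
    seed: int


class PhantomConfigError(ValueError):
    pass


def _brain_support(w: int, h: int, s: int) -> np.ndarray:
    """Elliptic-cylinder brain support occupying ~80% of the in-plane FOV."""
    x, y = np.meshgrid(np.arange(w), np.arange(h), indexing="ij")
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    disk = ((x - cx) / (0.42 * w)) ** 2 + ((y - cy) / (0.42 * h)) ** 2 <= 1.0
    return np.repeat(disk[:, :, None], s, axis=2)


def convolve_tissue(aif: np.ndarray, residue: np.ndarray, dt: float) -> np.ndarray:
    """Left-Riemann discrete convolution ``dt * (aif (*) residue)``.

    This is the same quadrature the deconvolution matrix uses, so a
    noiseless phantom round-trips exactly up to SVD truncation.
    """
    f = len(aif)
    out = np.zeros(f)
    for k in range(f):
        out[k] = dt * np.dot(aif[: k + 1], residue[k::-1])
    return out


def make_phantom(cfg: PhantomConfig | None = None, seed: int = 0) -> PhantomCase:
    """Simulate one phantom case, deterministic given ``(cfg, seed)``."""
    cfg = cfg or PhantomConfig()
    w, h, s, f = cfg.dims
    rng = np.random.default_rng(seed)
    times = cfg.frame_times()

    brain = _brain_support(w, h, s)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0

    # vessel: a through-slice tube at a random in-brain position
    ang = rng.uniform(0, 2 * np.pi)
    rad = rng.uniform(0.0, 0.22) * min(w, h)
    vx, vy = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
    x, y = np.meshgrid(np.arange(w), np.arange(h), indexing="ij")
    tube = (x - vx) ** 2 + (y - vy) ** 2 <= cfg.vessel_radius_vox**2
    vessel = np.repeat(tube[:, :, None], s, axis=2) & brain
    if not vessel.any():
        raise PhantomConfigError("vessel tube fell outside the brain support")

    aif_p = cfg.aif_params()
    aif = gamma_variate(times, aif_p)
    if cfg.recirculation:
        recirc = GammaVariateParams.from_peak(
            0.15 * cfg.aif_peak, aif_p.t0_s + 8.0, aif_p.alpha, 2.5 * aif_p.beta_s
        )
        aif = aif + gamma_variate(times, recirc)

    # physiology maps
    cbf = np.zeros((w, h, s))
    delay = np.zeros((w, h, s))
    mtt = np.zeros((w, h, s))
    cbf[brain] = cfg.tissue_cbf * (
        1.0 + cfg.tissue_cbf_jitter_frac * rng.standard_normal(int(brain.sum()))
    )
    cbf = np.clip(cbf, 0.2 * cfg.tissue_cbf, None) * brain
    delay[brain] = cfg.tissue_delay_s
    mtt[brain] = cfg.tissue_mtt_s

    adc = np.full((w, h, s), cfg.adc_background, dtype=float) * brain

    if cfg.lesion:
        # perfusion lesion: sphere in one hemisphere
        lz = (s - 1) / 2.0
        lx, ly = cx + 0.22 * w, cy
        rl = cfg.lesion_radius_frac * min(w, h)
        zz = np.arange(s)[None, None, :]
        aspect = cfg.voxel_mm[2] / cfg.voxel_mm[0]
        dist2 = (
            (x[:, :, None] - lx) ** 2
            + (y[:, :, None] - ly) ** 2
            + ((zz - lz) * aspect) ** 2
        )
        lesion = (dist2 <= rl**2) & brain
        if not lesion.any():
            raise PhantomConfigError("lesion region lies outside the brain mask")
        cbf[lesion] *= cfg.lesion_cbf_factor
        delay[lesion] += cfg.lesion_extra_delay_s
        core = (dist2 <= (cfg.core_radius_frac * min(w, h)) ** 2) & brain
        adc[core] = cfg.adc_core

    # tissue concentration: C = CBF * dt * (AIF (*) R(t - delay)); the shifted
    # residue is evaluated on the frame grid, zero before the delay.
    tissue = brain & ~vessel
    conc = np.zeros((w, h, s, f), dtype=float)

    # group voxels by (cbf, delay, mtt) rows for vectorized convolution
    tis_idx = np.argwhere(tissue)
    tvals = np.stack(
        [cbf[tissue], delay[tissue], mtt[tissue]], axis=1
    )  # (V, 3)
    # residue R(t - d) = exp(-(t-d)/mtt) for t >= d
    tt = times[None, :]  # (1, f)
    shifted = tt - tvals[:, 1:2]
    residue = np.where(shifted >= 0, np.exp(-np.maximum(shifted, 0) / tvals[:, 2:3]), 0.0)
    residue *= tvals[:, 0:1]  # CBF-scaled residue, (V, f)
    # convolution as lower-triangular Toeplitz matmul
    conv_mat = convolution_matrix(aif, cfg.dt_s)
    tis_conc = residue @ conv_mat.T  # (V, f)
    conc[tis_idx[:, 0], tis_idx[:, 1], tis_idx[:, 2], :] = tis_conc

    # arterial voxels: AIF with small per-voxel amplitude jitter
    ves_idx = np.argwhere(vessel)
    jit = 1.0 + cfg.arterial_jitter_frac * rng.standard_normal(len(ves_idx))
    conc[ves_idx[:, 0], ves_idx[:, 1], ves_idx[:, 2], :] = jit[:, None] * aif[None, :]

    # signal model + noise
    signal = np.where(brain[..., None], cfg.s0 * np.exp(-cfg.te_s * conc), 0.0)
    if cfg.noise_sd_frac > 0:
        peak_tissue_conc = tis_conc.max() if len(tis_conc) else 0.0
        dip = cfg.s0 * (1.0 - np.exp(-cfg.te_s * peak_tissue_conc))
        noise = cfg.noise_sd_frac * dip * rng.standard_normal(signal.shape)
        signal = np.where(brain[..., None], signal + noise, 0.0)
    signal = np.clip(signal, 0.0, None)

    series = PerfusionSeries(
        signal=signal,
        tr_s=cfg.dt_s,
        te_s=cfg.te_s,
        voxel_mm=np.asarray(cfg.voxel_mm),
        frame_times_s=times,
    )
    vmm = np.asarray(cfg.voxel_mm)
    return PhantomCase(
        series=series,
        vessel_truth=VolumeMask(vessel.astype(np.uint8), vmm),
        aif_truth=aif,
        cbf_map=cbf,
        delay_map=delay,
        mtt_map=mtt,
        adc_map=adc,
        brain_mask=VolumeMask(brain.astype(np.uint8), vmm),
        concentration_truth=conc,
        seed=seed,
    )


def convolution_matrix(aif: np.ndarray, dt: float) -> np.ndarray:
    """Lower-triangular Toeplitz matrix ``A`` with ``A @ r = dt*(aif (*) r)``."""
    f = len(aif)
    mat = np.zeros((f, f))
    for k in range(f):
        mat[k, : k + 1] = aif[k::-1]
    return dt * mat


def case_seed(master_seed: int, index: int) -> int:
    """Stable per-case seed derived from (master seed, case index)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def make_dataset(
    cfg: PhantomConfig | None = None, n_cases: int = 10, master_seed: int = 0
) -> list[PhantomCase]:
    """Generate ``n_cases`` phantoms with independent per-case RNG streams."""
    cfg = cfg or PhantomConfig()
    return [make_phantom(cfg, seed=case_seed(master_seed, i)) for i in range(n_cases)]


def write_phantom_case(case: PhantomCase, out_dir: str | Path) -> None:
    """Write one case (series, masks, truth maps, manifest) as NIfTI + JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vmm = case.series.voxel_mm
    write_series(case.series, out / "series.nii.gz")
    write_volume(case.vessel_truth.mask, vmm, out / "vessel_truth.nii.gz")
    write_volume(case.brain_mask.mask, vmm, out / "brain_mask.nii.gz")
    write_volume(case.cbf_map, vmm, out / "cbf_truth.nii.gz")
    write_volume(case.delay_map, vmm, out / "delay_truth.nii.gz")
    write_volume(case.mtt_map, vmm, out / "mtt_truth.nii.gz")
    write_volume(case.adc_map, vmm, out / "adc.nii.gz")
    manifest = {
        "seed": case.seed,
        "aif_truth": [float(v) for v in case.aif_truth],
        "frame_times_s": [float(t) for t in case.series.frame_times_s],
        "tr_s": float(case.series.tr_s),
        "te_s": float(case.series.te_s),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
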