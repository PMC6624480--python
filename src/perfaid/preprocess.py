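"""Preprocessing chain for DSC-MRI series.

Brain masking (intensity threshold), slice-time correction, in-plane
Gaussian smoothing, signal-to-concentration conversion and linear baseline
drift removal.  Motion correction is exposed as an identity hook so the
pipeline interface is complete for motion-free data.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .datamodel import PerfusionSeries, VolumeMask

__all__ = [
    "ConcentrationSeries",
    "brain_mask",
    "motion_correct",
    "slice_time_correct",
    "smooth_spatial",
    "signal_to_concentration",
    "detect_baseline_frames",
    "remove_drift",
    "preprocess",
    "DegenerateInputError",
]

log = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Input is degenerate for this operation (e.g. empty after masking)."""


@dataclasses.dataclass
class ConcentrationSeries:
    """Per-voxel tracer-concentration time curves (TDCs).

    ``conc`` has shape ``(w, h, s, f)`` and is zero outside ``brain_mask``.
    """

    conc: np.ndarray
    frame_times_s: np.ndarray
    brain_mask: VolumeMask
    baseline_frames: int

    def __post_init__(self) -> None:
        f = self.conc.shape[3]
        if not (2 <= self.baseline_frames < f):
            raise ValueError("baseline_frames must be >= 2 and < frame count")

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.frame_times_s)))

    @property
    def n_frames(self) -> int:
        return self.conc.shape[3]

    def tdcs(self, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (V, f) TDC matrix and (V, 3) voxel indices for a mask."""
        m = self.brain_mask.mask if mask is None else mask
        idx = np.argwhere(m > 0)
        return self.conc[idx[:, 0], idx[:, 1], idx[:, 2], :], idx


def brain_mask(series: PerfusionSeries) -> VolumeMask:
    """Brain support by Otsu threshold on the temporal-mean volume.

    Threshold, keep the largest connected component, then close small gaps
    (radius-1 ball).  Raises on volumes where thresholding separates nothing.
    """
    mean_vol = series.signal.mean(axis=3)
    lo, hi = float(mean_vol.min()), float(mean_vol.max())
    if hi <= lo:
        raise DegenerateInputError("uniform volume: cannot separate brain from background")
    thr = filters.threshold_otsu(mean_vol.ravel())
    fg = mean_vol > thr
    if not fg.any():
        raise DegenerateInputError("empty brain mask after thresholding")
    labels = measure.label(fg, connectivity=1)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    mask = morphology.closing(mask, morphology.ball(1))
    return VolumeMask(mask.astype(np.uint8), series.voxel_mm)


def motion_correct(series: PerfusionSeries) -> PerfusionSeries:
    """Motion-correction hook.

    Identity pass-through: the interface point where a registration-based
    corrector would slot in.  Phantom data are motion-free.
    """
    return series


def slice_time_correct(
    series: PerfusionSeries, slice_offsets_s: np.ndarray
) -> PerfusionSeries:
    """Interpolate every slice's curves onto the common frame grid.

    Slice ``z`` is assumed acquired at ``frame_times + offset[z]``; its
    voxel curves are linearly interpolated back to ``frame_times``, with
    first/last frames clamped.
    """
    offsets = np.asarray(slice_offsets_s, dtype=float)
    s = series.shape[2]
    if offsets.shape != (s,):
        raise ValueError(f"need one offset per slice ({s}), got {offsets.shape}")
    if np.any(offsets < 0) or np.any(offsets >= series.tr_s):
        raise ValueError("slice offsets must lie in [0, TR)")
    t = series.frame_times_s
    out = series.signal.astype(float).copy()
    for z in range(s):
        if offsets[z] == 0:
            continue
        acq_t = t + offsets[z]
        sl = series.signal[:, :, z, :]
        w, h, f = sl.shape
        flat = sl.reshape(-1, f)
        # common linear-interp weights: query times t against knots acq_t
        ti = np.clip(t, acq_t[0], acq_t[-1])
        j = np.clip(np.searchsorted(acq_t, ti, side="right") - 1, 0, f - 2)
        frac = (ti - acq_t[j]) / (acq_t[j + 1] - acq_t[j])
        interp = flat[:, j] * (1 - frac) + flat[:, j + 1] * frac
        out[:, :, z, :] = interp.reshape(w, h, f)
    return PerfusionSeries(
        np.clip(out, 0, None), series.tr_s, series.te_s, series.voxel_mm,
        series.frame_times_s,
    )


def smooth_spatial(series: PerfusionSeries, sigma_mm: float) -> PerfusionSeries:
    """In-plane 2D Gaussian smoothing, applied per slice and per frame.

    ``sigma_mm`` is converted to voxels through the in-plane voxel size;
    ``sigma_mm == 0`` is the identity.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if sigma_mm == 0:
        return series
    sig_vox = (sigma_mm / series.voxel_mm[0], sigma_mm / series.voxel_mm[1], 0.0, 0.0)
    sm = ndimage.gaussian_filter(series.signal.astype(float), sigma=sig_vox)
    return PerfusionSeries(
        np.clip(sm, 0, None), series.tr_s, series.te_s, series.voxel_mm,
        series.frame_times_s,
    )


def detect_baseline_frames(series: PerfusionSeries, mask: VolumeMask | None = None) -> int:
    """Number of pre-bolus frames: frames before the global mean signal
    drops 3 SD below its initial (first-3-frame) mean."""
    m = (mask or brain_mask(series)).mask > 0
    g = series.signal[m].mean(axis=0)
    m0, sd0 = g[:3].mean(), g[:3].std()
    floor = m0 - 3.0 * max(sd0, 1e-3 * abs(m0) + 1e-12)
    below = np.nonzero(g < floor)[0]
    arrival = int(below[0]) if len(below) else len(g)
    # the global-mean dip lags the arterial rise; back off one frame so the
    # baseline never contains bolus signal
    return int(np.clip(arrival - 1, 2, len(g) - 1))


def signal_to_concentration(
    series: PerfusionSeries,
    baseline_frames: int = 5,
    mask: VolumeMask | None = None,
) -> ConcentrationSeries:
    """Convert signal to tracer concentration, ``C = -ln(S/S0) / TE``.

    ``S0`` is the per-voxel mean over the first ``baseline_frames`` frames.
    Samples with ``S <= 0`` map to concentration 0 (counted in the log);
    voxels whose baseline is non-positive are dropped from the mask.
    """
    if baseline_frames < 2:
        raise ValueError("baseline_frames must be >= 2")
    mask = mask or brain_mask(series)
    m = mask.mask > 0
    sig = series.signal.astype(float)
    s0 = sig[..., :baseline_frames].mean(axis=3)

    bad_s0 = m & (s0 <= 0)
    if bad_s0.any():
        log.warning("excluding %d voxels with non-positive baseline", int(bad_s0.sum()))
        m = m & ~bad_s0

    conc = np.zeros_like(sig)
    mm = np.broadcast_to(m[..., None], sig.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mm & (sig > 0), sig / s0[..., None], 1.0)
        conc = np.where(mm & (sig > 0), -np.log(ratio) / series.te_s, 0.0)
    n_nonpos = int((mm & (sig <= 0)).sum())
    if n_nonpos:
        log.info("%d non-positive signal samples set to concentration 0", n_nonpos)
    return ConcentrationSeries(
        conc=conc,
        frame_times_s=series.frame_times_s,
        brain_mask=VolumeMask(m.astype(np.uint8), series.voxel_mm),
        baseline_frames=baseline_frames,
    )


def remove_drift(conc: ConcentrationSeries, tail_frames: int = 5) -> ConcentrationSeries:
    """Remove a linear baseline drift per voxel.

    Fits a straight line to the pre-bolus baseline frames plus the last
    ``tail_frames`` frames of each TDC and subtracts it over the whole
    curve.  On drift-free data (baseline and tail near zero) this is a
    near-identity.
    """
    if tail_frames < 1:
        raise ValueError("tail_frames must be >= 1")
    f = conc.n_frames
    idx = np.unique(np.r_[np.arange(conc.baseline_frames), np.arange(f - tail_frames, f)])
    t = conc.frame_times_s
    m = conc.brain_mask.mask > 0
    tdc, vox = conc.tdcs()
    # least-squares line through the selected samples, vectorized
    ts, ys = t[idx], tdc[:, idx]
    tm = ts.mean()
    denom = ((ts - tm) ** 2).sum()
    slope = ((ts - tm)[None, :] * (ys - ys.mean(axis=1, keepdims=True))).sum(axis=1) / denom
    intercept = ys.mean(axis=1) - slope * tm
    detrended = tdc - (slope[:, None] * t[None, :] + intercept[:, None])
    out = np.zeros_like(conc.conc)
    out[vox[:, 0], vox[:, 1], vox[:, 2], :] = detrended
    out[~m] = 0.0
    return ConcentrationSeries(out, conc.frame_times_s, conc.brain_mask, conc.baseline_frames)


def preprocess(
    series: PerfusionSeries,
    slice_offsets_s: np.ndarray | None = None,
    sigma_mm: float = 0.86,
    baseline_frames: int | None = None,
    detrend_tail_frames: int = 5,
) -> ConcentrationSeries:
    """Full chain: mask -> motion hook -> slice-time -> smooth -> concentration -> detrend."""
    mask = brain_mask(series)
    series = motion_correct(series)
    if slice_offsets_s is not None:
        series = slice_time_correct(series, slice_offsets_s)
    if sigma_mm > 0:
        series = smooth_spatial(series, sigma_mm)
    if baseline_frames is None:
        baseline_frames = detect_baseline_frames(series, mask)
    conc = signal_to_concentration(series, baseline_frames, mask)
    return remove_drift(conc, detrend_tail_frames)
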