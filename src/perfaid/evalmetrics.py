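"""Evaluation machinery: confusion metrics, Dice, AIF curve characteristics
and the discrete Fréchet distance between concentration curves."""

from __future__ import annotations

import dataclasses

import numpy as np

from .datamodel import VolumeMask

__all__ = [
    "SegmentationScores",
    "CurveCharacteristics",
    "segmentation_scores",
    "curve_characteristics",
    "curve_deltas",
    "frechet_distance",
]


@dataclasses.dataclass(frozen=True)
class SegmentationScores:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    dsc: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def _mip_axial(mask: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along the slice axis (any-voxel collapse)."""
    return mask.max(axis=2, keepdims=True)


def segmentation_scores(
    pred: VolumeMask | np.ndarray,
    truth: VolumeMask | np.ndarray,
    mip_axial: bool = False,
) -> SegmentationScores:
    """Voxel-wise confusion metrics and Dice similarity coefficient.

    DSC = 2|A n B| / (|A| + |B|); both-empty masks score 1 by convention.
    With ``mip_axial`` the masks are collapsed along the slice axis before
    scoring, which compares axial maximum-intensity projections — the
    surface on which AIF vessel masks are conventionally compared.
    """
    p = (pred.mask if isinstance(pred, VolumeMask) else np.asarray(pred)) > 0
    t = (truth.mask if isinstance(truth, VolumeMask) else np.asarray(truth)) > 0
    if p.shape != t.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {t.shape}")
    if mip_axial:
        p, t = _mip_axial(p), _mip_axial(t)
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    n = tp + tn + fp + fn

    def ratio(num: int, den: int) -> float:
        return num / den if den else 1.0

    return SegmentationScores(
        accuracy=ratio(tp + tn, n),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
        dsc=ratio(2 * tp, 2 * tp + fp + fn),
    )


@dataclasses.dataclass(frozen=True)
class CurveCharacteristics:
    """Amplitude, peak center and crest width (FWHM) of a bolus curve."""

    amplitude: float
    center_s: float
    width_s: float
    width_truncated: bool = False


def curve_characteristics(
    curve: np.ndarray, times_s: np.ndarray
) -> CurveCharacteristics:
    """Peak amplitude, peak time, and full width at half maximum.

    The half-maximum crossings are located by linear interpolation on each
    side of the (earliest) peak; if the curve never falls below half max on
    one side, the width extends to the curve boundary and is flagged.
    """
    c = np.asarray(curve, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if c.shape != t.shape:
        raise ValueError("curve and times must have the same length")
    amp = float(c.max())
    if amp <= 0:
        raise ValueError("curve must have a positive maximum")
    k = int(np.argmax(c))
    center = float(t[k])
    half = amp / 2.0

    truncated = False
    # left crossing
    left = t[0]
    below = np.nonzero(c[: k + 1] < half)[0]
    if len(below):
        i = below[-1]
        frac = (half - c[i]) / (c[i + 1] - c[i])
        left = t[i] + frac * (t[i + 1] - t[i])
    else:
        truncated = True
    # right crossing
    right = t[-1]
    below = np.nonzero(c[k:] < half)[0]
    if len(below):
        j = k + below[0]
        frac = (c[j - 1] - half) / (c[j - 1] - c[j])
        right = t[j - 1] + frac * (t[j] - t[j - 1])
    else:
        truncated = True
    return CurveCharacteristics(
        amplitude=amp, center_s=center, width_s=float(right - left),
        width_truncated=truncated,
    )


def curve_deltas(
    auto: CurveCharacteristics, manual: CurveCharacteristics
) -> tuple[float, float, float]:
    """Absolute characteristic differences (d_amplitude, d_center_s, d_width_s)."""
    return (
        abs(auto.amplitude - manual.amplitude),
        abs(auto.center_s - manual.center_s),
        abs(auto.width_s - manual.width_s),
    )


def frechet_distance(
    curve_a: np.ndarray,
    curve_b: np.ndarray,
    times_s: np.ndarray | None = None,
    normalize_by: float | None = None,
    rescale_time: bool = False,
) -> float:
    """Discrete Fréchet distance between two sampled curves.

    Curves are treated as polylines of points ``(t_i, c_i)``.  When
    ``normalize_by`` is given (conventionally the peak of the manually
    extracted AIF) both value axes are divided by it, putting the reference
    curve in [0, 1].  ``rescale_time`` additionally maps the time axis onto
    [0, 1] so distances are comparable across frame intervals (off by
    default: amplitude-only normalization is the conventional comparison).

    Computed by the standard O(n*m) coupling dynamic program; symmetric,
    non-negative, and zero iff the point sequences coincide.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("curves must be 1D")
    if len(a) != len(b):
        raise ValueError(f"curve length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("curves must have length >= 2")
    t = np.arange(len(a), dtype=float) if times_s is None else np.asarray(times_s, dtype=float)
    if normalize_by is not None:
        if normalize_by <= 0:
            raise ValueError("normalize_by must be > 0")
        a = a / normalize_by
        b = b / normalize_by
    if rescale_time:
        t = (t - t[0]) / (t[-1] - t[0])
    pa = np.stack([t, a], axis=1)
    pb = np.stack([t, b], axis=1)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)

    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j])
    return float(ca[-1, -1])
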