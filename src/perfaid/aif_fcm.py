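"""AIF selection by fuzzy c-means clustering of time density curves.

TDCs inside the brain mask are clustered as n-dimensional vectors (n = the
frame count).  The cluster whose mean curve best matches the ideal AIF
morphology — large amplitude, small width, fast attenuation — is selected
through a cost function, and the AIF is the arithmetic mean of the TDCs of
that cluster's voxels.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .datamodel import VolumeMask
from .evalmetrics import CurveCharacteristics, curve_characteristics
from .preprocess import ConcentrationSeries, DegenerateInputError

__all__ = [
    "FcmState",
    "AIFResult",
    "fcm_cluster",
    "aif_cost",
    "select_aif_fcm",
]


@dataclasses.dataclass
class FcmState:
    """Converged fuzzy c-means state.

    ``centroids`` is (c, n); ``membership`` is (V, c) with rows summing to
    one; ``objective`` is the per-iteration trace of the weighted
    within-cluster distance, non-increasing by construction.
    """

    centroids: np.ndarray
    membership: np.ndarray
    fuzzifier_m: float
    objective: np.ndarray
    n_iter: int


@dataclasses.dataclass
class AIFResult:
    roi: VolumeMask
    curve: np.ndarray
    characteristics: CurveCharacteristics


def _minmax_normalize(x: np.ndarray) -> np.ndarray:
    rng = x.max(axis=1, keepdims=True) - x.min(axis=1, keepdims=True)
    flat = rng[:, 0] <= 0
    out = np.zeros_like(x)
    ok = ~flat
    out[ok] = (x[ok] - x[ok].min(axis=1, keepdims=True)) / rng[ok]
    return out


def _init_centroids(x: np.ndarray, c: int) -> np.ndarray:
    """Order-invariant init: mean curves of evenly spaced bolus-timing bins.

    Curves are ranked by their temporal center of mass (arterial curves
    arrive early, delayed tissue late), split into ``c`` equal rank bins,
    and each bin's mean curve seeds one centroid.  Identical inputs under
    any voxel permutation yield identical centroids, which makes the whole
    clustering order-equivariant and reproducible without randomness.
    """
    frames = np.arange(x.shape[1])
    w = np.clip(x, 0, None)
    tot = w.sum(axis=1)
    com = np.where(tot > 0, (w * frames).sum(axis=1) / np.maximum(tot, 1e-300),
                   frames.mean())
    order = np.argsort(com, kind="stable")
    bins = np.array_split(order, c)
    return np.stack([x[b].mean(axis=0) for b in bins])


def candidate_mask(conc: ConcentrationSeries, frac: float = 0.1) -> np.ndarray:
    """High-amplitude candidate voxels for AIF clustering.

    Keeps the in-mask voxels whose peak concentration lies in the top
    ``frac`` fraction — the conventional preselection before clustering
    TDCs, which removes the mass of low-contrast tissue and noise curves
    that would otherwise dominate the distance structure.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    m = conc.brain_mask.mask > 0
    amp = conc.conc.max(axis=3)
    thr = np.quantile(amp[m], 1.0 - frac)
    return (amp >= thr) & m


def fcm_cluster(
    conc: ConcentrationSeries,
    c: int = 5,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed: int = 0,
    normalize: bool = True,
    voxel_subset: np.ndarray | None = None,
) -> FcmState:
    """Standard fuzzy c-means on the in-mask TDCs.

    Alternates the two closed-form updates — centroids as membership^m
    weighted means, memberships from inverse squared-distance ratios raised
    to 1/(m-1) — until the largest membership change falls below ``tol``.
    ``seed`` is accepted for interface stability; initialization is
    deterministic (amplitude-quantile curves), so it has no effect.
    """
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    x, _ = conc.tdcs(voxel_subset)
    if len(x) < c:
        raise DegenerateInputError(f"only {len(x)} TDCs for {c} clusters")
    if normalize:
        x = _minmax_normalize(x)

    cent = _init_centroids(x, c)
    u = _memberships(x, cent, m)
    objective = []
    for it in range(max_iter):
        um = u**m
        cent = (um.T @ x) / np.maximum(um.sum(axis=0)[:, None], 1e-300)
        u_new = _memberships(x, cent, m)
        d2 = _sq_distances(x, cent)
        objective.append(float((u_new**m * d2).sum()))
        delta = np.abs(u_new - u).max()
        u = u_new
        if delta < tol:
            break
    return FcmState(
        centroids=cent,
        membership=u,
        fuzzifier_m=m,
        objective=np.asarray(objective),
        n_iter=len(objective),
    )


def _sq_distances(x: np.ndarray, cent: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - cent[None, :, :]
    return np.einsum("vcn,vcn->vc", diff, diff)


def _memberships(x: np.ndarray, cent: np.ndarray, m: float) -> np.ndarray:
    d2 = _sq_distances(x, cent)
    # exact-hit handling: membership 1 on the coincident centroid(s)
    zero = d2 <= 1e-30
    u = np.zeros_like(d2)
    hit = zero.any(axis=1)
    if hit.any():
        u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    rest = ~hit
    if rest.any():
        p = 1.0 / (m - 1.0)
        inv = d2[rest] ** (-p)
        u[rest] = inv / inv.sum(axis=1, keepdims=True)
    return u


def aif_cost(centroid: np.ndarray, frame_times_s: np.ndarray) -> float:
    """Morphology cost for an AIF candidate curve: (t_peak * FWHM) / amplitude.

    Lower is better — it rewards large amplitude, small crest width and
    early, fast bolus passage.  Strictly positive and finite for any curve
    with a positive maximum; curves without one get infinite cost and are
    never selected.
    """
    c = np.asarray(centroid, dtype=float)
    if c.max() <= 0:
        return float("inf")
    ch = curve_characteristics(c, np.asarray(frame_times_s, dtype=float))
    eps = 1e-6
    t_peak = max(ch.center_s - frame_times_s[0], eps)
    width = max(ch.width_s, eps)
    return float(t_peak * width / ch.amplitude)


def select_aif_fcm(
    conc: ConcentrationSeries,
    c: int = 5,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed: int = 0,
    candidate_frac: float = 0.1,
    normalize: bool = False,
) -> AIFResult:
    """Cluster TDCs, pick the minimum-cost cluster, average its voxels.

    Clustering runs on the raw TDCs of the high-amplitude candidate
    voxels: within that subset, amplitude is the feature that separates
    true arterial voxels from their partial-volume neighbours, whose
    curves have the same *shape* at reduced scale and are therefore
    indistinguishable after per-voxel normalization (``normalize=True``
    restores shape-only clustering).  The cost is evaluated on each
    cluster's mean curve, and voxels are hard-assigned to their
    maximum-membership cluster (ties to the lower cluster index).
    """
    subset = candidate_mask(conc, candidate_frac)
    state = fcm_cluster(
        conc, c=c, m=m, tol=tol, max_iter=max_iter, seed=seed,
        voxel_subset=subset, normalize=normalize,
    )
    x, vox = conc.tdcs(subset)
    assign = np.argmax(state.membership, axis=1)

    t = conc.frame_times_s
    best_k, best_cost = -1, float("inf")
    for k in range(c):
        members = assign == k
        if not members.any():
            continue
        mean_curve = x[members].mean(axis=0)
        cost = aif_cost(mean_curve, t)
        if cost < best_cost:
            best_k, best_cost = k, cost
    if best_k < 0:
        raise DegenerateInputError("no cluster has a positive mean curve")

    members = assign == best_k
    roi = np.zeros(conc.brain_mask.mask.shape, dtype=np.uint8)
    sel = vox[members]
    roi[sel[:, 0], sel[:, 1], sel[:, 2]] = 1
    curve = x[members].mean(axis=0)
    return AIFResult(
        roi=VolumeMask(roi, conc.brain_mask.voxel_mm),
        curve=curve,
        characteristics=curve_characteristics(curve, t),
    )
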