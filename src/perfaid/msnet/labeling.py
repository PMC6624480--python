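"""Auto-labeling from manual AIF annotations and patch extraction.

A manual AIF ROI (a handful of annotated arterial voxels) is expanded into
a training label volume: voxels in a Chebyshev neighborhood of the ROI
whose TDC is strongly correlated with the manual AIF and carries a
comparable peak amplitude are labeled arterial.  Around every labeled
voxel a pair of patch tensors is cut — one in the spatial stream layout
(f, s_p, wh, wh), one in the temporal layout (s_p, f, wh, wh) — together
with amplitude-matched negative patches sampled from the rest of the
brain.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from ..datamodel import VolumeMask
from ..preprocess import ConcentrationSeries, DegenerateInputError

__all__ = ["LabeledPatchSet", "make_labels", "extract_patches", "concat_patch_sets",
           "normalization_scale"]


@dataclasses.dataclass
class LabeledPatchSet:
    """Index-aligned spatial/temporal patch tensors with binary labels."""

    spatial_patches: np.ndarray   # (N, f, s_p, wh, wh)
    temporal_patches: np.ndarray  # (N, s_p, f, wh, wh)
    labels: np.ndarray            # (N,) in {0, 1}
    provenance: np.ndarray        # (N, 4): case_id, x, y, z

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.spatial_patches) == len(self.temporal_patches) == n
                == len(self.provenance)):
            raise ValueError("patch arrays and labels must be index-aligned")

    @property
    def class_counts(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    def subset(self, idx: np.ndarray) -> "LabeledPatchSet":
        return LabeledPatchSet(
            self.spatial_patches[idx], self.temporal_patches[idx],
            self.labels[idx], self.provenance[idx],
        )


def concat_patch_sets(sets: list[LabeledPatchSet]) -> LabeledPatchSet:
    return LabeledPatchSet(
        np.concatenate([s.spatial_patches for s in sets]),
        np.concatenate([s.temporal_patches for s in sets]),
        np.concatenate([s.labels for s in sets]),
        np.concatenate([s.provenance for s in sets]),
    )


def make_labels(
    conc: ConcentrationSeries,
    manual_roi: VolumeMask,
    r_voxels: int = 2,
    corr_min: float = 0.9,
    amp_min_frac: float = 0.5,
) -> VolumeMask:
    """Expand a manual AIF ROI into a training label volume.

    The manual AIF is the mean TDC over the ROI.  Every brain voxel within
    Chebyshev radius ``r_voxels`` of the ROI is labeled arterial when its
    TDC has Pearson correlation >= ``corr_min`` with the manual AIF *and*
    a peak of at least ``amp_min_frac`` of the manual AIF peak.  ROI voxels
    themselves are always labeled.
    """
    if manual_roi.n_voxels == 0:
        raise ValueError("manual ROI is empty")
    if not (0 < corr_min <= 1):
        raise ValueError("corr_min must lie in (0, 1]")
    roi = manual_roi.mask > 0
    aif = conc.conc[roi].mean(axis=0)

    if r_voxels > 0:
        size = 2 * r_voxels + 1
        neighborhood = ndimage.binary_dilation(roi, np.ones((size,) * 3, dtype=bool))
    else:
        neighborhood = roi
    candidates = neighborhood & (conc.brain_mask.mask > 0) & ~roi
    labels = roi.copy()
    idx = np.argwhere(candidates)
    if len(idx):
        tdc = conc.conc[idx[:, 0], idx[:, 1], idx[:, 2], :]
        ac = aif - aif.mean()
        tc = tdc - tdc.mean(axis=1, keepdims=True)
        denom = np.sqrt((tc**2).sum(axis=1) * (ac**2).sum())
        corr = np.where(denom > 0, (tc @ ac) / np.maximum(denom, 1e-300), 0.0)
        keep = (corr >= corr_min) & (tdc.max(axis=1) >= amp_min_frac * aif.max())
        sel = idx[keep]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return VolumeMask(labels.astype(np.uint8), manual_roi.voxel_mm)


def normalization_scale(conc: ConcentrationSeries) -> float:
    """Per-case intensity scale: the in-mask maximum absolute concentration."""
    m = conc.brain_mask.mask > 0
    scale = float(np.abs(conc.conc[m]).max())
    return scale if scale > 0 else 1.0


def _clip_range(center: int, width: int, size: int) -> np.ndarray:
    start = center - width // 2
    return np.clip(np.arange(start, start + width), 0, size - 1)


def cut_patch_pair(
    conc_arr: np.ndarray, x: int, y: int, z: int, patch_wh: int, slices_per_patch: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the (spatial, temporal) patch tensors centered on one voxel.

    Borders are handled by edge-clamped index replication, so patches near
    the volume boundary keep their nominal size.
    """
    w, h, s, _ = conc_arr.shape
    xs = _clip_range(x, patch_wh, w)
    ys = _clip_range(y, patch_wh, h)
    zs = _clip_range(z, min(slices_per_patch, s), s)
    block = conc_arr[np.ix_(xs, ys, zs)]  # (wh, wh, s_p, f)
    spatial = np.transpose(block, (3, 2, 0, 1))   # f x s_p x wh x wh
    temporal = np.transpose(block, (2, 3, 0, 1))  # s_p x f x wh x wh
    return spatial, temporal


def extract_patches(
    conc: ConcentrationSeries,
    labels: VolumeMask,
    patch_wh: int = 8,
    slices_per_patch: int = 4,
    neg_ratio: float = 3.0,
    seed: int = 0,
    max_positives: int | None = None,
    case_id: int = 0,
    hard_neg_frac: float = 0.5,
) -> LabeledPatchSet:
    """Build the labeled patch set for one case.

    One patch pair per positive voxel (optionally subsampled to
    ``max_positives``), plus ``neg_ratio`` negatives per positive.  A
    ``hard_neg_frac`` share of the negatives is drawn from the shell just
    outside the labels (Chebyshev distance <= 3): patches centered there
    still contain the vessel, so without them the classifier learns
    "patch contains a vessel" rather than "the *center voxel* is
    arterial" and over-segments at inference.  The remainder is uniform
    over the unlabeled brain.  Sampling is deterministic given ``seed``.
    Concentrations are scaled by the case's in-mask maximum so patch
    intensities are comparable across cases.
    """
    w, h, s, f = conc.conc.shape
    if patch_wh > min(w, h):
        raise ValueError("patch_wh exceeds the in-plane volume size")
    pos = np.argwhere(labels.mask > 0)
    if len(pos) == 0:
        raise DegenerateInputError("no positive labels to extract patches from")
    rng = np.random.default_rng(seed)
    if max_positives is not None and len(pos) > max_positives:
        pos = pos[rng.permutation(len(pos))[:max_positives]]

    lab = labels.mask > 0
    brain = conc.brain_mask.mask > 0
    shell = ndimage.binary_dilation(lab, np.ones((7, 7, 7), bool)) & ~lab & brain
    n_neg = int(round(neg_ratio * len(pos)))
    n_hard = min(int(round(hard_neg_frac * n_neg)), int(shell.sum()))
    hard_pool = np.argwhere(shell)
    easy_pool = np.argwhere(brain & ~lab & ~shell)
    n_easy = min(n_neg - n_hard, len(easy_pool))
    neg = np.concatenate([
        hard_pool[rng.choice(len(hard_pool), size=n_hard, replace=False)],
        easy_pool[rng.choice(len(easy_pool), size=n_easy, replace=False)],
    ])

    scale = normalization_scale(conc)
    arr = (conc.conc / scale).astype(np.float32)

    sp, tp, lab, prov = [], [], [], []
    for voxels, y_val in ((pos, 1), (neg, 0)):
        for x, y, z in voxels:
            s_patch, t_patch = cut_patch_pair(arr, x, y, z, patch_wh, slices_per_patch)
            sp.append(s_patch)
            tp.append(t_patch)
            lab.append(y_val)
            prov.append((case_id, x, y, z))
    return LabeledPatchSet(
        np.stack(sp), np.stack(tp),
        np.asarray(lab, dtype=np.int64), np.asarray(prov, dtype=np.int64),
    )
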