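"""Inference: sliding-window AIF ROI segmentation and pipeline bundling."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from skimage import measure

from ..aif_fcm import AIFResult
from ..datamodel import VolumeMask
from ..evalmetrics import curve_characteristics
from ..preprocess import ConcentrationSeries
from .config import NetConfig, TrainConfig, net_preset, train_preset
from .fusion import apply_fusion, fuse_svm
from .labeling import (LabeledPatchSet, concat_patch_sets, cut_patch_pair,
                       extract_patches, make_labels, normalization_scale)
from .model import build_stream, stream_forward, train_stream
from .nn import Sequential

__all__ = ["EmptyROIError", "MsNetModel", "segment_aif", "train_msnet"]


class EmptyROIError(RuntimeError):
    """No voxel was classified arterial; lower the candidate threshold or stride."""


@dataclasses.dataclass
class MsNetModel:
    """Trained spatial + temporal streams with their SVM fusion layer."""

    spatial: Sequential
    temporal: Sequential
    fusion: object
    net_cfg_spatial: NetConfig
    net_cfg_temporal: NetConfig
    train_cfg: TrainConfig
    n_frames: int

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            out / "weights.npz",
            **{f"spatial_{i}": w for i, w in enumerate(self.spatial.get_weights())},
            **{f"temporal_{i}": w for i, w in enumerate(self.temporal.get_weights())},
            fusion_coef=self.fusion.coef_,
            fusion_intercept=self.fusion.intercept_,
            fusion_classes=self.fusion.classes_,
        )
        cfg = {
            "net_cfg_spatial": dataclasses.asdict(self.net_cfg_spatial),
            "net_cfg_temporal": dataclasses.asdict(self.net_cfg_temporal),
            "train_cfg": dataclasses.asdict(self.train_cfg),
            "n_frames": self.n_frames,
        }
        (out / "config.json").write_text(json.dumps(cfg, indent=1))

    @classmethod
    def load(cls, model_dir: str | Path) -> "MsNetModel":
        from sklearn.svm import LinearSVC

        d = Path(model_dir)
        cfg = json.loads((d / "config.json").read_text())

        def tupled(c: dict) -> NetConfig:
            c = dict(c)
            c["conv_filters"] = tuple(c["conv_filters"])
            c["kernel"] = tuple(c["kernel"])
            c["pool_kernels"] = tuple(tuple(k) for k in c["pool_kernels"])
            return NetConfig(**c)

        ncs = tupled(cfg["net_cfg_spatial"])
        nct = tupled(cfg["net_cfg_temporal"])
        tc = TrainConfig(**cfg["train_cfg"])
        f = int(cfg["n_frames"])
        spatial = build_stream(ncs, "spatial", f)
        temporal = build_stream(nct, "temporal", f)
        with np.load(d / "weights.npz") as z:
            spatial.set_weights(
                [z[f"spatial_{i}"] for i in range(len(spatial.get_weights()))]
            )
            temporal.set_weights(
                [z[f"temporal_{i}"] for i in range(len(temporal.get_weights()))]
            )
            svm = LinearSVC()
            svm.coef_ = z["fusion_coef"]
            svm.intercept_ = z["fusion_intercept"]
            svm.classes_ = z["fusion_classes"]
        return cls(spatial, temporal, svm, ncs, nct, tc, f)


def train_msnet(
    cases: list[tuple[ConcentrationSeries, VolumeMask]],
    preset: str = "desk",
    train_cfg: TrainConfig | None = None,
    r_voxels: int = 1,
    corr_min: float = 0.9,
    neg_ratio: float = 3.0,
    max_positives_per_case: int = 24,
    fusion_frac: float = 0.2,
    seed: int = 0,
) -> MsNetModel:
    """Full training pipeline on (concentration, manual ROI) cases.

    Auto-labels each case from its manual annotation, extracts patch
    pairs, trains the spatial and temporal streams on 80% of the patches,
    and fits the SVM fusion layer on the held-out 20% split.
    """
    if not cases:
        raise ValueError("no training cases")
    tcfg = train_cfg or dataclasses.replace(train_preset("desk"), seed=seed)
    n_frames = cases[0][0].n_frames
    ncs = net_preset(preset, "spatial")
    nct = net_preset(preset, "temporal")

    sets: list[LabeledPatchSet] = []
    for i, (conc, manual_roi) in enumerate(cases):
        labels = make_labels(conc, manual_roi, r_voxels=r_voxels, corr_min=corr_min)
        sets.append(
            extract_patches(
                conc, labels, patch_wh=ncs.patch_wh,
                slices_per_patch=ncs.slices_per_patch, neg_ratio=neg_ratio,
                seed=seed + 1000 + i, max_positives=max_positives_per_case,
                case_id=i,
            )
        )
    patches = concat_patch_sets(sets)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patches.labels))
    n_fuse = max(int(round(fusion_frac * len(order))), 4)
    fuse_set = patches.subset(order[:n_fuse])
    fit_set = patches.subset(order[n_fuse:])

    spatial = build_stream(ncs, "spatial", n_frames, seed=seed + 1)
    temporal = build_stream(nct, "temporal", n_frames, seed=seed + 2)
    train_stream(spatial, fit_set, "spatial", tcfg)
    train_stream(temporal, fit_set, "temporal",
                 dataclasses.replace(tcfg, seed=tcfg.seed + 1))

    s_scores = stream_forward(spatial, fuse_set.spatial_patches, "spatial")
    t_scores = stream_forward(temporal, fuse_set.temporal_patches, "temporal")
    svm = fuse_svm(s_scores, t_scores, fuse_set.labels)
    return MsNetModel(spatial, temporal, svm, ncs, nct, tcfg, n_frames)


def segment_aif(
    model: MsNetModel,
    conc: ConcentrationSeries,
    candidate_frac: float = 0.05,
    coarse_stride: int = 4,
    batch: int = 256,
    mode: str = "fused",
) -> AIFResult:
    """Classify brain voxels into an AIF ROI and average its TDCs.

    Voxels in the high-amplitude candidate region (top ``candidate_frac``
    of per-voxel peak concentration, dilated by one voxel) are classified
    at stride 1; the rest of the brain is scanned on a coarse grid of
    stride ``coarse_stride``.  Positive voxels are reduced to their
    largest connected component.  ``mode`` selects the fused decision or a
    single stream ("spatial"/"temporal") for ablation.
    """
    if mode not in ("fused", "spatial", "temporal"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = model.net_cfg_spatial
    m = conc.brain_mask.mask > 0
    amp = conc.conc.max(axis=3)
    thr = np.quantile(amp[m], 1.0 - candidate_frac)
    from scipy import ndimage

    cand = ndimage.binary_dilation(amp >= thr, np.ones((3, 3, 3), bool)) & m
    coarse = np.zeros_like(m)
    coarse[::coarse_stride, ::coarse_stride, ::coarse_stride] = True
    scan = cand | (coarse & m & ~cand)
    voxels = np.argwhere(scan)

    scale = normalization_scale(conc)
    arr = (conc.conc / scale).astype(np.float32)

    positives = np.zeros(m.shape, dtype=bool)
    for start in range(0, len(voxels), batch):
        chunk = voxels[start:start + batch]
        sp = np.stack([
            cut_patch_pair(arr, x, y, z, cfg.patch_wh, cfg.slices_per_patch)[0]
            for x, y, z in chunk
        ])
        tp = np.transpose(sp, (0, 2, 1, 3, 4))  # spatial -> temporal layout
        if mode in ("fused", "spatial"):
            s_scores = stream_forward(model.spatial, sp, "spatial", batch=batch)
        if mode in ("fused", "temporal"):
            t_scores = stream_forward(model.temporal, tp, "temporal", batch=batch)
        if mode == "fused":
            pred = apply_fusion(model.fusion, s_scores, t_scores)
        elif mode == "spatial":
            pred = (s_scores[:, 1] > 0.5).astype(np.int64)
        else:
            pred = (t_scores[:, 1] > 0.5).astype(np.int64)
        hits = chunk[pred == 1]
        positives[hits[:, 0], hits[:, 1], hits[:, 2]] = True

    positives &= m
    if not positives.any():
        raise EmptyROIError(
            "no voxel classified as AIF; consider a larger candidate_frac "
            "or smaller coarse_stride"
        )
    labels = measure.label(positives, connectivity=3)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    roi = labels == largest

    curve = conc.conc[roi].mean(axis=0)
    return AIFResult(
        roi=VolumeMask(roi.astype(np.uint8), conc.brain_mask.voxel_mm),
        curve=curve,
        characteristics=curve_characteristics(curve, conc.frame_times_s),
    )
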