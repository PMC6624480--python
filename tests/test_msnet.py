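import numpy as np
import pytest

from perfaid.datamodel import VolumeMask
from perfaid.msnet import (NetConfig, TrainConfig, apply_fusion, build_stream,
                           extract_patches, fuse_svm, make_labels, net_preset,
                           stream_forward, stream_input, train_stream)
from perfaid.msnet.nn import Conv3D, Dense, MaxPool3D, Sequential
from perfaid.preprocess import ConcentrationSeries, DegenerateInputError


def toy_conc(w=16, h=16, s=4, f=10, seed=0):
    rng = np.random.default_rng(seed)
    conc = rng.random((w, h, s, f))
    mask = VolumeMask(np.ones((w, h, s), np.uint8), np.ones(3))
    return ConcentrationSeries(conc, np.arange(f) * 1.5, mask, 2)


def synthetic_patch_set(n=200, f=10, wh=8, sp=4, seed=0, separation=3.0):
    """Separable two-class patch pairs: class 1 has a bright center bump."""
    from perfaid.msnet.labeling import LabeledPatchSet

    rng = np.random.default_rng(seed)
    labels = (np.arange(n) % 2).astype(np.int64)
    spatial = rng.standard_normal((n, f, sp, wh, wh)).astype(np.float32) * 0.3
    bump = np.zeros((f, sp, wh, wh), dtype=np.float32)
    bump[f // 3: 2 * f // 3, sp // 2, wh // 2, wh // 2] = separation
    spatial[labels == 1] += bump
    temporal = np.transpose(spatial, (0, 2, 1, 3, 4)).copy()
    prov = np.zeros((n, 4), dtype=np.int64)
    return LabeledPatchSet(spatial, temporal, labels, prov)


class TestMakeLabels:
    def test_zero_radius_returns_manual_roi(self):
        conc = toy_conc()
        roi = np.zeros((16, 16, 4), np.uint8)
        roi[4:6, 4:6, 1] = 1
        manual = VolumeMask(roi, np.ones(3))
        labels = make_labels(conc, manual, r_voxels=0, corr_min=1.0)
        assert np.array_equal(labels.mask, roi)

    def test_anticorrelated_neighbor_excluded(self):
        f = 12
        t = np.arange(f) * 1.0
        conc_arr = np.zeros((5, 5, 1, f))
        curve = np.exp(-((t - 5) ** 2) / 4)
        conc_arr[2, 2, 0] = 10 * curve
        conc_arr[2, 3, 0] = 10 * (curve.max() - curve)  # anticorrelated, big amp
        mask = VolumeMask(np.ones((5, 5, 1), np.uint8), np.ones(3))
        conc = ConcentrationSeries(conc_arr, t, mask, 2)
        roi = np.zeros((5, 5, 1), np.uint8)
        roi[2, 2, 0] = 1
        labels = make_labels(conc, VolumeMask(roi, np.ones(3)), r_voxels=1,
                             corr_min=0.9)
        assert labels.mask[2, 3, 0] == 0
        assert labels.mask[2, 2, 0] == 1

    def test_correlated_similar_amplitude_neighbor_included(self):
        f = 12
        t = np.arange(f) * 1.0
        conc_arr = np.zeros((5, 5, 1, f))
        curve = 10 * np.exp(-((t - 5) ** 2) / 4)
        conc_arr[2, 2, 0] = curve
        conc_arr[2, 3, 0] = 0.9 * curve
        mask = VolumeMask(np.ones((5, 5, 1), np.uint8), np.ones(3))
        conc = ConcentrationSeries(conc_arr, t, mask, 2)
        roi = np.zeros((5, 5, 1), np.uint8)
        roi[2, 2, 0] = 1
        labels = make_labels(conc, VolumeMask(roi, np.ones(3)), r_voxels=1,
                             corr_min=0.9)
        assert labels.mask[2, 3, 0] == 1

    def test_phantom_labels_high_precision(self, noiseless_case, noiseless_conc):
        labels = make_labels(noiseless_conc, noiseless_case.vessel_truth,
                             r_voxels=2, corr_min=0.9)
        lab = labels.mask > 0
        truth = noiseless_case.vessel_truth.mask > 0
        precision = (lab & truth).sum() / lab.sum()
        assert precision >= 0.9

    def test_empty_roi_rejected(self):
        conc = toy_conc()
        with pytest.raises(ValueError):
            make_labels(conc, VolumeMask(np.zeros((16, 16, 4), np.uint8),
                                         np.ones(3)))


class TestExtractPatches:
    def test_counts_single_positive(self):
        conc = toy_conc()
        lab = np.zeros((16, 16, 4), np.uint8)
        lab[8, 8, 2] = 1
        ps = extract_patches(conc, VolumeMask(lab, np.ones(3)), patch_wh=8,
                             slices_per_patch=4, neg_ratio=3.0, seed=0)
        assert ps.class_counts == (3, 1)
        assert len(ps.spatial_patches) == 4

    def test_layouts_are_axis_permutations(self):
        conc = toy_conc()
        lab = np.zeros((16, 16, 4), np.uint8)
        lab[8, 8, 2] = 1
        ps = extract_patches(conc, VolumeMask(lab, np.ones(3)), patch_wh=8,
                             slices_per_patch=4, seed=0)
        # temporal (s_p, f, wh, wh) is the (1,0,2,3) permutation of spatial
        assert np.array_equal(
            ps.temporal_patches, np.transpose(ps.spatial_patches, (0, 2, 1, 3, 4))
        )

    def test_same_seed_same_negatives(self):
        conc = toy_conc()
        lab = np.zeros((16, 16, 4), np.uint8)
        lab[5, 5, 1] = 1
        lab[9, 9, 2] = 1
        a = extract_patches(conc, VolumeMask(lab, np.ones(3)), patch_wh=8,
                            slices_per_patch=4, seed=7)
        b = extract_patches(conc, VolumeMask(lab, np.ones(3)), patch_wh=8,
                            slices_per_patch=4, seed=7)
        assert np.array_equal(a.provenance, b.provenance)
        assert np.array_equal(a.spatial_patches, b.spatial_patches)

    def test_no_positives_rejected(self):
        conc = toy_conc()
        with pytest.raises(DegenerateInputError):
            extract_patches(conc, VolumeMask(np.zeros((16, 16, 4), np.uint8),
                                             np.ones(3)))


class TestBuildStream:
    def test_softmax_output_normalized(self):
        cfg = net_preset("desk", "spatial")
        model = build_stream(cfg, "spatial", n_frames=10, seed=0)
        x = np.random.default_rng(0).standard_normal((3, 10, 8, 8, 4)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("stream", ["spatial", "temporal"])
    def test_layer_census(self, stream):
        model = build_stream(net_preset("desk", stream), stream, n_frames=10)
        n_conv = sum(isinstance(l, Conv3D) for l in model.layers)
        n_pool = sum(isinstance(l, MaxPool3D) for l in model.layers)
        n_dense = sum(isinstance(l, Dense) for l in model.layers)
        assert n_conv == 8
        assert n_pool == 5
        assert n_dense == 3  # two hidden fc layers + the softmax output head

    def test_temporal_first_pool_preserves_frames(self):
        cfg = net_preset("full", "temporal")
        assert cfg.pool_kernels[0] == (2, 2, 1)
        assert all(k == (2, 2, 2) for k in cfg.pool_kernels[1:])

    def test_full_scale_preset_filter_ladder(self):
        cfg = net_preset("full", "spatial")
        assert cfg.conv_filters == (64, 128, 256, 256, 512, 512, 512, 512)
        assert cfg.fc_units == 4096
        assert cfg.kernel == (3, 3, 3)

    def test_desk_parameter_count_under_5m(self):
        for stream in ("spatial", "temporal"):
            model = build_stream(net_preset("desk", stream), stream, n_frames=40)
            assert model.n_params < 5_000_000

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(patch_wh=4)


class TestTrainStream:
    def test_separable_patches_reach_high_accuracy(self):
        ps = synthetic_patch_set(n=200)
        cfg = net_preset("desk", "spatial")
        model = build_stream(cfg, "spatial", n_frames=10, seed=1)
        tcfg = TrainConfig(batch=50, epochs=10, lr=1e-3, momentum=0.9, seed=0)
        train_stream(model, ps, "spatial", tcfg)
        scores = stream_forward(model, ps.spatial_patches, "spatial")
        acc = ((scores[:, 1] > 0.5).astype(int) == ps.labels).mean()
        assert acc >= 0.95

    def test_zero_lr_constant_loss(self):
        ps = synthetic_patch_set(n=40)
        model = build_stream(net_preset("desk", "spatial"), "spatial",
                             n_frames=10, seed=1)
        trace = train_stream(model, ps, "spatial",
                             TrainConfig(batch=40, epochs=4, lr=0.0, seed=0))
        assert np.allclose(trace, trace[0], atol=1e-12)

    def test_same_seed_identical_traces(self):
        ps = synthetic_patch_set(n=60)
        tcfg = TrainConfig(batch=30, epochs=3, lr=1e-3, seed=5)
        traces = []
        for _ in range(2):
            model = build_stream(net_preset("desk", "spatial"), "spatial",
                                 n_frames=10, seed=2)
            traces.append(train_stream(model, ps, "spatial", tcfg))
        assert traces[0] == traces[1]

    def test_single_class_rejected(self):
        ps = synthetic_patch_set(n=20)
        ps.labels[:] = 1
        model = build_stream(net_preset("desk", "spatial"), "spatial", n_frames=10)
        with pytest.raises(DegenerateInputError):
            train_stream(model, ps, "spatial", TrainConfig(epochs=1))


class TestFusion:
    def _scores(self, p1):
        return np.stack([1 - p1, p1], axis=1)

    def test_agreeing_streams_reproduced(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 80)
        p = np.where(labels == 1, 0.9, 0.1) + rng.uniform(-0.05, 0.05, 80)
        s = self._scores(p)
        svm = fuse_svm(s, s, labels)
        assert np.array_equal(apply_fusion(svm, s, s), labels)

    def test_linearly_separable_scores_perfect(self):
        # one stream informative, the other noise: still linearly separable
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 100)
        informative = np.where(labels == 1, 0.8, 0.2)
        noise = rng.uniform(0.3, 0.7, 100)
        svm = fuse_svm(self._scores(informative), self._scores(noise), labels)
        pred = apply_fusion(svm, self._scores(informative), self._scores(noise))
        assert np.array_equal(pred, labels)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 60)
        p1 = np.clip(np.where(labels == 1, 0.8, 0.3)
                     + rng.uniform(-0.1, 0.1, 60), 0, 1)
        p2 = np.clip(np.where(labels == 1, 0.6, 0.4)
                     + rng.uniform(-0.1, 0.1, 60), 0, 1)
        s1, s2 = self._scores(p1), self._scores(p2)
        svm_a = fuse_svm(s1, s2, labels)
        perm = rng.permutation(60)
        svm_b = fuse_svm(s1[perm], s2[perm], labels[perm])
        assert np.allclose(svm_a.coef_, svm_b.coef_, atol=1e-6)

    def test_unnormalized_scores_rejected(self):
        with pytest.raises(ValueError):
            fuse_svm(np.ones((10, 2)), np.ones((10, 2)) / 2,
                     np.arange(10) % 2)

    def test_single_class_rejected(self):
        s = self._scores(np.full(10, 0.7))
        with pytest.raises(DegenerateInputError):
            fuse_svm(s, s, np.ones(10, dtype=int))


class TestStreamInput:
    def test_channel_axis_mapping(self):
        ps = synthetic_patch_set(n=2)
        x = stream_input(ps.spatial_patches, "spatial")
        # (N, f, s_p, wh, wh) -> (N, f, wh, wh, s_p)
        assert x.shape == (2, 10, 8, 8, 4)
        xt = stream_input(ps.temporal_patches, "temporal")
        assert xt.shape == (2, 4, 8, 8, 10)


class TestModelPersistence:
    def test_save_load_round_trip(self, tmp_path):
        from perfaid.msnet import MsNetModel
        from perfaid.msnet.config import TrainConfig

        rng = np.random.default_rng(0)
        ncs = net_preset("desk", "spatial")
        nct = net_preset("desk", "temporal")
        spatial = build_stream(ncs, "spatial", n_frames=10, seed=1)
        temporal = build_stream(nct, "temporal", n_frames=10, seed=2)
        labels = rng.integers(0, 2, 40)
        p = np.clip(np.where(labels == 1, 0.8, 0.2)
                    + rng.uniform(-0.1, 0.1, 40), 0, 1)
        scores = np.stack([1 - p, p], axis=1)
        svm = fuse_svm(scores, scores, labels)
        model = MsNetModel(spatial, temporal, svm, ncs, nct,
                           TrainConfig(epochs=1), n_frames=10)
        model.save(tmp_path / "model")
        loaded = MsNetModel.load(tmp_path / "model")

        x = rng.standard_normal((4, 10, 8, 8, 4)).astype(np.float32)
        assert np.allclose(loaded.spatial.predict_proba(x),
                           model.spatial.predict_proba(x), atol=1e-7)
        assert np.array_equal(apply_fusion(loaded.fusion, scores, scores),
                              apply_fusion(model.fusion, scores, scores))
        assert loaded.net_cfg_temporal.pool_kernels[0] == (2, 2, 1)
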