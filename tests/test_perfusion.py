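import math

import numpy as np
import pytest

from perfaid.datamodel import VolumeMask
from perfaid.perfusion import (cbv_mtt_maps, deconvolve, mismatch, rcbf_map,
                               tmax_map)
from perfaid.phantom import (GammaVariateParams, convolution_matrix,
                             gamma_variate)
from perfaid.preprocess import ConcentrationSeries


def make_conc(curves: np.ndarray, dt: float = 1.5) -> ConcentrationSeries:
    v, f = curves.shape
    mask = VolumeMask(np.ones((v, 1, 1), np.uint8), np.ones(3))
    return ConcentrationSeries(curves[:, None, None, :].astype(float),
                               np.arange(f) * dt, mask, 2)


@pytest.fixture(scope="module")
def aif_40():
    t = np.arange(40) * 1.5
    return gamma_variate(t, GammaVariateParams.from_peak(60, 6, 3, 1.5))


class TestDeconvolve:
    def test_roundtrip_recovers_residue(self, aif_40):
        # oracle: forward convolution with a known residue
        rng = np.random.default_rng(0)
        dt, f = 1.5, 40
        t = np.arange(f) * dt
        a = convolution_matrix(aif_40, dt)
        curves, truths = [], []
        for _ in range(50):
            cbf = rng.uniform(0.02, 0.2)
            mtt = rng.uniform(2, 8)
            delay = rng.integers(0, 5) * dt
            sh = t - delay
            r = cbf * np.where(sh >= 0, np.exp(-np.maximum(sh, 0) / mtt), 0)
            truths.append(r)
            curves.append(a @ r)
        conc = make_conc(np.asarray(curves))
        res = deconvolve(conc, aif_40, lambda_rel=1e-6)
        rec = res.residue[:, 0, 0, :]
        truths = np.asarray(truths)
        rel = np.linalg.norm(rec - truths, axis=1) / np.linalg.norm(truths, axis=1)
        assert rel.max() <= 0.01

    def test_zero_tissue_gives_zero_residue(self, aif_40):
        conc = make_conc(np.zeros((3, 40)))
        res = deconvolve(conc, aif_40)
        assert np.allclose(res.residue, 0.0)

    def test_joint_scaling_invariance(self, aif_40):
        rng = np.random.default_rng(1)
        curves = rng.random((4, 40))
        r1 = deconvolve(make_conc(curves), aif_40, 0.1).residue
        r2 = deconvolve(make_conc(5 * curves), 5 * aif_40, 0.1).residue
        assert np.allclose(r1, r2, atol=1e-10)

    def test_all_zero_aif_rejected(self):
        with pytest.raises(ValueError):
            deconvolve(make_conc(np.ones((2, 40))), np.zeros(40))


class TestTmax:
    def test_peak_at_first_frame_gives_zero(self):
        from perfaid.perfusion import ResidueMap

        residue = np.zeros((2, 1, 1, 40))
        residue[:, 0, 0, 0] = 1.0
        residue[:, 0, 0, 1:] = 0.5
        rm = ResidueMap(residue, 1.5, VolumeMask(np.ones((2, 1, 1), np.uint8),
                                                 np.ones(3)))
        assert (tmax_map(rm) == 0.0).all()

    def test_earliest_frame_wins_ties(self):
        from perfaid.perfusion import ResidueMap

        residue = np.zeros((1, 1, 1, 10))
        residue[0, 0, 0, [3, 6]] = 2.0  # tied peaks
        rm = ResidueMap(residue, 1.5, VolumeMask(np.ones((1, 1, 1), np.uint8),
                                                 np.ones(3)))
        assert tmax_map(rm)[0, 0, 0] == pytest.approx(3 * 1.5)

    def test_shift_equivariance(self, aif_40):
        dt, f = 1.5, 40
        t = np.arange(f) * dt
        a = convolution_matrix(aif_40, dt)
        r0 = 0.1 * np.exp(-t / 4.0)
        r1 = np.roll(r0, 1)
        r1[0] = 0.0
        conc = make_conc(np.stack([a @ r0, a @ r1]))
        res = deconvolve(conc, aif_40, lambda_rel=1e-6)
        tm = tmax_map(res)
        assert tm[1, 0, 0] - tm[0, 0, 0] == pytest.approx(dt)


class TestRcbfAndCbv:
    def test_homogeneous_volume_rcbf_one(self, aif_40):
        dt = 1.5
        a = convolution_matrix(aif_40, dt)
        t = np.arange(40) * dt
        r = 0.1 * np.exp(-t / 4.0)
        conc = make_conc(np.tile(a @ r, (10, 1)))
        res = deconvolve(conc, aif_40, lambda_rel=1e-6)
        rc = rcbf_map(res)
        assert np.allclose(rc[res.brain_mask.mask > 0], 1.0, atol=0.05)

    def test_global_scaling_invariance(self, aif_40):
        rng = np.random.default_rng(2)
        dt = 1.5
        a = convolution_matrix(aif_40, dt)
        t = np.arange(40) * dt
        curves = np.stack([
            rng.uniform(0.05, 0.2) * (a @ np.exp(-t / rng.uniform(2, 6)))
            for _ in range(6)
        ])
        res1 = deconvolve(make_conc(curves), aif_40, 1e-6)
        res2 = deconvolve(make_conc(2 * curves), aif_40, 1e-6)
        assert np.allclose(rcbf_map(res1), rcbf_map(res2), atol=1e-8)

    def test_tissue_equal_to_aif_gives_unit_cbv(self, aif_40):
        conc = make_conc(np.tile(aif_40, (3, 1)))
        res = deconvolve(conc, aif_40, lambda_rel=1e-6)
        cbv, _ = cbv_mtt_maps(conc, aif_40, res)
        assert np.allclose(cbv[conc.brain_mask.mask > 0], 1.0, atol=1e-9)

    def test_zero_tissue_zero_cbv_mtt(self, aif_40):
        conc = make_conc(np.zeros((2, 40)))
        res = deconvolve(conc, aif_40)
        cbv, mtt = cbv_mtt_maps(conc, aif_40, res)
        assert np.allclose(cbv, 0.0) and np.allclose(mtt, 0.0)


@pytest.fixture(scope="module")
def residue(noiseless_case, noiseless_conc):
    return deconvolve(noiseless_conc, noiseless_case.aif_truth, lambda_rel=1e-6)


class TestPhantomMapRecovery:
    def _tissue(self, case):
        return (case.brain_mask.mask > 0) & ~(case.vessel_truth.mask > 0)

    def test_tmax_recovers_delay_within_one_frame(self, noiseless_case, residue):
        tm = tmax_map(residue)
        tis = self._tissue(noiseless_case)
        assert np.abs(tm[tis] - noiseless_case.delay_map[tis]).max() <= residue.dt_s

    def test_cbf_bias_within_five_percent(self, noiseless_case, residue):
        tis = self._tissue(noiseless_case)
        cbf = residue.residue.max(axis=3)
        bias = np.abs(cbf[tis] - noiseless_case.cbf_map[tis]) / noiseless_case.cbf_map[tis]
        assert bias.max() <= 0.05

    def test_mtt_within_ten_percent(self, noiseless_case, noiseless_conc, residue):
        tis = self._tissue(noiseless_case)
        _, mtt = cbv_mtt_maps(noiseless_conc, noiseless_case.aif_truth, residue)
        rel = np.abs(mtt[tis] - noiseless_case.mtt_map[tis]) / noiseless_case.mtt_map[tis]
        assert np.median(rel) <= 0.10

    def test_lesion_rcbf_contrast(self, noiseless_case, residue):
        rc = rcbf_map(residue)
        tis = self._tissue(noiseless_case)
        lesion = tis & (noiseless_case.cbf_map
                        < 0.5 * np.median(noiseless_case.cbf_map[tis]))
        healthy = tis & ~lesion
        ratio = np.median(rc[lesion]) / np.median(rc[healthy])
        assert ratio == pytest.approx(0.40, abs=0.05)


class TestMismatch:
    def test_hand_computed_volumes(self):
        tmax = np.zeros((10, 10, 10))
        adc = np.full((10, 10, 10), 800.0)
        tmax.ravel()[:100] = 10.0     # 100 ischemic voxels
        adc.ravel()[:20] = 500.0      # 20 core voxels
        rep = mismatch(tmax, adc, voxel_mm=(1.0, 1.0, 1.0))
        assert rep.ischemic_volume_ml == pytest.approx(0.1)
        assert rep.core_volume_ml == pytest.approx(0.02)
        assert rep.mismatch_volume_ml == pytest.approx(0.08)
        assert rep.mismatch_ratio == pytest.approx(4.0)

    def test_empty_core_infinite_ratio(self):
        tmax = np.zeros((5, 5, 2))
        tmax[0, 0, 0] = 8.0
        adc = np.full((5, 5, 2), 800.0)
        rep = mismatch(tmax, adc, voxel_mm=(1.0, 1.0, 1.0))
        assert rep.ratio_infinite
        assert rep.mismatch_ratio == math.inf
        assert rep.mismatch_volume_ml == pytest.approx(rep.ischemic_volume_ml)

    def test_no_ischemia_undefined_ratio(self):
        tmax = np.zeros((5, 5, 2))
        adc = np.full((5, 5, 2), 800.0)
        rep = mismatch(tmax, adc, voxel_mm=(1.0, 1.0, 1.0))
        assert rep.ratio_undefined
        assert rep.ischemic_volume_ml == 0.0

    def test_voxel_order_invariance_and_additivity(self):
        rng = np.random.default_rng(5)
        tmax = rng.uniform(0, 12, (8, 8, 4))
        adc = rng.uniform(400, 900, (8, 8, 4))
        rep = mismatch(tmax, adc, voxel_mm=(1, 1, 1))
        perm = rng.permutation(tmax.size)
        rep_p = mismatch(tmax.ravel()[perm].reshape(tmax.shape),
                         adc.ravel()[perm].reshape(adc.shape), voxel_mm=(1, 1, 1))
        assert rep_p.ischemic_volume_ml == rep.ischemic_volume_ml
        assert rep_p.core_volume_ml == rep.core_volume_ml
        # additivity over a disjoint split
        half = np.zeros(tmax.shape, bool)
        half[:4] = True
        r1 = mismatch(tmax, adc, (1, 1, 1), mask=half)
        r2 = mismatch(tmax, adc, (1, 1, 1), mask=~half)
        assert r1.ischemic_volume_ml + r2.ischemic_volume_ml == pytest.approx(
            rep.ischemic_volume_ml)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mismatch(np.zeros((4, 4, 2)), np.zeros((4, 4, 3)), (1, 1, 1))

    def test_set_difference_mode(self):
        tmax = np.zeros((4, 4, 1))
        adc = np.full((4, 4, 1), 800.0)
        tmax[0, :2, 0] = 8.0          # 2 ischemic
        adc[1, 0, 0] = 500.0          # 1 core, disjoint from ischemic
        literal = mismatch(tmax, adc, (1, 1, 1))
        setdiff = mismatch(tmax, adc, (1, 1, 1), set_difference=True)
        assert literal.mismatch_volume_ml == pytest.approx(0.001)
        assert setdiff.mismatch_volume_ml == pytest.approx(0.002)
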