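"""Gamma analysis, Dice, IDD/R80 metrics, mask discrepancy, MCD, RBE dose."""

import numpy as np
import pytest

from ciondose.evaluation import (GammaParams, dice_isodose, evaluate_beamlet,
                                 gamma_pass_rate, idd, idd_metrics,
                                 mask_discrepancy, mcd_summary, r80,
                                 rbe_weighted_dose, rmse_3d_percent,
                                 summarize_gpr)
from ciondose.preprocess import MaskVolume, threshold_mask

from gamma_oracle import gamma_bruteforce_voxel, gamma_dense_interpolated

PARAMS_1_1 = GammaParams(dose_criterion=0.01, distance_criterion=1.0,
                         low_dose_threshold=0.10, search_radius=3.0,
                         interp_step=0.25)


def random_beamlet_like(seed, shape=(12, 12, 24)):
    """A smooth random positive volume with a dose-like hot region."""
    r = np.random.default_rng(seed)
    x = r.uniform(0, 1, shape)
    from scipy import ndimage
    x = ndimage.gaussian_filter(x, 1.5)
    x[shape[0] // 2, shape[1] // 2, shape[2] // 2] = x.max() * 3
    return ndimage.gaussian_filter(x, 1.0)


class TestGammaIdentities:
    def test_identical_volumes_pass_everywhere(self):
        v = random_beamlet_like(0)
        g, gmap = gamma_pass_rate(v, v.copy(), PARAMS_1_1, mode="voxel")
        assert g == 100.0
        assert np.nanmax(gmap) == 0.0

    def test_uniform_two_percent_offset_fails_everywhere(self):
        ref = np.ones((8, 8, 8))
        evl = np.full((8, 8, 8), 1.02)
        g, gmap = gamma_pass_rate(ref, evl, PARAMS_1_1, mode="voxel")
        assert g == 0.0
        # no spatial gradient can rescue: gamma = 2 everywhere
        assert np.nanmin(gmap) == pytest.approx(2.0)

    def test_one_voxel_shift_passes_at_gamma_one(self):
        ref = np.zeros((7, 7, 30))
        ref[3, 3, :] = np.linspace(1, 2, 30)
        evl = np.zeros_like(ref)
        evl[4, 3, :] = ref[3, 3, :]  # same column shifted by exactly 1 mm
        g, gmap = gamma_pass_rate(ref, evl, PARAMS_1_1, mode="voxel")
        assert g == 100.0
        assert np.nanmax(gmap) == pytest.approx(1.0)

    def test_scale_invariance(self):
        ref = random_beamlet_like(1)
        evl = random_beamlet_like(2)
        g1, _ = gamma_pass_rate(ref, evl, PARAMS_1_1, mode="voxel")
        g2, _ = gamma_pass_rate(7.3 * ref, 7.3 * evl, PARAMS_1_1, mode="voxel")
        assert g1 == pytest.approx(g2)

    def test_interpolation_never_hurts(self):
        ref = random_beamlet_like(3)
        evl = ref * (1 + 0.015 * np.sin(np.arange(ref.size).reshape(ref.shape)))
        gv, _ = gamma_pass_rate(ref, evl, PARAMS_1_1, mode="voxel")
        gi, _ = gamma_pass_rate(ref, evl, PARAMS_1_1, mode="interpolated")
        assert gi >= gv

    def test_empty_evaluated_set_returns_none(self):
        ref = np.ones((4, 4, 4))
        scope = MaskVolume(mask=np.zeros((4, 4, 4), dtype=bool), source="AI")
        g, _ = gamma_pass_rate(ref, ref, PARAMS_1_1, scope_mask=scope,
                               mode="voxel")
        assert g is None

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gamma_pass_rate(np.ones((4, 4, 4)), np.ones((4, 4, 5)), PARAMS_1_1)


class TestGammaOracle:
    def test_voxel_mode_matches_bruteforce_exactly(self):
        """Per-voxel pass/fail agreement with the nested-loop oracle."""
        for seed in range(8):
            r = np.random.default_rng(seed)
            ref = random_beamlet_like(seed, (10, 10, 14))
            evl = ref * r.uniform(0.97, 1.03, ref.shape)
            g, gmap = gamma_pass_rate(ref, evl, PARAMS_1_1, mode="voxel")
            go, omap = gamma_bruteforce_voxel(ref, evl, 0.01, 1.0, 0.10, 3.0)
            assert g == pytest.approx(go)
            ours = gmap[np.isfinite(gmap)] <= 1.0 + 1e-9
            theirs = omap[np.isfinite(omap)] <= 1.0 + 2e-9
            np.testing.assert_array_equal(ours, theirs)

    def test_interpolated_mode_close_to_dense_oracle(self):
        for seed in (0, 1):
            r = np.random.default_rng(seed + 50)
            ref = random_beamlet_like(seed + 50, (10, 10, 16))
            evl = ref * r.uniform(0.98, 1.02, ref.shape)
            gi, _ = gamma_pass_rate(ref, evl, PARAMS_1_1, mode="interpolated")
            go = gamma_dense_interpolated(ref, evl, 0.01, 1.0, 0.10, 3.0, 0.25)
            assert abs(gi - go) <= 0.5


class TestDice:
    def test_identity(self):
        v = random_beamlet_like(4)
        d, n = dice_isodose(v, v.copy(), 0.30)
        assert d == 1.0 and n > 0

    def test_disjoint_sets(self):
        a = np.zeros((4, 4, 4)); a[0, 0, 0] = 1.0
        b = np.zeros((4, 4, 4)); b[3, 3, 3] = 1.0
        d, _ = dice_isodose(a, b, 0.70)
        assert d == 0.0

    def test_formula_arithmetic(self):
        a = np.zeros((4, 4, 4)); b = np.zeros((4, 4, 4))
        a[0, 0, :4] = 1.0            # |A| = 4
        b[0, 0, 2:4] = 1.0; b[1, 1, :2] = 1.0  # |B| = 4, overlap 2
        d, n = dice_isodose(a, b, 0.5)
        assert d == pytest.approx(0.5) and n == 4


class TestIddAndR80:
    def test_conservation_to_roundoff(self, water_beamlet):
        v = water_beamlet["dose"].values
        assert idd(v).sum() == pytest.approx(v.sum(dtype=np.float64), rel=1e-9)

    def test_delta_beam_profile(self):
        v = np.zeros((5, 5, 10))
        series = np.arange(1.0, 11.0)
        v[2, 3, :] = series
        np.testing.assert_allclose(idd(v), series)

    def test_lateral_widening_preserves_idd(self, water_ct):
        from ciondose.beamlets import BeamletSpec, generate_ground_truth
        d1, _, _ = generate_ground_truth(water_ct, BeamletSpec(energy=150.0, fwhm0=3.0))
        d2, _, _ = generate_ground_truth(water_ct, BeamletSpec(energy=150.0, fwhm0=6.0))
        p1, p2 = idd(d1.values), idd(d2.values)
        contained = np.arange(300) < 120
        np.testing.assert_allclose(p1[contained], p2[contained], rtol=0.01)

    def test_r80_toy_profile(self):
        assert r80(np.array([0.0, 50.0, 100.0, 50.0, 0.0])) == pytest.approx(2.4)

    def test_r80_scale_invariant(self):
        p = np.array([0.0, 50.0, 100.0, 50.0, 0.0])
        assert r80(p) == r80(13.7 * p)

    def test_r80_increases_with_energy(self, water_ct):
        from ciondose.beamlets import BeamletSpec, generate_ground_truth
        vals = []
        for e in (130.0, 180.0, 230.0):
            d, _, _ = generate_ground_truth(water_ct, BeamletSpec(energy=e))
            vals.append(r80(idd(d.values)))
        assert vals[0] < vals[1] < vals[2]

    def test_r80_validation(self):
        with pytest.raises(ValueError):
            r80(np.array([1.0]))
        with pytest.raises(ValueError):
            r80(np.zeros(5))


class TestIddMetrics:
    def test_identical_profiles_all_zero(self):
        p = np.array([1.0, 3.0, 9.0, 4.0, 0.5])
        assert idd_metrics(p, p.copy()) == (0.0, 0.0, 0.0)

    def test_uniform_scaling_gives_dmax(self):
        p = np.array([1.0, 3.0, 9.0, 4.0, 0.5])
        d_r80, d_dmax, _ = idd_metrics(p, 1.1 * p)
        assert d_dmax == pytest.approx(10.0)
        assert d_r80 == pytest.approx(0.0, abs=1e-9)

    def test_hand_built_profiles(self):
        ref = np.array([0.0, 50.0, 100.0, 50.0, 0.0])
        evl = np.array([0.0, 40.0, 90.0, 60.0, 0.0])
        d_r80, d_dmax, rmse = idd_metrics(ref, evl)
        # eval R80: level 72; distal crossing between 2 (90) and 3 (60):
        # 2 + (90-72)/(90-60) = 2.6 -> delta = 0.2
        assert d_r80 == pytest.approx(2.6 - 2.4)
        assert d_dmax == pytest.approx(-10.0)
        expected_rmse = 100 * np.sqrt(np.mean([0, 100, 100, 100, 0])) / 100.0
        assert rmse == pytest.approx(expected_rmse)

    def test_rmse_3d(self):
        ref = np.full((3, 3, 3), 2.0)
        evl = ref + 0.2
        assert rmse_3d_percent(ref, evl) == pytest.approx(10.0)


class TestMaskDiscrepancy:
    def test_identical_masks_zero(self):
        m = np.zeros((5, 5, 5), dtype=bool); m[1:4, 1:4, 1:4] = True
        mc = MaskVolume(mask=m, source="MC")
        ai = MaskVolume(mask=m.copy(), source="AI")
        lost, lm, ls, gained = mask_discrepancy(mc, ai, np.ones((5, 5, 5)))
        assert lost == 0.0 and gained == 0.0 and lm == 0.0 and ls == 0.0

    def test_eight_percent_lost(self):
        m = np.zeros(100, dtype=bool).reshape(4, 5, 5)
        m[:] = True  # 100 voxels in MC mask
        ai = m.copy()
        ai.flat[:8] = False  # 8 voxels lost
        dose = np.full((4, 5, 5), 0.02)
        lost, lm, _, gained = mask_discrepancy(
            MaskVolume(mask=m, source="MC"), MaskVolume(mask=ai, source="AI"),
            dose)
        assert lost == pytest.approx(0.08)
        assert lm == pytest.approx(0.02)
        assert gained == 0.0

    def test_lost_and_gained_disjoint(self):
        r = np.random.default_rng(0)
        mc = MaskVolume(mask=r.random((6, 6, 6)) > 0.4, source="MC")
        ai = MaskVolume(mask=r.random((6, 6, 6)) > 0.4, source="AI")
        lost, _, _, gained = mask_discrepancy(mc, ai, np.ones((6, 6, 6)))
        n_mc = mc.mask.sum()
        both = (mc.mask & ~ai.mask) & (ai.mask & ~mc.mask)
        assert not both.any()
        assert 0 <= lost <= 1 and gained >= 0

    def test_empty_mc_mask_flagged(self):
        with pytest.raises(ValueError):
            mask_discrepancy(
                MaskVolume(mask=np.zeros((2, 2, 2), bool), source="MC"),
                MaskVolume(mask=np.ones((2, 2, 2), bool), source="AI"),
                np.ones((2, 2, 2)))


class TestMcdSummary:
    def test_identical_runs_zero_std(self):
        v = random_beamlet_like(5)
        runs = [(v.copy(), v.copy(), v.copy()) for _ in range(5)]
        s = mcd_summary(runs, ref={"dose": v}, params=PARAMS_1_1)
        np.testing.assert_allclose(s.std["dose"], 0.0, atol=1e-12)
        assert s.gpr_std["dose"] == 0.0
        assert len(s.gpr_runs["dose"]) == 5

    def test_symmetric_perturbation_mean(self):
        v = random_beamlet_like(6)
        eps = 0.01 * v
        runs = [(v + eps, v, v), (v - eps, v, v)]
        s = mcd_summary(runs, ref={"dose": v}, params=PARAMS_1_1)
        np.testing.assert_allclose(s.mean["dose"], v, rtol=1e-6)

    def test_run_count_preserved(self):
        v = random_beamlet_like(7)
        r = np.random.default_rng(0)
        runs = [(v * r.uniform(0.99, 1.01), v, v) for _ in range(30)]
        s = mcd_summary(runs, ref={"dose": v}, params=PARAMS_1_1)
        assert len(s.gpr_runs["dose"]) == 30

    def test_too_few_runs_rejected(self):
        v = random_beamlet_like(8)
        with pytest.raises(ValueError):
            mcd_summary([(v, v, v)], ref={"dose": v})


class TestRbeWeightedDose:
    def test_zero_dose_gives_zero(self):
        d = np.zeros((3, 3, 3))
        out = rbe_weighted_dose(d, np.ones_like(d), np.ones_like(d), 0.1, 0.05)
        np.testing.assert_array_equal(out, 0.0)

    def test_photon_self_consistency(self):
        d = np.linspace(0, 5, 20)
        out = rbe_weighted_dose(d, np.full_like(d, 0.1), np.full_like(d, 0.05),
                                0.1, 0.05)
        np.testing.assert_allclose(out, d, atol=1e-12)

    def test_hand_example(self):
        out = rbe_weighted_dose(np.array(2.0), np.array(0.5), np.array(0.05),
                                alpha_x=0.1, beta_x=0.05)
        assert out == pytest.approx(4.0)

    def test_monotone_in_dose(self):
        d = np.linspace(0, 5, 50)
        out = rbe_weighted_dose(d, np.full_like(d, 0.5), np.full_like(d, 0.05),
                                0.1, 0.05)
        assert np.all(np.diff(out) > 0)

    def test_invalid_beta_x(self):
        with pytest.raises(ValueError):
            rbe_weighted_dose(np.ones(3), np.ones(3), np.ones(3), 0.1, 0.0)


class TestEvaluateBeamlet:
    def test_full_report_on_perturbed_ground_truth(self, water_beamlet):
        gt = {"dose": water_beamlet["dose"].values[12:36, 12:36, :240],
              "alpha": water_beamlet["alpha"].values[12:36, 12:36, :240],
              "beta": water_beamlet["beta"].values[12:36, 12:36, :240]}
        r = np.random.default_rng(0)
        pred = {k: v * r.uniform(0.995, 1.005, v.shape) for k, v in gt.items()}
        rep = evaluate_beamlet(gt, pred, PARAMS_1_1, mode="voxel")
        for q in ("dose", "alpha", "beta"):
            assert rep.gpr_percent[q] > 95.0
        for lv in (0.01, 0.30, 0.70):
            assert rep.dice[lv] > 0.9
        assert abs(rep.delta_r80_mm) < 1.0
        assert rep.lost_voxel_fraction < 0.2

    def test_summarize_gpr_percentiles(self):
        vals = list(np.arange(1.0, 101.0))
        s = summarize_gpr(vals)
        assert s["median"] == pytest.approx(50.5)
        assert s["min"] == 1.0 and s["max"] == 100.0
        assert s["p10"] == pytest.approx(np.percentile(vals, 10))
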