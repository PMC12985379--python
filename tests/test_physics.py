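"""Unit and property tests for the analytic beamlet physics surrogate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciondose import physics
from ciondose.beamlets import water_equivalent_depth
from ciondose.grids import CTVolume


class TestHuToRsp:
    def test_water_is_unity(self):
        assert physics.hu_to_rsp(0.0) == 1.0

    def test_air_nearly_stops_nothing(self):
        assert physics.hu_to_rsp(-1000.0) == pytest.approx(0.001)

    def test_monotone_over_full_range(self):
        hu = np.linspace(-1000, 3000, 500)
        rsp = physics.hu_to_rsp(hu)
        assert np.all(np.diff(rsp) >= 0)


class TestWaterEquivalentDepth:
    def test_water_column_is_identity(self, water_ct):
        wed = water_equivalent_depth(water_ct)
        # WED at the distal face of voxel k is k+1 mm
        np.testing.assert_allclose(wed, np.arange(1, 301), atol=1e-9)

    def test_air_column_nearly_zero(self):
        ct = CTVolume(hu=np.full((4, 4, 400), -1000.0))
        wed = water_equivalent_depth(ct)
        assert wed[-1] <= 0.01 * 400

    def test_water_plus_bone_hand_sum(self):
        # 10 mm water then 10 mm of HU giving RSP exactly 1.5
        hu_bone = 1000.0 * (0.5 / 0.55)
        col = np.concatenate([np.zeros(10), np.full(10, hu_bone)])
        ct = CTVolume(hu=np.tile(col, (4, 4, 1)))
        wed = water_equivalent_depth(ct)
        assert wed[19] == pytest.approx(25.0, abs=1e-6)

    def test_non_decreasing(self, mixed_beamlet):
        wed = water_equivalent_depth(mixed_beamlet["ct"])
        assert np.all(np.diff(wed) >= 0)


class TestDepthDoseCurve:
    def test_single_global_bragg_peak(self):
        wed, idd = physics.depth_dose_curve(180.0)
        k = int(np.argmax(idd))
        assert 0 < k < len(idd) - 1
        # unimodal up to the peak region, dropping after
        assert idd[0] < idd[k]
        assert idd[-1] < 0.2 * idd[k]

    def test_peak_to_entrance_ratio(self):
        for e in (115.0, 180.0, 260.0):
            _, idd = physics.depth_dose_curve(e)
            assert idd.max() / idd[0] >= 3.0

    def test_fragment_tail_below_15_percent(self):
        wed, idd = physics.depth_dose_curve(200.0)
        r = physics.range_from_energy(200.0)
        tail = idd[wed > r + physics.PRIMARY_CUTOFF_MM]
        assert tail.max() <= 0.15 * idd.max()

    def test_peak_position_increases_with_energy(self):
        energies = np.linspace(115, 260, 30)
        peaks = []
        for e in energies:
            wed, idd = physics.depth_dose_curve(float(e))
            peaks.append(wed[np.argmax(idd)])
        assert np.all(np.diff(peaks) > 0)

    def test_momentum_spread_widens_peak(self):
        wed = np.arange(0.0, 120.0, 0.05)
        widths = []
        for ms in (0.005, 0.02):
            _, idd = physics.depth_dose_curve(180.0, momentum_spread=ms, wed=wed)
            above = wed[idd >= 0.8 * idd.max()]
            widths.append(above.max() - above.min())
        assert widths[1] > widths[0]

    def test_energy_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            physics.depth_dose_curve(100.0)
        with pytest.raises(ValueError):
            physics.depth_dose_curve(300.0)


class TestLateralSigma:
    def test_entrance_value_is_sigma0(self):
        fwhm0 = 7.05
        assert physics.lateral_sigma(0.0, fwhm0) == pytest.approx(
            fwhm0 / 2.3548, rel=1e-3)

    def test_hand_value_at_100mm(self):
        # sigma0 = 7.05 / 2.355 ~= 3.0; k z = 2.0 -> sigma = sqrt(13)
        s = physics.lateral_sigma(100.0, 7.05, k=0.02)
        assert s == pytest.approx(np.sqrt(3.0**2 + 2.0**2), abs=0.01)

    def test_monotone_in_depth(self):
        z = np.linspace(0, 300, 100)
        s = physics.lateral_sigma(z, 6.0)
        assert np.all(np.diff(s) >= 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            physics.lateral_sigma(10.0, 0.0)
        with pytest.raises(ValueError):
            physics.lateral_sigma(-1.0, 5.0)


class TestSpeciesProfiles:
    def test_primary_zero_beyond_cutoff_fragments_alive(self):
        e = 180.0
        r = physics.range_from_energy(e)
        wed = np.array([r + physics.PRIMARY_CUTOFF_MM + 1e-6, r + 10.0])
        sp = physics.species_idd(wed, e)
        assert np.all(sp[0] == 0.0)          # primary
        assert np.all(sp[1:] > 0.0)          # fragments

    def test_species_sum_equals_total(self):
        wed = np.arange(0.0, 100.0, 1.0)
        sp = physics.species_idd(wed, 200.0)
        _, total = physics.depth_dose_curve(200.0, wed=wed)
        np.testing.assert_allclose(sp.sum(axis=0), total, rtol=1e-12)

    def test_alpha_rises_toward_peak(self):
        e = 180.0
        r = physics.range_from_energy(e)
        alpha, beta = physics.species_alpha_beta(np.array([0.0, r]), e)
        assert alpha[0, 1] > alpha[0, 0]     # primary alpha: peak > entrance
        assert np.all(alpha >= 0) and np.all(beta >= 0)


class TestMixAlphaBeta:
    def test_single_species_identity(self):
        a, b = physics.mix_alpha_beta(
            np.array([2.0]), np.array([0.5]), np.array([0.04]))
        assert a == pytest.approx(0.5) and b == pytest.approx(0.04)

    def test_equal_dose_mean(self):
        a, _ = physics.mix_alpha_beta(
            np.array([1.0, 1.0]), np.array([0.4, 0.8]), np.array([0.01, 0.01]))
        assert a == pytest.approx(0.6)

    def test_sqrt_beta_worked_example(self):
        # sqrt(beta)_mix = (3*0.2 + 1*0) / 4 = 0.15 -> beta = 0.0225
        _, b = physics.mix_alpha_beta(
            np.array([3.0, 1.0]), np.array([0.5, 0.5]), np.array([0.04, 0.0]))
        assert b == pytest.approx(0.0225)

    def test_beta_convention_switch(self):
        dose = np.array([3.0, 1.0])
        beta = np.array([0.04, 0.0])
        _, b_direct = physics.mix_alpha_beta(
            dose, np.array([0.5, 0.5]), beta, convention="beta")
        assert b_direct == pytest.approx(0.03)  # (3*0.04 + 0)/4

    def test_zero_dose_flagged_undefined(self):
        a, b = physics.mix_alpha_beta(
            np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]]),
            np.array([[0.02, 0.02]]))
        assert np.isfinite(a[0]) and np.isnan(a[1]) and np.isnan(b[1])

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            physics.mix_alpha_beta(np.array([1.0]), np.array([0.5]),
                                   np.array([0.02]), convention="geometric")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_convexity_of_mixture(self, seed):
        """Mixed alpha (and sqrt-beta) lie in the species convex hull."""
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 9))
        dose = r.uniform(0.0, 5.0, n)
        dose[int(r.integers(0, n))] += 0.1  # ensure positive total
        alpha = r.uniform(0.0, 2.0, n)
        beta = r.uniform(0.0, 0.06, n)
        am, bm = physics.mix_alpha_beta(dose, alpha, beta)
        assert alpha.min() - 1e-12 <= am <= alpha.max() + 1e-12
        sb = np.sqrt(beta)
        assert sb.min() - 1e-12 <= np.sqrt(bm) <= sb.max() + 1e-12
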