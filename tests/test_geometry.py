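"""Ensemble geometry: R_g, distance maps, chain nulls, Debye/Guinier/Kratky."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from idpbind.exceptions import InputError, ParameterError
from idpbind.geometry import (
    AnalyticalFloryCoil,
    ConformationalEnsemble,
    NullChainModel,
    ScatteringProfile,
    afrc_reference,
    debye_scattering,
    dimensionless_kratky,
    frc_mean_square_distance,
    guinier_fit,
    mean_distance_map,
    normalized_distance_map,
    radius_of_gyration,
    rg_density,
)


def gaussian_chain_debye(q, rg, n_beads):
    """Closed-form Debye function of an ideal Gaussian chain."""
    x = (q * rg) ** 2
    return n_beads**2 * 2.0 * (np.exp(-x) - 1.0 + x) / x**2


class TestRadiusOfGyration:
    def test_point_mass_has_zero_rg(self):
        ens = ConformationalEnsemble(np.zeros((1, 1, 3)))
        assert radius_of_gyration(ens).mean == 0.0

    def test_symmetric_dimer(self):
        ens = ConformationalEnsemble(np.array([[[0, 0, 0], [10, 0, 0]]], float))
        assert radius_of_gyration(ens).mean == pytest.approx(5.0)

    def test_right_triangle_of_equal_masses(self):
        # pair-sum identity: Rg² = (9 + 16 + 25)/3² = 50/9
        ens = ConformationalEnsemble(
            np.array([[[0, 0, 0], [3, 0, 0], [0, 4, 0]]], float))
        assert radius_of_gyration(ens).mean == pytest.approx(np.sqrt(50 / 9))

    def test_mass_weighting_shifts_rg(self):
        coords = np.array([[[0, 0, 0], [10, 0, 0]]], float)
        heavy = ConformationalEnsemble(coords.copy(), masses=[3.0, 1.0])
        assert radius_of_gyration(heavy).mean == pytest.approx(
            np.sqrt(0.75 * 2.5**2 + 0.25 * 7.5**2))

    def test_rigid_motion_invariance(self, frc_ensemble_small, rng):
        ref = radius_of_gyration(frc_ensemble_small).per_frame
        rot = Rotation.random(rng=123).as_matrix()
        moved = ConformationalEnsemble(
            frc_ensemble_small.coords @ rot.T + np.array([5.0, -3.0, 11.0]))
        np.testing.assert_allclose(radius_of_gyration(moved).per_frame, ref,
                                   rtol=1e-10)


class TestDistanceMaps:
    def test_single_frame_collinear_beads(self):
        ens = ConformationalEnsemble(
            np.array([[[0, 0, 0], [5, 0, 0], [10, 0, 0]]], float))
        m = mean_distance_map(ens)
        assert m[0, 1] == pytest.approx(5.0)
        assert m[0, 2] == pytest.approx(10.0)
        np.testing.assert_allclose(np.diag(m), 0.0)
        np.testing.assert_allclose(m, m.T)

    def test_frame_averaging_is_arithmetic_mean(self):
        frames = np.array([[[0, 0, 0], [4, 0, 0]], [[0, 0, 0], [6, 0, 0]]], float)
        m = mean_distance_map(ConformationalEnsemble(frames))
        assert m[0, 1] == pytest.approx(5.0)

    def test_self_normalization_is_identity(self, frc_ensemble_small):
        m = mean_distance_map(frc_ensemble_small)
        n = m.shape[0]
        # null indexed by separation: use the map's own mean per separation
        sep_mean = np.array(
            [1.0] + [np.mean([m[i, i + k] for i in range(n - k)])
                     for k in range(1, n)])
        ratio = normalized_distance_map(m, sep_mean)
        for k in range(1, n):
            vals = [ratio[i, i + k] for i in range(n - k)]
            assert np.mean(vals) == pytest.approx(1.0, rel=1e-10)

    def test_uniform_compaction_scales_ratio(self):
        m = np.array([[0.0, 4.0], [4.0, 0.0]])
        out = normalized_distance_map(0.5 * m, np.array([1.0, 4.0]))
        assert out[0, 1] == pytest.approx(0.5)
        assert out[0, 0] == 1.0


class TestFreelyRotatingChain:
    def test_single_bond_is_bond_length_squared(self):
        assert frc_mean_square_distance(1) == pytest.approx(3.8**2)

    def test_ten_bond_closed_form(self):
        assert frc_mean_square_distance(10) == pytest.approx(784.0, abs=0.1)

    def test_long_chain_flory_ratio(self):
        model = NullChainModel()
        r2 = frc_mean_square_distance(10**6, model)
        assert r2 / (10**6 * model.l**2) == pytest.approx(9.0, rel=1e-5)

    def test_invalid_separation_rejected(self):
        with pytest.raises(ParameterError):
            frc_mean_square_distance(0)

    def test_sampled_chains_match_closed_form(self, frc_ensemble_small):
        coords = frc_ensemble_small.coords
        for sep in (5, 20, 50):
            d2 = ((coords[:, sep] - coords[:, 0]) ** 2).sum(axis=1)
            sem = d2.std(ddof=1) / np.sqrt(len(d2))
            assert abs(d2.mean() - frc_mean_square_distance(sep)) < 3 * sem


class TestAnalyticalFloryCoil:
    def test_mean_rg_for_68mer_matches_random_coil_expectation(self):
        assert afrc_reference(68).mean_rg() == pytest.approx(20.8, rel=0.01)

    def test_distance_zero_at_zero_separation(self):
        coil = AnalyticalFloryCoil(68)
        assert coil.mean_distance(0) == 0.0

    def test_expected_distance_strictly_increasing(self):
        prof = afrc_reference(68).distance_profile("rms")
        assert np.all(np.diff(prof) > 0)

    def test_mean_distance_below_rms(self):
        coil = afrc_reference(30)
        n = np.arange(1, 30)
        assert np.all(coil.mean_distance(n) < coil.rms_distance(n))

    def test_too_short_chain_rejected(self):
        with pytest.raises(ParameterError):
            afrc_reference(1)


class TestDebyeScattering:
    q = np.linspace(0.01, 0.5, 40)

    def test_single_bead_scatters_flat(self):
        ens = ConformationalEnsemble(np.zeros((1, 1, 3)))
        prof = debye_scattering(ens, self.q)
        np.testing.assert_allclose(prof.intensity, 1.0)

    def test_two_bead_closed_form(self):
        d = 12.0
        ens = ConformationalEnsemble(np.array([[[0, 0, 0], [d, 0, 0]]], float))
        prof = debye_scattering(ens, self.q)
        expected = 2.0 + 2.0 * np.sin(self.q * d) / (self.q * d)
        np.testing.assert_allclose(prof.intensity, expected, rtol=1e-10)

    def test_forward_limit_is_bead_count_squared(self, frc_ensemble_small):
        sub = ConformationalEnsemble(frc_ensemble_small.coords[:50])
        prof = debye_scattering(sub, np.array([1e-6]))
        assert prof.intensity[0] == pytest.approx(sub.n_beads**2, rel=1e-6)

    def test_nonpositive_q_rejected(self):
        ens = ConformationalEnsemble(np.zeros((1, 1, 3)))
        with pytest.raises(ParameterError):
            debye_scattering(ens, np.array([0.0, 0.1]))


class TestGuinier:
    def test_exact_guinier_profile_recovered(self):
        rg, i0 = 25.0, 1000.0
        q = np.linspace(0.002, 0.2, 100)
        prof = ScatteringProfile(q, i0 * np.exp(-(q * rg) ** 2 / 3.0))
        res = guinier_fit(prof)
        assert res.success
        assert res.rg == pytest.approx(rg, rel=1e-6)
        assert res.i0 == pytest.approx(i0, rel=1e-6)
        assert res.q_max * res.rg <= 1.1 + 1e-9

    def test_gaussian_chain_debye_profile_within_two_percent(self):
        rg = 25.0
        q = np.linspace(0.002, 0.2, 200)
        prof = ScatteringProfile(q, gaussian_chain_debye(q, rg, 68))
        res = guinier_fit(prof, qrg_limit=0.65)
        assert res.success
        assert res.rg == pytest.approx(rg, rel=0.02)

    def test_rising_intensity_flags_failure(self):
        q = np.linspace(0.01, 0.2, 30)
        res = guinier_fit(ScatteringProfile(q, 1.0 + q**2))
        assert not res.success

    def test_ensemble_round_trip_recovers_rms_rg(self, frc_ensemble_small):
        sub = ConformationalEnsemble(frc_ensemble_small.coords[:400])
        rms_rg = float(np.sqrt((radius_of_gyration(sub).per_frame ** 2).mean()))
        q = np.linspace(0.003, 0.08, 60)
        res = guinier_fit(debye_scattering(sub, q), qrg_limit=0.65)
        assert res.success
        assert res.rg == pytest.approx(rms_rg, rel=0.03)


class TestKratky:
    def test_low_q_ordinate_vanishes(self):
        rg = 20.0
        q = np.linspace(0.001, 0.3, 300)
        prof = ScatteringProfile(q, gaussian_chain_debye(q, rg, 50))
        x, y = dimensionless_kratky(prof, guinier_fit(prof, qrg_limit=0.65))
        assert y[0] == pytest.approx(0.0, abs=1e-3)

    def test_ideal_chain_plateau_approaches_two(self):
        rg = 20.0
        q = np.linspace(0.001, 0.5, 500)
        prof = ScatteringProfile(q, gaussian_chain_debye(q, rg, 50))
        x, y = dimensionless_kratky(prof, guinier_fit(prof, qrg_limit=0.65))
        assert y[x > 8].mean() == pytest.approx(2.0, rel=0.05)

    def test_globule_peaks_then_decays_while_coil_plateaus(self):
        rg = 20.0
        q = np.linspace(0.001, 0.5, 500)
        coil = ScatteringProfile(q, gaussian_chain_debye(q, rg, 50))
        # rigid-sphere-like: sharp Gaussian decay of scattering
        globule = ScatteringProfile(q, 2500 * np.exp(-(q * rg) ** 2 / 3.0))
        xg, yg = dimensionless_kratky(globule, guinier_fit(globule))
        xc, yc = dimensionless_kratky(coil, guinier_fit(coil))
        assert yg.argmax() < len(yg) - 1 and yg[-1] < 0.5 * yg.max()
        assert yc[-1] > 0.8 * yc.max()


class TestRgDensity:
    def test_kde_integrates_to_one(self, frc_ensemble_small):
        rg = radius_of_gyration(frc_ensemble_small).per_frame
        grid, dens = rg_density(rg)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.02)

    def test_single_value_rejected(self):
        with pytest.raises(InputError):
            rg_density(np.array([10.0]))
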