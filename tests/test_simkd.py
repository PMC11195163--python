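"""Trajectory → bound/unbound annotation → apparent K_D pipeline."""

import numpy as np
import pytest
from scipy.stats import norm

from idpbind.exceptions import InputError, ModelDomainError, ParameterError
from idpbind.geometry import ConformationalEnsemble
from idpbind.simkd import (
    BindingTrajectoryModel,
    BoundAnnotation,
    ComDistanceTrajectory,
    SimulationBox,
    TwoGaussianFit,
    apparent_kd,
    bound_threshold,
    classify_bound_frames,
    coarse_grain_rna_structure,
    com_distance_trajectory,
    contact_frequency,
    fit_two_gaussian_rdf,
    relative_kd,
)

BOX40 = SimulationBox(40.0)


def _pdb_text(n_models=2, n_res=5, atom="C1'"):
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:4d}")
        serial = 1
        for i in range(1, n_res + 1):
            x = 3.0 * i + 0.1 * m
            for name, offset in (("P", 0.5), (atom, 0.0)):
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s}  U A{i:4d}    "
                    f"{x + offset:8.3f}{1.0:8.3f}{2.0:8.3f}  1.00  0.00           C"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


class TestSimulationBox:
    def test_single_pair_concentration_in_40nm_box(self):
        assert BOX40.c_box_uM == pytest.approx(25.95, abs=0.01)

    def test_volume_and_edge_units(self):
        assert BOX40.volume_nm3 == 64000.0
        assert BOX40.edge_angstrom == 400.0

    def test_nonpositive_edge_rejected(self):
        with pytest.raises(ParameterError):
            SimulationBox(0.0)


class TestComDistance:
    def test_two_isolated_beads(self):
        coords = np.array([[[0, 0, 0], [30, 0, 0]]], float)
        traj = com_distance_trajectory(ConformationalEnsemble(coords),
                                       ([0], [1]), BOX40)
        assert traj.distances[0] == pytest.approx(30.0)

    def test_minimum_image_wrap(self):
        coords = np.array([[[5, 0, 0], [395, 0, 0]]], float)
        traj = com_distance_trajectory(ConformationalEnsemble(coords),
                                       ([0], [1]), BOX40)
        assert traj.distances[0] == pytest.approx(10.0)

    def test_rigid_translation_invariance(self, rng):
        coords = rng.uniform(0, 100, size=(5, 6, 3))
        ens = ConformationalEnsemble(coords)
        moved = ConformationalEnsemble(coords + np.array([7.0, -13.0, 2.0]))
        part = ([0, 1, 2], [3, 4, 5])
        np.testing.assert_allclose(
            com_distance_trajectory(ens, part, BOX40).distances,
            com_distance_trajectory(moved, part, BOX40).distances, rtol=1e-10)

    def test_overlapping_partition_rejected(self):
        ens = ConformationalEnsemble(np.zeros((1, 3, 3)))
        with pytest.raises(InputError):
            com_distance_trajectory(ens, ([0, 1], [1, 2]), BOX40)


class TestCoarseGrainRna:
    def test_one_bead_per_nucleotide(self, tmp_path):
        p = tmp_path / "rna.pdb"
        p.write_text(_pdb_text(n_models=1, n_res=29))
        ens = coarse_grain_rna_structure(str(p))
        assert ens.n_frames == 1 and ens.n_beads == 29

    def test_conformer_count_preserved(self, tmp_path):
        p = tmp_path / "rna20.pdb"
        p.write_text(_pdb_text(n_models=20, n_res=5))
        ens = coarse_grain_rna_structure(str(p))
        assert ens.n_frames == 20 and ens.n_beads == 5

    def test_missing_anchor_atom_names_nucleotide(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(_pdb_text(n_models=1, n_res=3, atom="C2'"))
        with pytest.raises(InputError) as exc:
            coarse_grain_rna_structure(str(p))
        assert "C1'" in str(exc.value)


class TestTwoGaussianRdf:
    def test_known_mixture_means_recovered(self, rng):
        d = np.concatenate([rng.normal(30, 5, 25000),
                            rng.normal(150, 40, 25000)])
        fit = fit_two_gaussian_rdf(ComDistanceTrajectory(np.abs(d)))
        assert fit.converged and fit.unbound_present
        assert fit.mu1 == pytest.approx(30.0, rel=0.02)
        assert fit.mu2 == pytest.approx(150.0, rel=0.02)

    def test_unimodal_distances_lack_unbound_component(self, rng):
        d = np.abs(rng.normal(150, 40, 30000))
        fit = fit_two_gaussian_rdf(ComDistanceTrajectory(d))
        assert not fit.unbound_present
        if fit.converged:
            with pytest.raises(ModelDomainError):
                bound_threshold(fit)

    def test_too_few_bins_rejected(self, rng):
        d = np.abs(rng.normal(100, 20, 1000))
        with pytest.raises(ParameterError):
            fit_two_gaussian_rdf(ComDistanceTrajectory(d), n_bins=5)


class TestBoundThreshold:
    def test_symmetric_mixture_threshold_is_midpoint(self):
        fit = TwoGaussianFit(1.0, 30.0, 10.0, 1.0, 150.0, 10.0,
                             converged=True, unbound_present=True)
        assert bound_threshold(fit) == pytest.approx(90.0, rel=1e-6)

    def test_amplitude_asymmetry_matches_grid_scan_oracle(self):
        fit = TwoGaussianFit(2.0, 30.0, 10.0, 1.0, 150.0, 10.0,
                             converged=True, unbound_present=True)
        thr = bound_threshold(fit)
        grid = np.linspace(30, 150, 200001)
        diff = (2.0 * norm.pdf(grid, 30, 10) - norm.pdf(grid, 150, 10))
        oracle = grid[np.nonzero(np.diff(np.sign(diff)))[0][0]]
        assert thr == pytest.approx(oracle, abs=1e-3)
        assert thr > 90.0  # shifted toward the weaker component


class TestClassifyBoundFrames:
    def test_short_runs_filtered_out(self):
        d = np.full(20, 100.0)
        d[2:5] = 10.0   # run of 3: filtered
        d[8:14] = 10.0  # run of 6: kept
        ann = classify_bound_frames(ComDistanceTrajectory(d), 50.0, min_run=5)
        assert int(ann.bound.sum()) == 6
        assert ann.bound[8:14].all() and not ann.bound[2:5].any()

    def test_all_frames_above_threshold(self):
        ann = classify_bound_frames(
            ComDistanceTrajectory(np.full(50, 100.0)), 50.0)
        assert ann.fraction_bound == 0.0

    def test_min_run_one_is_plain_thresholding(self, rng):
        d = rng.uniform(0, 100, 500)
        ann = classify_bound_frames(ComDistanceTrajectory(d), 50.0, min_run=1)
        np.testing.assert_array_equal(ann.bound, d < 50.0)

    def test_matches_brute_force_run_length_oracle(self, rng):
        for _ in range(20):
            below = rng.random(rng.integers(10, 2000)) < 0.5
            d = np.where(below, 10.0, 100.0)
            ann = classify_bound_frames(ComDistanceTrajectory(d), 50.0, min_run=5)
            # oracle: scan runs explicitly
            expect = np.zeros(len(below), bool)
            start = None
            for i, b in enumerate(list(below) + [False]):
                if b and start is None:
                    start = i
                elif not b and start is not None:
                    if i - start >= 5:
                        expect[start:i] = True
                    start = None
            np.testing.assert_array_equal(ann.bound, expect)


class TestApparentKd:
    def test_half_bound_in_40nm_box(self):
        ann = BoundAnnotation(np.array([True, False] * 50), 50.0, 1)
        est = apparent_kd(ann, BOX40)
        assert est.kd_uM == pytest.approx(12.98, abs=0.01)

    def test_volume_scaling_at_fixed_fraction(self):
        ann = BoundAnnotation(np.array([True, False] * 50), 50.0, 1)
        big = SimulationBox(40.0 * 2 ** (1 / 3))  # doubled volume
        assert apparent_kd(ann, big).kd_uM == pytest.approx(
            apparent_kd(ann, BOX40).kd_uM / 2.0, rel=1e-6)

    def test_tight_binding_limit(self):
        ann = BoundAnnotation(np.array([True] * 999 + [False]), 50.0, 1)
        assert apparent_kd(ann, BOX40).kd_uM < 0.05

    @pytest.mark.parametrize("labels", [[False] * 10, [True] * 10])
    def test_degenerate_occupancy_rejected(self, labels):
        ann = BoundAnnotation(np.array(labels), 50.0, 1)
        with pytest.raises(ModelDomainError):
            apparent_kd(ann, BOX40)

    def test_relative_kd_fold(self):
        assert relative_kd(1.0, 3.5) == 3.5
        assert relative_kd(2.0, 2.0) == 1.0
        with pytest.raises(ParameterError):
            relative_kd(1.0, 0.0)


class TestContactFrequency:
    def _pair_traj(self):
        # 3 frames; beads 0-1 are molecule A, bead 2 is molecule B
        coords = np.array([
            [[0, 0, 0], [5, 0, 0], [10, 0, 0]],
            [[0, 0, 0], [5, 0, 0], [40, 0, 0]],
            [[0, 0, 0], [5, 0, 0], [12, 0, 0]],
        ], float)
        return ConformationalEnsemble(coords)

    def test_enumerated_frequencies_over_bound_frames(self):
        traj = self._pair_traj()
        ann = BoundAnnotation(np.array([True, False, True]), 50.0, 1)
        cm = contact_frequency(traj, ([0, 1], [2]), ann, cutoff=11.0)
        assert cm.frequencies[0, 0] == pytest.approx(0.5)  # 10 Å then 12 Å
        assert cm.frequencies[1, 0] == pytest.approx(1.0)

    def test_monotone_in_cutoff(self):
        traj = self._pair_traj()
        ann = BoundAnnotation(np.array([True, True, True]), 50.0, 1)
        c1 = contact_frequency(traj, ([0, 1], [2]), ann, cutoff=8.0)
        c2 = contact_frequency(traj, ([0, 1], [2]), ann, cutoff=15.0)
        assert np.all(c2.frequencies >= c1.frequencies)

    def test_no_bound_frames_rejected(self):
        traj = self._pair_traj()
        ann = BoundAnnotation(np.zeros(3, bool), 50.0, 1)
        with pytest.raises(ModelDomainError):
            contact_frequency(traj, ([0, 1], [2]), ann)


class TestPipeline:
    def test_omitted_replicate_when_unbound_state_unsampled(self, rng):
        d = np.abs(rng.normal(30, 5, 20000))  # bound-only trajectory
        res = BindingTrajectoryModel(ComDistanceTrajectory(d), BOX40).fit()
        assert res.omitted and res.kd is None

    def test_threshold_override_skips_rdf_decision(self, rng):
        d = np.concatenate([rng.normal(30, 5, 5000),
                            rng.normal(250, 60, 5000)])
        res = BindingTrajectoryModel(
            ComDistanceTrajectory(np.abs(d)), BOX40).fit(threshold=53.5)
        assert res.threshold == 53.5
        assert res.kd is not None
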