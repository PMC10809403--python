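import numpy as np
import pytest

from finsize.core import K_BOLTZMANN
from finsize.ensemble import (
    basin_delta_g,
    box_series,
    end_to_end,
    free_energy_profile,
    min_image_self_distance,
    orientation_map,
    wall_distance_summary,
)
from finsize.fixtures import orientation_sampler, two_state_distance_sampler

KT300 = K_BOLTZMANN * 300.0


class TestMinImageSelfDistance:
    def test_single_atom_half_box(self):
        assert min_image_self_distance([[1.0, 2.0, 0.5]], 3.0) == pytest.approx(1.5)

    def test_two_atoms_one_dimensional(self):
        pos = [[0.0, 0.0, 0.0], [1.3, 0.0, 0.0]]
        assert min_image_self_distance(pos, 2.5) == pytest.approx(0.6)

    def test_translation_invariance(self, helix):
        system, _, _ = helix
        L = 4.0
        d0 = min_image_self_distance(system.positions, L)
        d1 = min_image_self_distance(system.positions + [0.7, -1.2, 3.3], L)
        assert d1 == pytest.approx(d0, rel=1e-12)

    def test_overlapping_molecule_returns_zero(self):
        pos = [[0.0, 0.0, 0.0], [2.6, 0.0, 0.0]]
        with pytest.warns(UserWarning):
            assert min_image_self_distance(pos, 2.5) == 0.0

    def test_point_particle_upper_bound(self):
        # for any configuration the value cannot exceed the single-point
        # value L/2 (adding atoms can only reduce the minimum)
        rng = np.random.default_rng(3)
        pos = rng.random((20, 3)) * 1.2
        assert min_image_self_distance(pos, 3.0) <= 1.5 + 1e-12


class TestWallDistanceSummary:
    def test_constant_trajectory(self):
        frame = np.array([[0.0, 0.0, 0.0], [0.9, 0.0, 0.0]])
        out = wall_distance_summary([[frame, frame], [frame]], 3.0)
        assert out["init_nm"] == out["avg_nm"] == out["min_nm"]
        assert out["n_frames"] == 3

    def test_mixed_frames(self):
        f1 = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])  # min dist 2.0 -> 1.0
        f2 = np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0]])  # min dist 1.6 -> 0.8
        out = wall_distance_summary([[f1, f2]], 3.0)
        assert out["init_nm"] == pytest.approx(1.0)
        assert out["min_nm"] == pytest.approx(0.8)
        assert out["avg_nm"] == pytest.approx(0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wall_distance_summary([], 3.0)


class TestEndToEnd:
    def test_basic_and_helix_range(self, helix):
        assert end_to_end([[0, 0, 0], [1, 0, 0]], 0, 1) == pytest.approx(1.0)
        assert end_to_end([[0.2, 0.2, 0.2]], 0, 0) == 0.0
        system, ni, ci = helix
        assert 1.1 <= end_to_end(system.positions, ni, ci) <= 1.5


class TestFreeEnergyProfile:
    def test_uniform_samples_flat_profile(self):
        rng = np.random.default_rng(0)
        series = [rng.random(4000) for _ in range(8)]
        prof = free_energy_profile(series, bins=10, bin_range=(0.0, 1.0))
        ok = np.isfinite(prof.dg_mean)
        assert np.all(prof.dg_mean[ok] <= prof.ci95[ok] + 0.25)

    def test_two_state_gap_matches_mixture_weights(self):
        series = two_state_distance_sampler(
            p_a=0.2, n_frames=4000, n_replicas=10, seed=5
        )
        prof = free_energy_profile(series, bins=60, bin_range=(0.0, 3.0))
        in_a = (prof.bin_centers > 0.4) & (prof.bin_centers < 0.9)
        in_b = (prof.bin_centers > 1.8) & (prof.bin_centers < 2.6)
        g_a = np.nanmin(prof.dg_mean[in_a])
        g_b = np.nanmin(prof.dg_mean[in_b])
        expected = -KT300 * np.log(0.2 / 0.8)  # ~ +3.46 kJ/mol
        assert g_a - g_b == pytest.approx(expected, abs=0.4)

    def test_ci_shrinks_with_sample_size(self):
        s1 = two_state_distance_sampler(n_frames=1000, n_replicas=10, seed=7)
        s2 = two_state_distance_sampler(n_frames=2000, n_replicas=10, seed=7)
        p1 = free_energy_profile(s1, bins=30, bin_range=(0.0, 3.0))
        p2 = free_energy_profile(s2, bins=30, bin_range=(0.0, 3.0))
        m1 = np.nanmean(p1.ci95)
        m2 = np.nanmean(p2.ci95)
        assert m2 < m1

    def test_minimum_anchored_to_zero(self):
        series = two_state_distance_sampler(seed=2)
        prof = free_energy_profile(series, bins=40)
        assert np.nanmin(prof.dg_mean) == pytest.approx(0.0, abs=1e-12)

    def test_single_replica_rejected(self):
        with pytest.raises(ValueError):
            free_energy_profile([np.array([1.0, 2.0])], bins=5)


class TestBasinDeltaG:
    def test_equal_counts_zero(self):
        d = [np.array([0.5] * 50 + [2.0] * 50)] * 3
        out = basin_delta_g(d, (0.4, 0.9), (1.8, 2.6))
        assert out.dg_ab == pytest.approx(0.0, abs=1e-12)

    def test_two_state_generator_closed_form(self):
        series = two_state_distance_sampler(
            p_a=0.2, n_frames=5000, n_replicas=10, seed=11
        )
        out = basin_delta_g(series, (0.0, 1.2), (1.2, 4.0))
        expected = -KT300 * np.log(0.2 / 0.8)
        assert abs(out.dg_ab - expected) < max(out.ci95, 0.15)

    def test_window_swap_flips_sign(self):
        series = two_state_distance_sampler(seed=3)
        fwd = basin_delta_g(series, (0.0, 1.2), (1.2, 4.0))
        rev = basin_delta_g(series, (1.2, 4.0), (0.0, 1.2))
        assert rev.dg_ab == pytest.approx(-fwd.dg_ab)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            basin_delta_g([np.array([1.0])], (0.0, 1.0), (0.5, 2.0))

    def test_empty_window_replica_excluded(self):
        series = [
            np.array([0.5, 0.6, 2.0, 2.1]),
            np.array([2.0, 2.1, 2.2, 2.3]),  # nothing in basin A
        ]
        with pytest.warns(UserWarning):
            out = basin_delta_g(series, (0.4, 0.9), (1.8, 2.6))
        assert out.excluded_replicas == [1]


class TestOrientationMap:
    def test_isotropic_uniform_within_poisson(self):
        v = orientation_sampler("isotropic", n=20000, seed=4)
        out = orientation_map(v, n_theta=6, n_phi=12)
        counts = out["counts"]
        expected = out["n_samples"] / counts.size
        # equal-area bins: all counts within 4 sigma of the Poisson mean
        assert np.all(np.abs(counts - expected) < 4.0 * np.sqrt(expected))

    def test_six_face_mixture_detected(self):
        iso = orientation_map(orientation_sampler("isotropic", n=8000, seed=5))
        six = orientation_map(
            orientation_sampler("six-face", concentration=30.0, n=8000, seed=5)
        )
        assert six["face_alignment_score"] > iso["face_alignment_score"]
        assert six["face_alignment_score"] > six["isotropic_expectation"] * 2

    def test_all_plus_z_single_bin(self):
        v = np.tile([0.0, 0.0, 1.0], (100, 1))
        out = orientation_map(v, n_theta=6, n_phi=12)
        assert out["counts"].sum() == 100
        assert np.count_nonzero(out["counts"]) == 1
        assert out["counts"][0].sum() == 100  # polar band at theta ~ 0

    def test_zero_vectors_skipped(self):
        v = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.warns(UserWarning):
            out = orientation_map(v)
        assert out["n_samples"] == 1


class TestBoxSeries:
    def test_identical_values_no_significance(self):
        vals = [np.array([2.0, 2.1, 1.9])] * 3
        out = box_series([3.0, 6.0, 9.0], vals)
        assert out.differences == pytest.approx([0.0, 0.0, 0.0])
        assert not any(out.significant)

    def test_largest_box_difference_is_zero(self):
        rng = np.random.default_rng(0)
        vals = [rng.normal(i, 0.1, 5) for i in range(3)]
        out = box_series([4.5, 9.0, 3.0], vals)
        assert out.box_edges == [3.0, 4.5, 9.0]
        assert out.differences[-1] == 0.0

    def test_injected_offset_flagged(self):
        rng = np.random.default_rng(1)
        base = [rng.normal(0.0, 0.05, 5) for _ in range(3)]
        base[0] = base[0] + 3.0  # large artifact in the smallest box
        out = box_series([3.0, 6.0, 9.0], base)
        assert out.significant[0]
        assert not out.significant[-1]

    def test_worked_five_replica_normal_ci(self):
        # textbook normal-approximation CI on a worked example
        small = np.array([1.0, 1.2, 0.8, 1.1, 0.9])
        large = np.array([0.5, 0.5, 0.5, 0.5, 0.5])
        out = box_series([3.0, 9.0], [small, large])
        se = small.std(ddof=1) / np.sqrt(5)
        assert out.ci95[0] == pytest.approx(1.959963984540054 * se)
        assert out.differences[0] == pytest.approx(0.5)

    def test_single_replica_no_ci(self):
        out = box_series([3.0, 9.0], [np.array([1.0]), np.array([0.5])])
        assert not out.has_ci
        assert out.differences[0] == pytest.approx(0.5)
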