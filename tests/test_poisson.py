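import numpy as np
import pytest

from finsize.core import ChargeSystem, F_COULOMB, PerturbationTopology
from finsize.fixtures import born_ion, random_neutral_cloud
from finsize.poisson import (
    GridSpec,
    build_dielectric_grid,
    delta_g_pol,
    padded_geometry,
    periodic_geometry,
    solvation_free_energy,
    solve_poisson_fd,
    solve_poisson_fft,
    spread_charges,
)

BORN = -F_COULOMB / (2 * 0.2) * (1 - 1 / 66.6)  # q=1e, R=0.2 nm, eps=66.6


def _uniform_system(positions, charges, box=None):
    n = len(charges)
    return ChargeSystem(
        positions=np.asarray(positions, float),
        charges=np.asarray(charges, float),
        radii=np.zeros(n),
        names=[f"Q{i}" for i in range(n)],
        box_edge=box,
    )


class TestDielectricGrid:
    def test_no_atoms_uniform(self):
        empty = ChargeSystem(
            positions=np.zeros((0, 3)), charges=[], radii=[], names=[], box_edge=2.0
        )
        spec = GridSpec(spacing=0.1)
        grid = build_dielectric_grid(empty, spec)
        assert np.all(grid.node_eps == spec.eps_out)
        assert grid.uniform

    def test_sphere_interior_cell_count(self):
        spec = GridSpec(spacing=0.05)
        ion = born_ion(1.0, 0.2, 2.0)
        grid = build_dielectric_grid(ion, spec, periodic_geometry(2.0, spec))
        inside = int(np.sum(grid.node_eps == spec.eps_in))
        expected = 4.0 / 3.0 * np.pi * (0.2 / 0.05) ** 3
        assert abs(inside - expected) / expected < 0.15

    def test_disjoint_atoms_disjoint_interiors(self):
        sys_ = ChargeSystem(
            positions=[[0.5, 1.0, 1.0], [1.5, 1.0, 1.0]],
            charges=[1.0, -1.0],
            radii=[0.15, 0.15],
            names=["A", "B"],
            box_edge=2.0,
        )
        spec = GridSpec(spacing=0.05)
        both = build_dielectric_grid(sys_, spec)
        single_a = build_dielectric_grid(sys_.subset([0]), spec)
        single_b = build_dielectric_grid(sys_.subset([1]), spec)
        in_both = both.node_eps == spec.eps_in
        in_a = single_a.node_eps == spec.eps_in
        in_b = single_b.node_eps == spec.eps_in
        assert not np.any(in_a & in_b)
        assert np.array_equal(in_both, in_a | in_b)


class TestSpreadCharges:
    def test_charge_on_node(self):
        spec = GridSpec(spacing=0.1)
        sys_ = _uniform_system([[0.5, 0.5, 0.5]], [1.0], box=2.0)
        rho = spread_charges(sys_, spec)
        assert rho[5, 5, 5] == pytest.approx(1.0)
        assert np.count_nonzero(rho) == 1

    def test_partition_of_unity(self, neutral_cloud):
        rho = spread_charges(neutral_cloud, GridSpec(spacing=0.07))
        assert rho.sum() == pytest.approx(neutral_cloud.net_charge, abs=1e-12)

    def test_cell_center_splits_evenly(self):
        spec = GridSpec(spacing=0.1)
        sys_ = _uniform_system([[0.55, 0.55, 0.55]], [1.0], box=2.0)
        rho = spread_charges(sys_, spec)
        nz = rho[rho != 0]
        assert len(nz) == 8
        assert np.allclose(nz, 0.125)


class TestSolvers:
    def test_zero_density_zero_potential(self):
        spec = GridSpec(spacing=0.1)
        geom = periodic_geometry(2.0, spec)
        empty = ChargeSystem(
            positions=np.zeros((0, 3)), charges=[], radii=[], names=[], box_edge=2.0
        )
        eps = build_dielectric_grid(empty, spec, geom)
        rho = np.zeros((geom.dims,) * 3)
        phi = solve_poisson_fd(rho, eps, spec, "periodic")
        assert np.all(phi.values == 0.0)
        assert np.all(solve_poisson_fft(rho, spec, geom).values == 0.0)

    def test_point_charge_matches_coulomb(self):
        # uniform dielectric, nonperiodic: phi(0.5 nm) ~ f q / (eps r)
        one = _uniform_system([[0.0, 0.0, 0.0]], [1.0])
        spec = GridSpec(spacing=0.05, eps_out=66.6, min_extent=2.4)
        geom = padded_geometry(one, spec)
        eps = build_dielectric_grid(one, spec, geom)
        rho = spread_charges(one, spec, geom)
        phi = solve_poisson_fd(rho, eps, spec, "coulomb-dirichlet", source_system=one)
        ref = F_COULOMB / (66.6 * 0.5)
        at = phi.interpolate(np.array([[0.5, 0.0, 0.0]]))[0]
        assert at == pytest.approx(ref, rel=0.02)

    def test_fd_fft_equivalence_uniform_eps(self, neutral_cloud):
        spec = GridSpec(spacing=0.05, eps_out=66.6, sor_tol=1e-10)
        geom = periodic_geometry(2.0, spec)
        uni = neutral_cloud.with_charges(neutral_cloud.charges)
        uni.radii = np.zeros(uni.n_atoms)
        eps = build_dielectric_grid(uni, spec, geom)
        assert eps.uniform
        rho = spread_charges(uni, spec, geom)
        fd = solve_poisson_fd(rho, eps, spec, "periodic")
        fft = solve_poisson_fft(rho, spec, geom)
        scale = np.max(np.abs(fft.values))
        assert np.max(np.abs(fd.values - fft.values)) / scale < 1e-6

    def test_periodic_gauge_zero_mean(self, periodic_born):
        spec = GridSpec(spacing=0.1)
        geom = periodic_geometry(3.0, spec)
        eps = build_dielectric_grid(periodic_born, spec, geom)
        rho = spread_charges(periodic_born, spec, geom)
        phi = solve_poisson_fd(rho, eps, spec, "periodic")
        assert abs(phi.values.mean()) < 1e-10

    def test_fft_self_energy_matches_wigner(self):
        # 1/2 q phi_self of a unit charge on the grid, minus the same grid's
        # isolated self-energy, reproduces the Ewald self+background term
        from finsize.lattice import EwaldParams, ewald_energy

        L = 2.0
        spec = GridSpec(spacing=0.025, eps_out=1.0)
        geom = periodic_geometry(L, spec)
        ion = _uniform_system([[L / 2, L / 2, L / 2]], [1.0], box=L)
        rho = spread_charges(ion, spec, geom)
        phi = solve_poisson_fft(rho, spec, geom)
        e_grid = 0.5 * phi.interpolate(ion.positions)[0]
        # isolated grid self-energy via a large padded Dirichlet solve
        iso_spec = GridSpec(spacing=0.025, eps_out=1.0, min_extent=2.0)
        iso = _uniform_system([[0.0, 0.0, 0.0]], [1.0])
        geom2 = padded_geometry(iso, iso_spec)
        eps2 = build_dielectric_grid(iso, iso_spec, geom2)
        rho2 = spread_charges(iso, iso_spec, geom2)
        phi2 = solve_poisson_fd(rho2, eps2, iso_spec, "coulomb-dirichlet", source_system=iso)
        e_self = 0.5 * phi2.interpolate(iso.positions)[0]
        wigner = ewald_energy(ion, EwaldParams(r_cut=L / 2, rel_tol=1e-7))
        assert e_grid - e_self == pytest.approx(wigner, rel=0.02)


class TestSolvationFreeEnergy:
    def test_zero_charges_zero_energy(self):
        ion = born_ion(0.0, 0.2)
        assert solvation_free_energy(ion, GridSpec(spacing=0.1)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_born_ion_nonperiodic(self):
        g = solvation_free_energy(born_ion(1.0, 0.2), GridSpec(spacing=0.05))
        assert g == pytest.approx(BORN, rel=0.03)

    def test_grid_refinement_converges_to_born(self):
        errs = [
            abs(solvation_free_energy(born_ion(1.0, 0.2), GridSpec(spacing=h)) - BORN)
            for h in (0.1, 0.05, 0.025)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_quadratic_in_charge(self):
        spec = GridSpec(spacing=0.05)
        g1 = solvation_free_energy(born_ion(1.0, 0.2), spec)
        g2 = solvation_free_energy(born_ion(2.0, 0.2), spec)
        assert g2 == pytest.approx(4.0 * g1, rel=1e-6)


class TestDeltaGPol:
    def _topology(self, qa, qb):
        return PerturbationTopology(
            q_solute_a=sum(qa),
            q_solute_b=sum(qb),
            q_ion_a=0.0,
            q_ion_b=0.0,
            q_overall_a=sum(qa),
            q_overall_b=sum(qb),
            charges_a=qa,
            charges_b=qb,
        )

    def test_identity_perturbation_is_zero(self, periodic_born):
        top = self._topology([1.0], [1.0])
        res = delta_g_pol([periodic_born], [periodic_born], top, GridSpec(spacing=0.1))
        assert res.dg_pol == 0.0

    def test_wigner_scaling_with_box_size(self):
        top = self._topology([0.0], [1.0])
        spec = GridSpec(spacing=0.1)
        vals = {
            L: delta_g_pol([born_ion(1.0, 0.2, L)], [born_ion(1.0, 0.2, L)], top, spec).dg_pol
            for L in (3.0, 6.0)
        }
        assert abs(vals[3.0]) > abs(vals[6.0])
        assert vals[3.0] / vals[6.0] == pytest.approx(2.0, abs=0.3)

    def test_neutral_pair_much_smaller_than_monopole(self):
        spec = GridSpec(spacing=0.1)
        L = 3.0
        mono = born_ion(1.0, 0.2, L)
        res_mono = delta_g_pol([mono], [mono], self._topology([0.0], [1.0]), spec)
        pair = ChargeSystem(
            positions=[[L / 2 - 0.25, L / 2, L / 2], [L / 2 + 0.25, L / 2, L / 2]],
            charges=[0.0, 0.0],
            radii=[0.2, 0.2],
            names=["P", "M"],
            box_edge=L,
        )
        res_pair = delta_g_pol(
            [pair], [pair], self._topology([0.0, 0.0], [1.0, -1.0]), spec
        )
        assert abs(res_pair.dg_pol) * 5 < abs(res_mono.dg_pol)
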