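"""Mesh construction and the nonlinear potential solver.

The constant-conductivity solve is validated against the closed-form
potential of two parallel cylindrical conductors (bipolar line-charge
solution): for cylinders of radius a with centre separation 2d at potentials
V0 and 0, phi = V0/2 + U ln(r2/r1) with U = V0 / (2 arccosh(d/a)) and r1, r2
the distances to the equivalent line charges at +/- sqrt(d^2 - a^2) from the
midpoint.  The closed form describes free space, so agreement is asserted in
the central region where the influence of the insulated outer box is below
the tolerance.
"""

import numpy as np
import pytest

from irepf import (
    SimulationDomain,
    build_mesh,
    cervical_cancer_params,
    converge_mesh,
    electrode_currents,
    solve_potential,
)
from irepf.errors import MeshError


def two_cylinder_potential(points, domain, v0):
    """Independent closed-form oracle: bipolar two-wire potential."""
    a = domain.electrode_radius_mm
    d = domain.electrode_spacing_mm / 2.0
    cx, cy = domain.center
    c = np.sqrt(d * d - a * a)
    u = (v0 / 2.0) / np.arccosh(d / a)
    r_anode = np.hypot(points[:, 0] - (cx - c), points[:, 1] - cy)
    r_cathode = np.hypot(points[:, 0] - (cx + c), points[:, 1] - cy)
    return v0 / 2.0 + u * np.log(r_cathode / r_anode)


class TestBuildMesh:
    def test_element_count_scaling(self, domain_1kv, coarse_mesh):
        fine = build_mesh(domain_1kv, 0.4)
        ratio = fine.n_elements / coarse_mesh.n_elements
        assert 4.0 * 0.8 <= ratio <= 4.0 * 1.2

    def test_electrode_nodes_on_their_disc(self, domain_1kv, coarse_mesh):
        a = domain_1kv.electrode_radius_mm
        for nodes, center in zip(
            (coarse_mesh.anode_nodes, coarse_mesh.cathode_nodes),
            domain_1kv.electrode_centers,
        ):
            p = coarse_mesh.points[nodes]
            r = np.hypot(p[:, 0] - center[0], p[:, 1] - center[1])
            assert np.all(np.abs(r - a) < 1e-9)

    def test_total_area_matches_geometry(self, domain_1kv, coarse_mesh):
        expected = (
            domain_1kv.width_mm * domain_1kv.height_mm
            - 2.0 * np.pi * domain_1kv.electrode_radius_mm**2
        )
        assert coarse_mesh.total_area == pytest.approx(expected, rel=1e-3)

    def test_determinism(self, domain_1kv, coarse_mesh):
        again = build_mesh(domain_1kv, 0.8)
        assert np.array_equal(again.points, coarse_mesh.points)
        assert np.array_equal(again.triangles, coarse_mesh.triangles)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.0, 2.0])
    def test_resolution_bounds(self, domain_1kv, bad):
        with pytest.raises(MeshError):
            build_mesh(domain_1kv, bad)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(MeshError):
            SimulationDomain(electrode_spacing_mm=0.5)


class TestLinearSolve:
    def test_matches_two_cylinder_oracle(self, domain_1kv, coarse_mesh, linear_solution):
        p = coarse_mesh.points
        cx, cy = domain_1kv.center
        dist_e = np.minimum.reduce(
            [
                np.hypot(p[:, 0] - c[0], p[:, 1] - c[1])
                for c in domain_1kv.electrode_centers
            ]
        ) - domain_1kv.electrode_radius_mm
        central = np.hypot(p[:, 0] - cx, p[:, 1] - cy) <= 20.0
        mask = (dist_e >= 2.0) & central
        oracle = two_cylinder_potential(p[mask], domain_1kv, 1000.0)
        err = np.abs(linear_solution.phi[mask] - oracle) / 1000.0
        assert err.max() < 0.02

    def test_linearity_in_voltage(self, coarse_mesh, linear_solution):
        doubled = solve_potential(coarse_mesh, 2000.0, 0.23)
        assert np.allclose(doubled.phi, 2.0 * linear_solution.phi, rtol=1e-10, atol=1e-8)
        assert np.allclose(
            doubled.e_mag_node, 2.0 * linear_solution.e_mag_node, rtol=1e-10, atol=1e-8
        )

    def test_maximum_principle(self, linear_solution):
        assert linear_solution.phi.min() >= -1e-9 * 1000.0
        assert linear_solution.phi.max() <= 1000.0 * (1 + 1e-9)


class TestNonlinearSolve:
    def test_picard_converges_and_respects_maximum_principle(self, nonlinear_solution):
        assert nonlinear_solution.iterations < 100
        assert nonlinear_solution.residual_history[-1] < 1e-6
        assert nonlinear_solution.phi.min() >= -1e-9 * 1000.0
        assert nonlinear_solution.phi.max() <= 1000.0 * (1 + 1e-9)

    def test_current_conservation(self, nonlinear_solution):
        i_anode, i_cathode = electrode_currents(nonlinear_solution)
        assert abs(i_anode + i_cathode) / abs(i_anode) < 0.01

    def test_mirror_symmetry(self, domain_1kv, coarse_mesh, nonlinear_solution):
        from scipy.interpolate import LinearNDInterpolator

        p = coarse_mesh.points
        interp = LinearNDInterpolator(p, nonlinear_solution.phi)
        inner = (
            (p[:, 0] > 5)
            & (p[:, 0] < domain_1kv.width_mm - 5)
            & (p[:, 1] > 5)
            & (p[:, 1] < domain_1kv.height_mm - 5)
        )
        mirrored = interp(
            np.column_stack([domain_1kv.width_mm - p[inner, 0], p[inner, 1]])
        )
        ok = np.isfinite(mirrored)
        err = np.abs(nonlinear_solution.phi[inner][ok] + mirrored[ok] - 1000.0)
        assert err.max() < 0.01 * 1000.0

    def test_nonlinearity_changes_the_field(self, coarse_mesh, nonlinear_solution):
        # the conductivity rise around the electrodes must redistribute the
        # field: the midpoint magnitude differs from the constant-sigma0 case
        linear = solve_potential(
            coarse_mesh, 1000.0, cervical_cancer_params(100.0).sigma0
        )
        p = coarse_mesh.points
        mid = np.argmin(np.hypot(p[:, 0] - 50.0, p[:, 1] - 40.0))
        e_nl = nonlinear_solution.e_mag_node[mid]
        e_lin = linear.e_mag_node[mid]
        assert abs(e_nl - e_lin) / e_lin > 0.02

    def test_sigma_within_gompertz_bounds(self, nonlinear_solution):
        params = cervical_cancer_params(100.0)
        assert np.all(nonlinear_solution.sigma_elem > params.sigma0 * 0.999)
        assert np.all(nonlinear_solution.sigma_elem <= params.sigma_max * (1 + 1e-9))


class TestConvergeMesh:
    def test_threshold_area_refinement_terminates(self, domain_1kv):
        cond = cervical_cancer_params(100.0)
        mesh, sol, history = converge_mesh(domain_1kv, cond, 600.0, 0.8)
        areas = [a for _, _, a in history]
        assert len(areas) >= 2
        final_change = abs(areas[-1] - areas[-2]) / areas[-2]
        assert final_change < 1e-3
        # Cauchy-like tail: late-stage fluctuations are below 1 %
        tail = areas[-3:]
        assert (max(tail) - min(tail)) / areas[-1] < 0.01

    def test_history_is_deterministic(self, domain_1kv):
        cond = cervical_cancer_params(100.0)
        _, _, h1 = converge_mesh(domain_1kv, cond, 600.0, 0.8)
        _, _, h2 = converge_mesh(domain_1kv, cond, 600.0, 0.8)
        assert h1 == h2
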