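"""Flow solver: analytic limits, conservation, streamfunction, symmetry."""

import numpy as np
import pytest

from lutflow import geometry as geo
from lutflow import meshing as msh
from lutflow.flow_solver import (BoundarySet, FluidProperties, FVGeom,
                                 FlowSolution, NumericsConfig, SolverError,
                                 compute_streamfunction, solve_steady_flow)

MU = 0.8583e-3
RHO = 1035.0


class TestConfigValidation:
    def test_rejects_bad_relaxation(self):
        with pytest.raises(ValueError):
            NumericsConfig(alpha_u=0.0)
        with pytest.raises(ValueError):
            NumericsConfig(alpha_p=1.5)

    def test_rejects_bad_tolerance(self):
        with pytest.raises(ValueError):
            NumericsConfig(tol=-1e-5)

    def test_rejects_nonpositive_fluid(self):
        with pytest.raises(ValueError):
            FluidProperties(density=-1.0)

    def test_rejects_adverse_pressures(self):
        with pytest.raises(ValueError):
            BoundarySet(inlet_gauge_pressure=0.0, outlet_gauge_pressure=10.0)


class TestPoiseuilleLimit:
    """Creeping channel flow against the plane-Poiseuille closed form."""

    def test_profile_within_one_percent(self, poiseuille_state):
        domain, mesh, sol, bc = poiseuille_state
        assert sol.converged
        g = sol.geom
        w = 0.003                          # half gap, m
        length = 0.04
        umax = bc.inlet_gauge_pressure * (2 * w) ** 2 / (8 * MU * length)
        mid = np.abs(g.xc[:, 1] + length / 2) < 0.002
        xs = g.xc[mid][:, 0]
        v = -sol.v[mid]
        parabola = umax * (1.0 - (xs / w) ** 2)
        assert np.max(np.abs(v - parabola)) / umax < 0.01

    def test_mass_conservation(self, poiseuille_state):
        _, _, sol, _ = poiseuille_state
        assert sol.mass_imbalance <= 1e-3
        assert sol.inlet_flux() == pytest.approx(sol.outlet_flux(), rel=1e-3)

    def test_flux_matches_closed_form(self, poiseuille_state):
        _, _, sol, bc = poiseuille_state
        w, length = 0.003, 0.04
        q_theory = 2.0 * bc.inlet_gauge_pressure * w**3 / (3 * MU * length)
        assert sol.inlet_flux() == pytest.approx(q_theory, rel=0.02)

    def test_no_reverse_flow_anywhere(self, poiseuille_state):
        _, _, sol, _ = poiseuille_state
        assert np.all(-sol.v > -1e-9)


class TestStreamfunction:
    def test_uniform_flow_gives_linear_psi(self, poiseuille_state):
        # fabricate a uniform downward flow on the channel mesh: the exact
        # streamfunction is linear in x
        _, mesh, sol, _ = poiseuille_state
        g = sol.geom
        uspeed = 0.5
        mf = RHO * (-uspeed) * g.i_sf[:, 1]
        mb = RHO * (-uspeed) * g.b_sf[:, 1]
        fake = FlowSolution(
            p=np.zeros(g.nc), u=np.zeros(g.nc),
            v=np.full(g.nc, -uspeed), k=None, eps=None, mu_t=None,
            converged=True, n_iter=1, mass_imbalance=0.0, residuals={},
            fluid=FluidProperties(), bc=BoundarySet(), cfg=NumericsConfig(),
            face_flux=mf, boundary_flux=mb, geom=g)
        psi = compute_streamfunction(fake, mesh)
        x = mesh.nodes[:, 0]
        fit = np.polyfit(x, psi, 1)
        assert fit[0] == pytest.approx(uspeed, rel=1e-6)
        assert np.max(np.abs(psi - np.polyval(fit, x))) < 1e-9 * uspeed + 1e-12

    def test_wall_constancy_and_total_jump(self, poiseuille_state):
        _, mesh, sol, _ = poiseuille_state
        psi = compute_streamfunction(sol, mesh)
        g = sol.geom
        wall_nodes = np.unique(g.f_nodes[g.boundary[g.b_wall]])
        x = mesh.nodes[wall_nodes, 0]
        psi_r = psi[wall_nodes[x > 0]]
        psi_l = psi[wall_nodes[x < 0]]
        jump = abs(np.median(psi_r) - np.median(psi_l))
        assert jump == pytest.approx(sol.inlet_flux(), rel=1e-3)
        assert np.ptp(psi_r) < 1e-4 * jump
        assert np.ptp(psi_l) < 1e-4 * jump

    def test_poiseuille_psi_is_cubic(self, poiseuille_state):
        _, mesh, sol, _ = poiseuille_state
        psi = compute_streamfunction(sol, mesh)
        nodes = mesh.nodes
        mid = np.abs(nodes[:, 1] + 0.02) < 0.0015
        x, p = nodes[mid, 0], psi[mid]
        coeff = np.polyfit(x, p, 3)
        resid = np.max(np.abs(np.polyval(coeff, x) - p))
        assert resid < 0.01 * np.ptp(p)

    def test_requires_convergence(self, poiseuille_state):
        _, mesh, sol, _ = poiseuille_state
        bad = FlowSolution(**{**sol.__dict__, "converged": False})
        with pytest.raises(SolverError):
            compute_streamfunction(bad, mesh)


class TestIndexCaseFlow:
    def test_converged_with_tight_residuals(self, cats_coarse_state):
        mesh, sol = cats_coarse_state
        assert sol.converged
        assert sol.residuals["continuity"][-1] < 1e-5
        assert sol.mass_imbalance <= 1e-3

    def test_turbulence_fields_nonnegative(self, cats_coarse_state):
        _, sol = cats_coarse_state
        assert np.all(sol.k >= 0)
        assert np.all(sol.eps >= 0)

    def test_speed_below_free_discharge_bound(self, cats_coarse_state):
        # with losses, no point exceeds the frictionless discharge velocity
        # by more than a modest numerical margin
        _, sol = cats_coarse_state
        u_bernoulli = np.sqrt(2 * 4958.8 / RHO)
        assert sol.speed.max() < 1.25 * u_bernoulli

    def test_residuals_decay(self, cats_coarse_state):
        _, sol = cats_coarse_state
        cont = sol.residuals["continuity"]
        # smoke property: late-stage residuals far below the post-ramp level
        assert cont[-1] < 1e-2 * cont[150]

    def test_unconverged_run_is_flagged_not_raised(self, cats_half_domain):
        mesh = msh.triangulate(cats_half_domain, 1250)
        cfg = NumericsConfig(max_iter=150)
        sol = solve_steady_flow(mesh, FluidProperties(), BoundarySet(), cfg)
        assert not sol.converged
        assert sol.n_iter == 150


class TestMirrorSymmetry:
    def test_full_domain_fields_mirror_within_one_percent(
            self, cats_full_coarse_state):
        mesh, sol = cats_full_coarse_state
        assert sol.converged
        g = sol.geom
        from scipy.spatial import cKDTree

        tree = cKDTree(g.xc)
        mirrored = g.xc * np.array([-1.0, 1.0])
        d, j = tree.query(mirrored)
        ok = d < 1e-9
        peak = sol.speed.max()
        du = np.abs(sol.u[ok] + sol.u[j[ok]])      # u is odd in x
        dv = np.abs(sol.v[ok] - sol.v[j[ok]])      # v is even in x
        assert np.percentile(du, 99) < 0.01 * peak
        assert np.percentile(dv, 99) < 0.01 * peak

    def test_half_and_full_solutions_agree(self, cats_coarse_state,
                                           cats_full_coarse_state):
        from lutflow.postprocess import mv_euo

        half_mesh, half_sol = cats_coarse_state
        full_mesh, full_sol = cats_full_coarse_state
        v_half = mv_euo(half_sol, half_mesh)
        v_full = mv_euo(full_sol, full_mesh)
        assert v_half == pytest.approx(v_full, rel=0.02)
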