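import numpy as np
import pytest

from fhrdyn.core_models import Cubic, FHN2DParams
from fhrdyn.integrate import rk4_solve
from fhrdyn.rd_simulator import (
    Grid,
    NhFHNParams,
    c_profile_ball,
    c_profile_quartic,
    laplacian_matrix,
    laplacian_neumann,
    propagation_diagnostics,
    simulate_nhfhn,
    stable_dt,
    stationary_solve,
)
from fhrdyn.stability import fixed_point_2d


@pytest.fixture
def grid1d():
    return Grid(101, (-10.0, 10.0), dimension=1)


@pytest.fixture
def grid2d():
    return Grid(33, (-8.0, 8.0), dimension=2)


class TestLaplacian:
    def test_constant_field_zero(self, grid1d, grid2d):
        assert np.all(laplacian_neumann(np.ones(101), grid1d.dx) == 0.0)
        assert np.all(laplacian_neumann(np.ones((33, 33)), grid2d.dx) == 0.0)

    def test_quadratic_interior(self, grid1d):
        lap = laplacian_neumann(grid1d.x ** 2, grid1d.dx)
        np.testing.assert_allclose(lap[2:-2], 2.0, atol=1e-9)
        # boundary values reflect the ghost-point (no-flux) closure
        assert lap[0] != pytest.approx(2.0, abs=0.5)

    def test_separable_2d(self, grid2d):
        X, Y = np.meshgrid(grid2d.x, grid2d.x, indexing="ij")
        lap = laplacian_neumann(X ** 2 + Y ** 2, grid2d.dx)
        np.testing.assert_allclose(lap[2:-2, 2:-2], 4.0, atol=1e-9)

    def test_no_flux_conserves_mean(self, grid1d, rng):
        f = rng.normal(size=101)
        assert abs(np.mean(laplacian_neumann(f, grid1d.dx))) < 1e-12

    def test_matrix_matches_stencil(self, grid2d, rng):
        f = rng.normal(size=(33, 33))
        L = laplacian_matrix(grid2d)
        np.testing.assert_allclose(
            (L @ f.ravel()).reshape(33, 33),
            laplacian_neumann(f, grid2d.dx), atol=1e-10)


class TestProfiles:
    def test_ball_values(self, grid2d):
        c = c_profile_ball(grid2d, 3.0, 0.0, -1.21)
        ci = grid2d.center_index()
        assert c[ci] == 0.0
        assert c[0, 0] == -1.21

    def test_ball_area_fraction(self):
        grid = Grid(201, (-10.0, 10.0), dimension=2)
        radius = 4.0
        c = c_profile_ball(grid, radius, 1.0, 0.0)
        frac = c.sum() / c.size
        expected = np.pi * radius ** 2 / 20.0 ** 2
        # agreement within roughly one ring of cells
        ring = 2 * np.pi * radius * grid.dx / 20.0 ** 2
        assert abs(frac - expected) < 1.5 * ring

    def test_quartic_values(self):
        grid = Grid(201, (-25.0, 25.0), dimension=1)
        c = c_profile_quartic(grid, 1.21, 25.0)
        s = grid.x / 25.0
        np.testing.assert_allclose(c, 1.21 * s ** 4 - 2 * 1.21 * s ** 2)
        mid = 100
        assert c[mid] == pytest.approx(0.0, abs=1e-3)
        # monotone decreasing away from the center for p > 0
        right = c[mid:]
        assert np.all(np.diff(right) < 0)
        # border value approaches -p
        assert c[-1] == pytest.approx(-1.21, abs=0.05)


class TestSimulation:
    def test_rejects_unstable_dt(self, grid1d):
        params = NhFHNParams(eps=0.1, b=0.0, d_u=1.0, d_v=0.0)
        with pytest.raises(ValueError, match="stability bound"):
            simulate_nhfhn(params, grid1d, T=1.0,
                           dt=10 * stable_dt(params, grid1d))

    def test_homogeneous_limit_matches_ode(self, grid1d):
        """Spatially constant data: every grid point follows the
        diffusion-less planar ODE (and stays spatially homogeneous)."""
        params = NhFHNParams(eps=0.1, b=0.8, d_u=1.0, d_v=1.0,
                             cubic=Cubic.soft, I_profile=0.5, c_profile=-0.3)
        dt = 8e-4  # divides T exactly and respects the stability bound
        assert dt < stable_dt(params, grid1d)
        sol = simulate_nhfhn(params, grid1d, ic=(0.2, 0.1), T=20.0, dt=dt,
                             store_stride=50)

        def ode_rhs(y):
            u, v = y
            f = -u ** 3 / 3 + u
            return np.array([(f - v + 0.5) / 0.1, u - 0.8 * v + 0.3])

        ref = rk4_solve(ode_rhs, [0.2, 0.1], 0.0, 20.0, dt)
        # compare at stored times
        idx = np.rint(sol.times / dt).astype(int)
        err_u = np.max(np.abs(sol.u - ref.states[idx, 0][:, None]))
        err_v = np.max(np.abs(sol.v - ref.states[idx, 1][:, None]))
        assert err_u < 1e-6 and err_v < 1e-6
        assert np.max(np.ptp(sol.u, axis=1)) < 1e-9  # stays homogeneous

    def test_spatial_refinement_second_order(self):
        """Halving dx changes the final field at O(dx^2) on a smooth run."""
        params = NhFHNParams(eps=0.1, b=0.8, d_u=1.0, d_v=0.5,
                             cubic=Cubic.soft, I_profile=0.0, c_profile=0.0)
        finals = {}
        for n in (32, 64, 128):
            grid = Grid(n, (-5.0, 5.0), dimension=1)
            ic_u = np.sin(np.pi * grid.x / 5.0)
            ic_v = 0.2 * np.cos(np.pi * grid.x / 5.0)
            sol = simulate_nhfhn(params, grid, ic=(ic_u, ic_v), T=0.5,
                                 dt=2e-5, store_stride=10 ** 9)
            finals[n] = (grid.x, sol.u[-1])
        x_f, u_f = finals[128]
        e1 = np.max(np.abs(np.interp(finals[32][0], x_f, u_f) - finals[32][1]))
        e2 = np.max(np.abs(np.interp(finals[64][0], x_f, u_f) - finals[64][1]))
        assert e1 / e2 > 2.5

    def test_blowup_flag_on_divergent_reaction(self, grid1d):
        # an inverted-sign current far outside the attracting set diverges
        params = NhFHNParams(eps=0.1, b=0.0, d_u=1.0, d_v=0.0,
                             cubic=Cubic.steep, I_profile=0.0, c_profile=0.0)
        sol = simulate_nhfhn(params, grid1d, ic=(1e4, 0.0), T=5.0)
        assert sol.blew_up


class TestStationary:
    def test_b_zero_u_equals_c_exactly(self, grid1d):
        c = c_profile_quartic(grid1d, 1.21, 10.0)
        params = NhFHNParams(eps=0.1, b=0.0, d_u=1.0, d_v=0.0,
                             cubic=Cubic.steep, c_profile=c)
        u, v = stationary_solve(params, grid1d)
        assert np.array_equal(u, c)

    def test_homogeneous_matches_ode_fixed_point(self, grid1d):
        params = NhFHNParams(eps=0.1, b=0.5, d_u=1.0, d_v=0.0,
                             cubic=Cubic.soft, I_profile=0.3, c_profile=0.0)
        u, v = stationary_solve(params, grid1d)
        us, vs = fixed_point_2d(FHN2DParams(I=0.3, b=0.5, eps=0.1,
                                            cubic=Cubic.soft))
        assert np.ptp(u) == 0.0
        assert u[0] == pytest.approx(us, abs=1e-10)
        assert v[0] == pytest.approx(vs, abs=1e-10)

    def test_uniqueness_probe_two_guesses(self, grid1d):
        c = c_profile_quartic(grid1d, 1.21, 10.0)
        params = NhFHNParams(eps=0.1, b=0.5, d_u=1.0, d_v=0.0,
                             cubic=Cubic.steep, c_profile=c)
        u1, _ = stationary_solve(params, grid1d, initial_guess=np.zeros(101))
        u2, _ = stationary_solve(params, grid1d,
                                 initial_guess=np.full(101, -1.5))
        assert np.max(np.abs(u1 - u2)) < 1e-8

    def test_residual_of_solution(self, grid2d):
        c = c_profile_ball(grid2d, 3.0, 0.0, -1.21)
        params = NhFHNParams(eps=0.1, b=0.4, d_u=1.0, d_v=0.0,
                             cubic=Cubic.steep, c_profile=c)
        u, v = stationary_solve(params, grid2d)
        f = -u ** 3 + 3 * u
        res = f - u / 0.4 + c / 0.4 + laplacian_neumann(u, grid2d.dx)
        assert np.max(np.abs(res)) < 1e-9
        np.testing.assert_allclose(v, (u - c) / 0.4)

    def test_stationary_state_persists_under_simulation(self, grid1d):
        """Injecting the stationary solution as IC leaves it unchanged."""
        c = -1.5 + 0.3 * np.cos(np.pi * grid1d.x / 10.0)
        params = NhFHNParams(eps=0.1, b=0.0, d_u=1.0, d_v=0.0,
                             cubic=Cubic.steep, c_profile=c)
        u0, v0 = stationary_solve(params, grid1d)
        sol = simulate_nhfhn(params, grid1d, ic=(u0, v0), T=5.0)
        assert np.max(np.abs(sol.u[-1] - u0)) < 1e-6
        assert np.max(np.abs(sol.v[-1] - v0)) < 1e-6

    def test_requires_dv_zero(self, grid1d):
        params = NhFHNParams(eps=0.1, b=0.0, d_u=1.0, d_v=1.0)
        with pytest.raises(ValueError):
            stationary_solve(params, grid1d)


class TestDiagnostics:
    def test_homogeneous_run_has_zero_laplacian_series(self, grid1d):
        from fhrdyn.rd_simulator import local_dynamics_extract
        params = NhFHNParams(eps=0.1, b=0.8, d_u=1.0, d_v=0.0,
                             cubic=Cubic.soft, I_profile=0.5, c_profile=0.0)
        sol = simulate_nhfhn(params, grid1d, ic=(0.2, 0.1), T=5.0,
                             store_stride=100)
        out = local_dynamics_extract(sol, 50)
        assert np.max(np.abs(out["lap_u"])) < 1e-9

    def test_stationary_medium_reports_quiescence(self, grid1d):
        params = NhFHNParams(eps=0.1, b=0.0, d_u=1.0, d_v=0.0,
                             cubic=Cubic.steep, c_profile=-1.5)
        u0, v0 = stationary_solve(params, grid1d)
        sol = simulate_nhfhn(params, grid1d, ic=(u0, v0), T=20.0,
                             store_stride=20)
        rep = propagation_diagnostics(sol)
        assert rep.stationary
        assert rep.total_counts.max() == 0
        assert rep.death_spot == pytest.approx(grid1d.dx, abs=1e-9)
        assert rep.filtering_ratio == 1.0
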