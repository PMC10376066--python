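import math

import numpy as np
import pytest

from fhrdyn.canard_reduced import (
    FoldSingularityError,
    OrbitClass,
    blowup_rhs,
    classify_orbit,
    escape_threshold,
    first_integral_G,
    fold_frame,
    from_blowup_frame,
    integrate_blowup,
    orbit_diameter,
    subsystem_rhs,
    to_blowup_frame,
)
from fhrdyn.core_models import Cubic, FHRParams, cubic_eval
from fhrdyn.integrate import rk4_path3, rk4_solve


def steep_params(I=0.0, b=0.8, eps=0.01):
    return FHRParams(I=I, b=b, c=0.0, eps=eps, cubic=Cubic.steep)


class TestSubsystems:
    def setup_method(self):
        self.p = FHRParams(I=0.5, b=0.8, c=0.0, eps=0.1, cubic=Cubic.soft)

    def on_manifold(self, u, w):
        f, _ = cubic_eval(u, self.p.cubic)
        return np.array([u, f + w + self.p.I, w])

    def test_layer_equilibria_fill_critical_manifold(self):
        s = self.on_manifold(0.4, -0.2)
        np.testing.assert_allclose(subsystem_rhs("layer", s, self.p), 0.0,
                                   atol=1e-15)

    def test_layer_flow_reaches_attractive_branch(self):
        """From a generic start the fast flow lands where f'(u) < 0."""
        for u0 in (-3.0, 0.2, 3.0):
            s = np.array([u0, 0.3, 0.0])
            traj = rk4_solve(lambda y: subsystem_rhs("layer", y, self.p),
                             s, 0.0, 50.0, 1e-2)
            u_end = traj.states[-1, 0]
            _, fp = cubic_eval(u_end, self.p.cubic)
            assert fp < 0

    def test_superslow_w_equation(self):
        # superslow regime also requires the planar constraint u = b v
        s = self.on_manifold(u_star(self.p, -0.2), -0.2)
        d = subsystem_rhs("superslow", s, self.p)
        assert d[2] == pytest.approx(-(s[2] + s[0]))

    def test_reduced_fold_singularity(self):
        s = self.on_manifold(1.0, 0.0)  # fold of the soft cubic
        with pytest.raises(FoldSingularityError):
            subsystem_rhs("reduced", s, self.p)

    def test_off_manifold_rejected(self):
        with pytest.raises(ValueError):
            subsystem_rhs("reduced", np.array([0.0, 5.0, 0.0]), self.p)


def u_star(p, w):
    from fhrdyn.mmo_analysis import u_star_of_w
    return u_star_of_w(w, FHRParams(I=p.I, b=p.b, c=p.c, eps=p.eps,
                                    cubic=Cubic.soft))


class TestFoldFrame:
    def test_hand_values(self):
        fr = fold_frame(steep_params(I=0.0, b=1.0))
        assert fr.v_tilde == 1.0
        assert fr.w_tilde == -1.0
        assert fr.mu == 0.0

    def test_mu_formula(self, rng):
        for b, I in rng.uniform([0.2, 0.0], [2.0, 1.5], size=(20, 2)):
            fr = fold_frame(steep_params(I=I, b=b))
            assert fr.mu == pytest.approx(-1.0 + 1.0 / b - I, abs=1e-12)
            assert fr.mu == pytest.approx(1.0 + fr.w_tilde, abs=1e-12)

    def test_steep_expansion_about_fold(self, rng):
        """f(1 + u) - f(1) = -3u^2 - u^3 for the steep cubic."""
        for u in rng.normal(size=20):
            f1p, _ = cubic_eval(1.0 + u, Cubic.steep)
            f1, _ = cubic_eval(1.0, Cubic.steep)
            assert f1p - f1 == pytest.approx(-3 * u ** 2 - u ** 3, abs=1e-10)

    def test_requires_steep_cubic(self):
        with pytest.raises(ValueError):
            fold_frame(FHRParams(I=0.0, b=0.8, cubic=Cubic.soft))


class TestFirstIntegral:
    def test_center_value(self):
        assert first_integral_G(0.0, 0.0, 0.0) == pytest.approx(1 / 6)

    def test_zero_on_separatrix_parabola(self, rng):
        for u in rng.uniform(-2, 2, size=10):
            v = 1 / 6 - 3 * u ** 2
            assert abs(first_integral_G(u, v, 0.0)) < 1e-14

    def test_shift_in_w(self, rng):
        for u, v, w in rng.normal(size=(10, 3)):
            assert first_integral_G(u, v, w) == pytest.approx(
                first_integral_G(u, v - w, 0.0), rel=1e-12)

    def test_conserved_along_flow(self):
        traj = integrate_blowup(0.0, 0.1, 0.0, 20.0, dt=1e-4, store_stride=50)
        G = first_integral_G(traj.states[:, 0], traj.states[:, 1], 0.0)
        assert np.max(np.abs(G - G[0])) / abs(G[0]) < 1e-6

    def test_conservation_is_fourth_order(self):
        """G drift under RK4 shrinks ~2^4 per halving of dt."""
        drifts = []
        for dt in (2e-2, 1e-2, 5e-3):
            traj = integrate_blowup(0.0, 0.16, 0.0, 10.0, dt=dt)
            G = first_integral_G(traj.states[:, 0], traj.states[:, 1], 0.0)
            drifts.append(np.max(np.abs(G - G[0])))
        assert 8 < drifts[0] / drifts[1] < 40
        assert 8 < drifts[1] / drifts[2] < 40

    def test_w_constant_along_flow(self):
        traj = integrate_blowup(0.0, 0.1, 0.3, 5.0, dt=1e-3)
        assert np.all(traj.states[:, 2] == 0.3)
        np.testing.assert_allclose(blowup_rhs((0.5, -1.0, 0.3))[2], 0.0)


class TestOrbitClassification:
    def test_center_is_fixed_point(self):
        assert classify_orbit(0.0, 0.0) is OrbitClass.fixed_point
        assert classify_orbit(0.5, 0.5) is OrbitClass.fixed_point

    @pytest.mark.parametrize("method", ["analytic", "integrate"])
    def test_periodic_below_threshold(self, method):
        assert classify_orbit(0.1, 0.0, method) is OrbitClass.periodic

    @pytest.mark.parametrize("method", ["analytic", "integrate"])
    def test_escape_above_threshold(self, method):
        assert classify_orbit(0.2, 0.0, method) is OrbitClass.escape

    def test_escape_goes_to_minus_infinity(self):
        traj = integrate_blowup(0.0, 0.2, 0.0, 50.0, dt=1e-3)
        assert traj.blew_up
        assert traj.states[-1, 0] < 0
        assert traj.states[-1, 1] < 0

    def test_classifiers_agree_away_from_threshold(self):
        """Analytic (first integral) vs integration classification on a
        grid of launches at least 1e-3 from the separatrix."""
        cs = np.concatenate([np.linspace(0.02, 0.16, 15),
                             np.linspace(0.18, 0.4, 10)])
        for w in (-0.5, 0.0, 0.5):
            for dc in cs:
                a = classify_orbit(w + dc, w, "analytic")
                b = classify_orbit(w + dc, w, "integrate")
                assert a is b, (w, dc)

    def test_escape_threshold_at_one_sixth(self):
        c_star = escape_threshold(0.0, tol=1e-4)
        assert abs(c_star - 1 / 6) < 1e-4

    def test_escape_threshold_shift_invariance(self):
        c_star = escape_threshold(0.5, tol=1e-4)
        assert abs(c_star - (0.5 + 1 / 6)) < 1e-4

    def test_orbit_diameter_grows_toward_threshold(self):
        diams = [orbit_diameter(c, 0.0)
                 for c in np.linspace(0.05, 0.165, 12)]
        assert np.all(np.diff(diams) > 0)


class TestBlowupScaling:
    def test_symbolic_limit_gives_blowup_system(self):
        """Substituting u = d*u_, v = d^2*v_, w = d^2*w_, t = d*t_ with
        d = sqrt(eps) into the fold-shifted steep system and letting
        d -> 0 yields exactly u' = -3u^2 - v + w, v' = u, w' = 0."""
        import sympy as sym

        d, u, v, w, mu, b = sym.symbols("d u v w mu b", positive=True)
        eps = d ** 2
        # shifted system: eps*u' = -3u^2 - u^3 - v + w ; v' = u - b v ;
        # w' = -eps*(mu + u + w), in original time
        U, V, W = d * u, d ** 2 * v, d ** 2 * w
        # d/dt = (1/d) d/dt_  ->  multiply each rhs by d/(scale)
        du_dtbar = sym.simplify(
            ((-3 * U ** 2 - U ** 3 - V + W) / eps) * d / d)
        dv_dtbar = sym.simplify((U - b * V) * d / d ** 2)
        dw_dtbar = sym.simplify((-eps * (mu + U + W)) * d / d ** 2)
        assert sym.limit(du_dtbar, d, 0) == -3 * u ** 2 - v + w
        assert sym.limit(dv_dtbar, d, 0) == u
        assert sym.limit(dw_dtbar, d, 0) == 0

    def _roundtrip_error(self, eps, Tbar=3.0, v0=0.05):
        b = 0.8
        p = steep_params(I=1.0 / b - 1.0, b=b, eps=eps)  # mu = 0
        ref = integrate_blowup(0.0, v0, 0.0, Tbar, dt=1e-4, store_stride=10)
        _, s0 = from_blowup_frame(np.array([[0.0, v0, 0.0]]),
                                  np.array([0.0]), p)
        u0, vv0, w0 = s0[0]

        def rhs(u, v, w):
            return ((-u ** 3 + 3 * u - v + w + p.I) / eps,
                    u - b * v, -eps * (u + w))

        dt = 1e-6 if eps < 5e-3 else 1e-5
        traj = rk4_path3(rhs, (u0, vv0, w0), 0.0, Tbar * math.sqrt(eps), dt,
                         store_stride=10)
        tb, sb = to_blowup_frame(traj.states, traj.times, p)
        ub = np.interp(tb, ref.times, ref.states[:, 0])
        vb = np.interp(tb, ref.times, ref.states[:, 1])
        return max(np.max(np.abs(sb[:, 0] - ub)), np.max(np.abs(sb[:, 1] - vb)))

    def test_roundtrip_discrepancy_shrinks_with_eps(self):
        """A full-model arc near the fold, mapped into blow-up coordinates,
        converges to the blow-up trajectory as eps -> 0; the estimated
        order is consistent with the sqrt(eps) scaling."""
        e1 = self._roundtrip_error(0.01)
        e2 = self._roundtrip_error(0.001)
        assert e2 < e1
        order = math.log(e1 / e2) / math.log(10.0)
        assert 0.3 < order < 0.9
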