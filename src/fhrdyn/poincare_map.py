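"""Numerical return map on the section {u = 0, v < 0} and periodic orbits.

For small eps and small |I| the three-variable model executes relaxation
loops; the first-return (Poincare) map F on the section

    M = {(u, v, w) : u = 0, v < 0}

is well defined.  A periodic orbit is a fixed point of F, found in two
stages mirroring the slow-fast structure: the v-component of the return
is a strong contraction (the relaxation loop forgets the launch v and
returns near f(-1) + w + I), so for each w an inner fixed point
v = phi(w) of the v-return converges in a few iterations; the outer
problem is then a scalar root of F3(0, phi(w), w) - w in w, which brackets
a sign change around 0 (w' = -eps*(u + w) integrates to F3(w0) > w0 for
small w0 < 0 and F3(w0) < w0 for small w0 > 0).

Crossing orientation: departures and returns are both taken with
du/dt > 0 at u = 0 (the fast jump off the left branch of the critical
manifold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_models import Cubic, FHRParams, cubic_eval

__all__ = [
    "SectionPoint",
    "ReturnResult",
    "PeriodicOrbit",
    "return_map",
    "find_periodic_orbit",
]


@dataclass(frozen=True)
class SectionPoint:
    v: float
    w: float

    def __post_init__(self):
        if not self.v < 0:
            raise ValueError("section requires v < 0")


@dataclass(frozen=True)
class ReturnResult:
    image: SectionPoint | None
    return_time: float
    converged: bool


@dataclass(frozen=True)
class PeriodicOrbit:
    v_star: float
    w_star: float
    period: float
    residual: float


def _make_rhs(p: FHRParams):
    e, b, c, I = p.eps, p.b, p.c, p.I
    if p.cubic is Cubic.soft:
        def rhs(u, v, w):
            return ((-u * u * u / 3.0 + u - v + w + I) / e,
                    u - b * v - c,
                    e * (-u - w))
    else:
        def rhs(u, v, w):
            return ((-u * u * u + 3.0 * u - v + w + I) / e,
                    u - b * v - c,
                    e * (-u - w))
    return rhs


def _newton_crossing(rhs, state, dt_guess, tol=1e-13, max_iter=12):
    """Refine the time h in (0, dt] at which u(h) = 0 from ``state``.

    One RK4 step of trial size h from the pre-crossing state; Newton on h
    using du/dt evaluated at the step endpoint.
    """
    u0, v0, w0 = state
    h = dt_guess

    def step(h):
        a1, b1, c1 = rhs(u0, v0, w0)
        a2, b2, c2 = rhs(u0 + 0.5 * h * a1, v0 + 0.5 * h * b1, w0 + 0.5 * h * c1)
        a3, b3, c3 = rhs(u0 + 0.5 * h * a2, v0 + 0.5 * h * b2, w0 + 0.5 * h * c2)
        a4, b4, c4 = rhs(u0 + h * a3, v0 + h * b3, w0 + h * c3)
        return (u0 + h * (a1 + 2.0 * (a2 + a3) + a4) / 6.0,
                v0 + h * (b1 + 2.0 * (b2 + b3) + b4) / 6.0,
                w0 + h * (c1 + 2.0 * (c2 + c3) + c4) / 6.0)

    out = step(h)
    for _ in range(max_iter):
        du = rhs(*out)[0]
        if du == 0:
            break
        h_new = h - out[0] / du
        h_new = min(max(h_new, 0.0), dt_guess)
        if abs(h_new - h) < tol * max(1.0, abs(h)):
            h = h_new
            out = step(h)
            break
        h = h_new
        out = step(h)
    return h, out


def return_map(
    p0: SectionPoint,
    params: FHRParams,
    dt: float | None = None,
    t_budget: float | None = None,
) -> ReturnResult:
    """First return of the flow to {u = 0, v < 0}, crossing upward.

    Integrates from (0, p0.v, p0.w) with fixed-step RK4 and locates the
    next upward crossing of u = 0 with v < 0 by a Newton-refined partial
    step (the image lies on the section to near machine precision).
    Returns ``converged=False`` if no return occurs within the budget
    (default 50/eps time units).
    """
    if dt is None:
        dt = 1e-3 * params.eps / 0.1  # scales the ODE-section default with eps
    if t_budget is None:
        t_budget = 50.0 / params.eps
    rhs = _make_rhs(params)
    u, v, w = 0.0, p0.v, p0.w
    if rhs(u, v, w)[0] <= 0:
        raise ValueError("launch point does not depart with du/dt > 0")
    t = 0.0
    n = int(t_budget / dt)
    armed = False  # becomes True once u has been negative (left branch)
    for _ in range(n):
        a1, b1, c1 = rhs(u, v, w)
        a2, b2, c2 = rhs(u + 0.5 * dt * a1, v + 0.5 * dt * b1, w + 0.5 * dt * c1)
        a3, b3, c3 = rhs(u + 0.5 * dt * a2, v + 0.5 * dt * b2, w + 0.5 * dt * c2)
        a4, b4, c4 = rhs(u + dt * a3, v + dt * b3, w + dt * c3)
        un = u + dt * (a1 + 2.0 * (a2 + a3) + a4) / 6.0
        vn = v + dt * (b1 + 2.0 * (b2 + b3) + b4) / 6.0
        wn = w + dt * (c1 + 2.0 * (c2 + c3) + c4) / 6.0
        if u < 0:
            armed = True
        if armed and u < 0 <= un and vn < 0:
            h, (uc, vc, wc) = _newton_crossing(rhs, (u, v, w), dt)
            if vc < 0:
                return ReturnResult(SectionPoint(vc, wc), t + h, True)
        u, v, w = un, vn, wn
        t += dt
    return ReturnResult(None, t, False)


def _phi(w: float, params: FHRParams, dt, v0: float | None = None,
         tol: float = 1e-10, max_iter: int = 12):
    """Inner fixed point v = phi(w) of the v-component of the return map.

    The v-return is a strong contraction (the loop passes both folds,
    resetting v), so plain fixed-point iteration converges in a few steps.
    Returns (phi_w, last ReturnResult).
    """
    f_m1, _ = cubic_eval(-1.0, params.cubic)
    v = v0 if v0 is not None else f_m1 + w + params.I  # loop re-entry level
    last = None
    for _ in range(max_iter):
        res = return_map(SectionPoint(v, w), params, dt=dt)
        if not res.converged:
            raise RuntimeError(f"no return from (v={v}, w={w})")
        last = res
        if abs(res.image.v - v) < tol:
            return res.image.v, res
        v = res.image.v
    return v, last


def find_periodic_orbit(
    params: FHRParams | None = None,
    w_bracket: tuple[float, float] = (-0.05, 0.05),
    dt: float | None = None,
    w_tol: float = 1e-10,
) -> PeriodicOrbit:
    """Periodic orbit of the three-variable model as a Poincare fixed point.

    Defaults to I = 0, eps = 0.01, b = 0.8, soft cubic.  Inner stage:
    fixed point phi(w) of the v-return at each w; outer stage: brentq on
    g(w) = F3(0, phi(w), w) - w over ``w_bracket`` (g changes sign across
    the periodic orbit).  The residual is the phase-space distance between
    the section point and its image.
    """
    from scipy.optimize import brentq

    if params is None:
        params = FHRParams(I=0.0, b=0.8, c=0.0, eps=0.01, cubic=Cubic.soft)
    if dt is None:
        dt = 1e-3 * params.eps / 0.1

    cache: dict[float, tuple[float, ReturnResult]] = {}

    def g(w):
        phi_w, res = _phi(w, params, dt)
        cache[w] = (phi_w, res)
        return res.image.w - w

    lo, hi = w_bracket
    g_lo, g_hi = g(lo), g(hi)
    if g_lo * g_hi > 0:
        raise RuntimeError(
            f"outer map does not change sign on {w_bracket}: "
            f"g({lo})={g_lo:.3g}, g({hi})={g_hi:.3g}")
    w_star = brentq(g, lo, hi, xtol=w_tol)
    phi_w, res = cache.get(w_star) or _phi(w_star, params, dt)
    image = res.image
    residual = float(np.hypot(image.v - phi_w, image.w - w_star))
    return PeriodicOrbit(v_star=phi_w, w_star=w_star,
                         period=res.return_time, residual=residual)
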