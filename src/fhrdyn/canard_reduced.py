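"""Slow-fast subsystems, the fold blow-up system and its first integral.

Singular limits of the three-variable model (eps -> 0 after the three
time rescalings):

* reduced  (slow time):    0 = f(u) - v + w + I,  v' = u - b v - c,  w' = 0
* layer    (fast time):    u' = f(u) - v + w + I,  v' = 0,  w' = 0
* superslow:               constraints of the planar fixed point,  w' = -(w + u)

Near the fold (u, v) = (1, f(1)) of the steep cubic, shifting by
(1, v~, w~) with v~ = 1/b and f(1) - v~ + w~ + I = 0, then rescaling

    u = delta*u_,  v = delta^2*v_,  w = delta^2*w_,  t = delta*t_,
    delta = sqrt(eps),

and letting delta -> 0 yields the integrable blow-up system

    u' = -3 u^2 - v + w,   v' = u,   w' = 0,

whose first integral is G(u, v) = (-3u^2 - (v - w) + 1/6) * exp(6 (v - w)).
Its zero level set (the parabola v = w + 1/6 - 3u^2) separates periodic
orbits around the nonlinear center (0, w) from orbits escaping to
u, v -> -inf: a trajectory through (0, c) is periodic iff
0 < G(0, c, w) < G(0, w, w) = 1/6, i.e. launching above c = w + 1/6 escapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core_models import Cubic, FHRParams, cubic_eval
from .integrate import Trajectory, rk4_path3

__all__ = [
    "FoldFrame",
    "OrbitClass",
    "FoldSingularityError",
    "subsystem_rhs",
    "fold_frame",
    "first_integral_G",
    "blowup_rhs",
    "integrate_blowup",
    "classify_orbit",
    "escape_threshold",
    "blowup_scaling_exponents",
]


class FoldSingularityError(ArithmeticError):
    """Reduced system evaluated at a fold point f'(u) = 0, where the slow
    flow is undefined (the derivative explodes in finite time)."""


class OrbitClass(str, Enum):
    fixed_point = "fixed_point"
    periodic = "periodic"
    escape = "escape"


def subsystem_rhs(regime: str, s, p: FHRParams):
    """Derivatives of one of the three singular-limit subsystems.

    ``regime`` is "reduced", "layer" or "superslow".  For the reduced and
    superslow regimes the state must lie on the critical manifold
    v = f(u) + w + I; the slaved derivatives are obtained by
    differentiating the constraints.  At a fold (f'(u) = 0) the reduced
    flow raises :class:`FoldSingularityError`.
    """
    u, v, w = s
    f, fp = cubic_eval(u, p.cubic)
    if regime == "layer":
        return np.array([f - v + w + p.I, 0.0, 0.0])
    # both remaining regimes live on the critical manifold
    if abs(f - v + w + p.I) > 1e-8:
        raise ValueError("state is not on the critical manifold v = f(u)+w+I")
    if regime == "reduced":
        dv = u - p.b * v - p.c
        if fp == 0.0:
            raise FoldSingularityError(
                "reduced flow undefined at the fold f'(u) = 0")
        # w' = 0 and v = f(u) + w + I  ->  v' = f'(u) u'
        return np.array([dv / fp, dv, 0.0])
    if regime == "superslow":
        dw = -(w + u)
        denom = fp - 1.0 / p.b
        if denom == 0.0:
            raise FoldSingularityError(
                "superslow flow undefined where f'(u) = 1/b")
        # differentiating f(u) - u/b + w + I + c/b = 0 in time
        du = -dw / denom
        return np.array([du, du / p.b, dw])
    raise ValueError(f"unknown regime {regime!r}")


@dataclass(frozen=True)
class FoldFrame:
    """Shift that centres the steep-cubic model on its fold at u = 1.

    v_tilde = 1/b and w_tilde solve 1 - b*v_tilde = 0 and
    f(1) - v_tilde + w_tilde + I = 0; mu = 1 + w_tilde = -1 + 1/b - I
    measures the distance of the super-slow nullcline from the fold.
    """

    v_tilde: float
    w_tilde: float
    mu: float


def fold_frame(p: FHRParams) -> FoldFrame:
    if p.cubic is not Cubic.steep:
        raise ValueError("the fold frame is defined for the steep cubic")
    if p.b == 0:
        raise ValueError("fold frame requires b != 0")
    v_tilde = 1.0 / p.b
    f1, _ = cubic_eval(1.0, Cubic.steep)  # = 2
    w_tilde = v_tilde - f1 - p.I
    return FoldFrame(v_tilde, w_tilde, 1.0 + w_tilde)


def blowup_scaling_exponents() -> dict:
    """Exponents of the fold blow-up rescaling, in powers of delta = sqrt(eps).

    u = delta*u_, v = delta^2*v_, w = delta^2*w_, t = delta*t_: the unique
    power combination under which the shifted steep-cubic system converges
    to the integrable blow-up system as delta -> 0.
    """
    return {"delta": "sqrt(eps)", "u": 1, "v": 2, "w": 2, "t": 1}


def to_blowup_frame(states, times, p: FHRParams):
    """Map full-model samples near the fold into blow-up coordinates.

    With delta = sqrt(eps) and the fold frame (1, v~, w~):
    u_ = (u - 1)/delta, v_ = (v - v~)/delta^2, w_ = (w - w~)/delta^2,
    t_ = t/delta.
    """
    fr = fold_frame(p)
    d = math.sqrt(p.eps)
    states = np.asarray(states, dtype=float)
    out = np.empty_like(states)
    out[..., 0] = (states[..., 0] - 1.0) / d
    out[..., 1] = (states[..., 1] - fr.v_tilde) / d ** 2
    out[..., 2] = (states[..., 2] - fr.w_tilde) / d ** 2
    return np.asarray(times, dtype=float) / d, out


def from_blowup_frame(states, times, p: FHRParams):
    """Inverse of :func:`to_blowup_frame`."""
    fr = fold_frame(p)
    d = math.sqrt(p.eps)
    states = np.asarray(states, dtype=float)
    out = np.empty_like(states)
    out[..., 0] = 1.0 + d * states[..., 0]
    out[..., 1] = fr.v_tilde + d ** 2 * states[..., 1]
    out[..., 2] = fr.w_tilde + d ** 2 * states[..., 2]
    return np.asarray(times, dtype=float) * d, out


def first_integral_G(u, v, w=0.0):
    """G(u, v; w) = (-3u^2 - (v - w) + 1/6) * exp(6 (v - w)).

    Constant along flows of the blow-up system; G = 0 on the separatrix
    parabola v = w + 1/6 - 3u^2, G = 1/6 at the center (0, w).
    """
    s = np.asarray(v, dtype=float) - w
    return (-3.0 * np.asarray(u, dtype=float) ** 2 - s + 1.0 / 6.0) * np.exp(6.0 * s)


def blowup_rhs(s, _p=None):
    """Right-hand side of the blow-up system (w is a constant of motion)."""
    u, v, w = s
    return np.array([-3.0 * u * u - v + w, u, 0.0])


def integrate_blowup(u0, v0, w, t1, dt=1e-3, store_stride=1) -> Trajectory:
    """Fixed-step RK4 trajectory of the blow-up system (fast scalar path)."""
    def rhs3(u, v, _w):
        return (-3.0 * u * u - v + w, u, 0.0)
    return rk4_path3(rhs3, (u0, v0, w), 0.0, t1, dt, store_stride=store_stride)


def classify_orbit(
    c: float,
    w: float = 0.0,
    method: str = "analytic",
    dt: float = 1e-3,
    t_max: float = 400.0,
    return_tol: float = 1e-4,
) -> OrbitClass:
    """Classify the blow-up orbit launched at (u, v) = (0, c).

    "analytic": by the first integral -- periodic iff
    0 < G(0, c, w) < G(0, w, w), escape iff G <= 0 (c >= w + 1/6),
    fixed point at c = w.

    "integrate": by direct RK4 integration -- escape orbits trip the
    blow-up detector (u, v -> -inf); periodic orbits re-cross the
    half-line {u = 0, v > w} within ``return_tol`` of the start.
    """
    if c == w:
        return OrbitClass.fixed_point
    if method == "analytic":
        g = float(first_integral_G(0.0, c, w))
        if 0.0 < g < float(first_integral_G(0.0, w, w)):
            return OrbitClass.periodic
        return OrbitClass.escape
    if method != "integrate":
        raise ValueError("method must be 'analytic' or 'integrate'")

    u, v = 0.0, float(c)
    n = int(t_max / dt)
    thr = 1e8
    for _ in range(n):
        try:
            a1, b1 = -3.0 * u * u - v + w, u
            u2, v2 = u + 0.5 * dt * a1, v + 0.5 * dt * b1
            a2, b2 = -3.0 * u2 * u2 - v2 + w, u2
            u3, v3 = u + 0.5 * dt * a2, v + 0.5 * dt * b2
            a3, b3 = -3.0 * u3 * u3 - v3 + w, u3
            u4, v4 = u + dt * a3, v + dt * b3
            a4, b4 = -3.0 * u4 * u4 - v4 + w, u4
            un = u + dt * (a1 + 2.0 * (a2 + a3) + a4) / 6.0
            vn = v + dt * (b1 + 2.0 * (b2 + b3) + b4) / 6.0
        except OverflowError:
            return OrbitClass.escape
        if not (abs(un) <= thr and abs(vn) <= thr):
            return OrbitClass.escape
        # crossing of u = 0 above the center, i.e. a full revolution
        if u != 0.0 and ((u < 0.0 <= un) or (un <= 0.0 < u)):
            frac = u / (u - un)
            v_cross = v + frac * (vn - v)
            if v_cross > w and abs(v_cross - c) <= return_tol:
                return OrbitClass.periodic
        u, v = un, vn
    # bounded but no clean return within budget: treat as periodic-side
    # (escape orbits always blow up quickly once past the separatrix)
    return OrbitClass.periodic


def escape_threshold(
    w: float = 0.0,
    tol: float = 1e-4,
    dt: float = 1e-3,
    t_max: float = 400.0,
) -> float:
    """Bisection estimate of the periodic/escape threshold c*(w).

    Uses the integration-based classifier between a known periodic launch
    (c = w + 0.1) and a known escaping one (c = w + 0.25); the analytic
    value is w + 1/6.
    """
    lo, hi = w + 0.1, w + 0.25
    if classify_orbit(lo, w, "integrate", dt, t_max) is not OrbitClass.periodic:
        raise RuntimeError("lower bisection seed did not classify as periodic")
    if classify_orbit(hi, w, "integrate", dt, t_max) is not OrbitClass.escape:
        raise RuntimeError("upper bisection seed did not classify as escape")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if classify_orbit(mid, w, "integrate", dt, t_max) is OrbitClass.periodic:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def orbit_diameter(c: float, w: float = 0.0) -> float:
    """u-diameter of the periodic blow-up orbit through (0, c).

    From the first integral: the orbit's extreme u values at v-level of
    the widest section.  Computed numerically from the level set
    G(u, v) = G(0, c, w) by scanning v; used to exhibit the divergence of
    the diameter as c -> w + 1/6.
    """
    g0 = float(first_integral_G(0.0, c, w))
    if not 0.0 < g0 < 1.0 / 6.0:
        raise ValueError("orbit through (0, c) is not periodic")
    # on the level set: 3u^2 = 1/6 - (v - w) - g0*exp(-6(v - w))
    s = np.linspace(-60.0, 1.0 / 6.0, 200001)
    rhs = 1.0 / 6.0 - s - g0 * np.exp(-6.0 * s)
    rhs = rhs[rhs >= 0]
    return float(2.0 * np.sqrt(rhs.max() / 3.0))
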