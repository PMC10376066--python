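"""Fixed points, Jacobians, Routh-Hurwitz/Cardan classification, Hopf location.

For the three-variable model

    eps*u' = f(u) - v + w + I,   v' = u - b*v - c,   w' = eps*(-u - w)

the unique fixed point (soft cubic, b > 0, c = 0) satisfies v* = u*/b,
w* = -u*, with u* the unique real root of f(u) - (1 + 1/b)*u + I = 0.
The characteristic polynomial of the Jacobian is normalized monic,

    lambda^3 + a2*lambda^2 + a1*lambda + a0,

    a2 = eps + b - f'(u*)/eps,
    a1 = -(f'(u*) + b*f'(u*)/eps - b*eps - 1/eps - 1),
    a0 = b*u*^2 + 1,

so the Routh-Hurwitz conditions for stability read a2 > 0, a0 > 0 and
a2*a1 - a0 > 0 (a0 is always positive here).  The Hopf point I* is where
the complex-conjugate eigenvalue pair crosses the imaginary axis;
equivalently the largest I at which a2 or a2*a1 - a0 vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_models import (
    Cubic,
    FHN2DParams,
    FHRParams,
    cubic_eval,
    solve_depressed_cubic_real,
)

__all__ = [
    "FixedPoint3",
    "SpectralSummary",
    "fixed_point_3d",
    "fixed_point_2d",
    "jacobian3",
    "char_coeffs",
    "cardan_delta",
    "eig_signature",
    "hopf_locate",
    "hurwitz_stable",
]

#: tolerance on Re(lambda) when counting stable/unstable eigenvalues
REAL_PART_TOL = 1e-9


@dataclass(frozen=True)
class FixedPoint3:
    u_star: float
    v_star: float
    w_star: float
    residual: float

    def as_array(self) -> np.ndarray:
        return np.array([self.u_star, self.v_star, self.w_star])


@dataclass(frozen=True)
class SpectralSummary:
    """Jacobian spectrum at a fixed point, with both classifications.

    ``hurwitz_margin`` is a2*a1 - a0: together with a2 > 0 and a0 > 0 its
    positivity is equivalent (Routh-Hurwitz) to all eigenvalues having
    negative real part.  ``cardan_delta`` is the discriminant of the
    depressed cubic: negative iff one real root plus a complex pair.
    """

    fixed_point: FixedPoint3
    jacobian: np.ndarray
    a2: float
    a1: float
    a0: float
    cardan_delta: float
    eigenvalues: np.ndarray
    n_unstable: int
    n_stable: int
    has_complex_pair: bool
    hurwitz_margin: float

    def to_dict(self) -> dict:
        return {
            "u_star": self.fixed_point.u_star,
            "v_star": self.fixed_point.v_star,
            "w_star": self.fixed_point.w_star,
            "a2": self.a2,
            "a1": self.a1,
            "a0": self.a0,
            "cardan_delta": self.cardan_delta,
            "eigenvalues_re": [float(z.real) for z in self.eigenvalues],
            "eigenvalues_im": [float(z.imag) for z in self.eigenvalues],
            "n_unstable": self.n_unstable,
            "n_stable": self.n_stable,
            "has_complex_pair": self.has_complex_pair,
            "hurwitz_margin": self.hurwitz_margin,
        }


def _unique_real_root(coeffs: np.ndarray) -> float:
    """The unique real root of a cubic given by numpy poly coefficients."""
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9 * (1.0 + np.abs(roots.real))].real
    if len(real) == 0:
        raise ArithmeticError("no real root found")
    if len(real) > 1:
        # distinct real roots -> fixed point not unique for these parameters
        if np.ptp(real) > 1e-9:
            raise ValueError(f"fixed point not unique: real roots {sorted(real)}")
    return float(real[0])


def fixed_point_3d(p: FHRParams) -> FixedPoint3:
    """Unique fixed point of the three-variable model (requires b > 0).

    Solves f(u) - (1 + 1/b)*u + I = 0; for the soft cubic the left side is
    strictly decreasing (f' <= 1 < 1 + 1/b) so the root is unique and the
    closed-form monotone-cubic solver applies.  ``c`` shifts the recovery
    nullcline: the defining equation becomes
    f(u) - (1 + 1/b)*u + c/b + I = 0 with v* = (u* - c)/b, w* = -u*.
    """
    if p.b <= 0:
        raise ValueError("fixed_point_3d requires b > 0")
    I_eff = p.I + p.c / p.b
    if p.cubic is Cubic.soft:
        # -u^3/3 - u/b + I_eff = 0  ->  u^3 + (3/b) u - 3 I_eff = 0
        u = solve_depressed_cubic_real(3.0 / p.b, -3.0 * I_eff)
    else:
        # -u^3 + (2 - 1/b) u + I_eff = 0 -> u^3 - (2 - 1/b) u - I_eff = 0
        u = _unique_real_root(np.array([1.0, 0.0, -(2.0 - 1.0 / p.b), -I_eff]))
    f, _ = cubic_eval(u, p.cubic)
    residual = abs(f - (1.0 + 1.0 / p.b) * u + p.c / p.b + p.I)
    v = (u - p.c) / p.b
    return FixedPoint3(u, v, -u, residual)


def fixed_point_2d(p: FHN2DParams) -> tuple[float, float]:
    """Unique fixed point of the planar system: root of f(u) - u/b + I_tot = 0.

    Uniqueness holds for the soft cubic with 0 < b < 1 (f' <= 1 < 1/b).
    """
    if not 0 < p.b:
        raise ValueError("fixed_point_2d requires b > 0")
    I_tot = p.I + p.drive_w
    if p.cubic is Cubic.soft and p.b < 1:
        # -u^3/3 + (1 - 1/b) u + I_tot = 0 -> u^3 + 3(1/b - 1) u - 3 I_tot = 0
        u = solve_depressed_cubic_real(3.0 * (1.0 / p.b - 1.0), -3.0 * I_tot)
    else:
        if p.cubic is Cubic.soft:
            coeffs = np.array([-1.0 / 3.0, 0.0, 1.0 - 1.0 / p.b, I_tot])
        else:
            coeffs = np.array([-1.0, 0.0, 3.0 - 1.0 / p.b, I_tot])
        u = _unique_real_root(coeffs)
    return u, u / p.b


def jacobian3(u_star: float, p: FHRParams) -> np.ndarray:
    """Jacobian of the three-variable model at a point with u = u_star."""
    _, fp = cubic_eval(u_star, p.cubic)
    e = p.eps
    return np.array([
        [fp / e, -1.0 / e, 1.0 / e],
        [1.0, -p.b, 0.0],
        [-e, 0.0, -e],
    ])


def char_coeffs(u_star: float, p: FHRParams) -> tuple[float, float, float]:
    """Monic characteristic coefficients (a2, a1, a0) at u = u_star."""
    _, fp = cubic_eval(u_star, p.cubic)
    e, b = p.eps, p.b
    a2 = e + b - fp / e
    a1 = -(fp + b * fp / e - b * e - 1.0 / e - 1.0)
    a0 = b * u_star * u_star + 1.0
    return a2, a1, a0


def cardan_delta(a2: float, a1: float, a0: float) -> float:
    """Discriminant of the depressed cubic of lambda^3 + a2 l^2 + a1 l + a0.

    Convention: Delta = -4 p^3 - 27 q^2 for t^3 + p t + q; Delta > 0 means
    three distinct real roots, Delta < 0 means one real root and a
    complex-conjugate pair.
    """
    p = a1 - a2 * a2 / 3.0
    q = 2.0 * a2 ** 3 / 27.0 - a2 * a1 / 3.0 + a0
    return -4.0 * p ** 3 - 27.0 * q * q


def hurwitz_stable(a2: float, a1: float, a0: float) -> bool:
    """Routh-Hurwitz stability of lambda^3 + a2 l^2 + a1 l + a0."""
    return a2 > 0 and a0 > 0 and a2 * a1 - a0 > 0


def eig_signature(p: FHRParams, tol: float = REAL_PART_TOL) -> SpectralSummary:
    """Full spectral summary at the unique fixed point of the model."""
    fp = fixed_point_3d(p)
    J = jacobian3(fp.u_star, p)
    a2, a1, a0 = char_coeffs(fp.u_star, p)
    eig = np.linalg.eigvals(J)
    n_unstable = int(np.sum(eig.real > tol))
    n_stable = int(np.sum(eig.real < -tol))
    has_pair = bool(np.any(np.abs(eig.imag) > tol))
    return SpectralSummary(
        fixed_point=fp,
        jacobian=J,
        a2=a2,
        a1=a1,
        a0=a0,
        cardan_delta=cardan_delta(a2, a1, a0),
        eigenvalues=eig,
        n_unstable=n_unstable,
        n_stable=n_stable,
        has_complex_pair=has_pair,
        hurwitz_margin=a2 * a1 - a0,
    )


def _complex_pair_realpart(p: FHRParams) -> float:
    """Real part of the complex-conjugate eigenvalue pair at the fixed point.

    Falls back to the largest real part if the spectrum is entirely real
    (keeps the bisection objective continuous across the discriminant).
    """
    fp = fixed_point_3d(p)
    eig = np.linalg.eigvals(jacobian3(fp.u_star, p))
    cplx = eig[np.abs(eig.imag) > 1e-12]
    if len(cplx):
        return float(np.max(cplx.real))
    return float(np.max(eig.real))


def hopf_locate(
    p: FHRParams,
    I_bracket: tuple[float, float] = (0.5, 2.5),
    tol: float = 1e-10,
) -> float:
    """Locate the Hopf point I* of the three-variable model by bisection.

    Bisection on the real part of the complex eigenvalue pair of the
    Jacobian at the fixed point: positive (unstable) for I < I*, negative
    (stable) for I > I*.  ``p`` supplies eps, b, c and the cubic; its I
    is ignored.  Raises if the bracket does not straddle a sign change.
    """
    lo, hi = I_bracket
    if not hi > lo:
        raise ValueError("invalid bracket")

    def re_pair(I):
        return _complex_pair_realpart(
            FHRParams(I=I, b=p.b, c=p.c, eps=p.eps, cubic=p.cubic))

    f_lo, f_hi = re_pair(lo), re_pair(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no sign change of Re(lambda) on [{lo}, {hi}]: "
            f"{f_lo:.3g} and {f_hi:.3g}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = re_pair(mid)
        if f_mid == 0.0:
            return mid
        if f_mid * f_lo > 0:
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
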