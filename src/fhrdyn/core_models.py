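"""Right-hand sides and parameter records for the FitzHugh family of models.

Three ODE families are defined here and consumed everywhere else in the
package:

* the original three-variable FitzHugh-Rinzel (FHR) bursting model,
* a rotated FHR variant whose super-slow variable feeds back into the
  voltage equation (the workhorse for the mixed-mode-oscillation and
  canard analysis),
* the planar FitzHugh-Nagumo (FHN) system, optionally driven by a frozen
  value of the slow variable.

All quantities are dimensionless; time is the model's own time unit.

Variable naming: the original FHR model is usually written in the
variables (v, w, y).  Internally every three-dimensional state is stored
in the slots (u, v, w) with the map u<-v (voltage), v<-w (recovery),
w<-y (super-slow drive), so that a single ``State3`` convention serves
all models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from enum import Enum

import numpy as np

__all__ = [
    "Cubic",
    "cubic_eval",
    "FHROriginalParams",
    "FHRParams",
    "FHN2DParams",
    "fhr_rhs",
    "fhr_original_rhs",
    "fhn2d_rhs",
    "NumericalBlowUpError",
]


class NumericalBlowUpError(FloatingPointError):
    """Raised when a right-hand side is evaluated on a non-finite state."""


class Cubic(str, Enum):
    """The two cubic fast nullclines used by the model family.

    * ``soft``:  f(u) = -u**3/3 + u   (folds at u = +-1, f(1) = 2/3)
    * ``steep``: f(u) = -u**3 + 3*u   (folds at u = +-1, f(1) = 2)
    """

    soft = "soft"
    steep = "steep"


def cubic_eval(u, cubic: Cubic):
    """Evaluate the cubic nonlinearity and its derivative.

    Parameters
    ----------
    u : float or ndarray
    cubic : Cubic

    Returns
    -------
    (f, fprime) : pair of float or ndarray
    """
    cubic = Cubic(cubic)
    u2 = u * u
    if cubic is Cubic.soft:
        return -u * u2 / 3.0 + u, 1.0 - u2
    return -u * u2 + 3.0 * u, 3.0 - 3.0 * u2


def _check_finite(s) -> None:
    if not np.all(np.isfinite(s)):
        raise NumericalBlowUpError(f"non-finite state: {s!r}")


@dataclass(frozen=True)
class FHROriginalParams:
    """Parameters of the original FitzHugh-Rinzel bursting model.

    With the defaults below the model produces bursting: alternating
    trains of spikes and quiescent drifts, organised by the super-slow
    variable.

    ``literal_eps_on_v`` selects between the form with eps dividing the
    voltage equation (du/dt = (f(u)-v+w+I)/eps) and the classical
    convention without that factor.  The recovery and super-slow
    equations are dw_rec/dt = phi*(a + u - b*w_rec) and
    dy/dt = eps*(c - u - d*y) in both cases.
    """

    I: float = 0.3125
    a: float = 0.7
    b: float = 0.8
    c: float = -0.775
    d: float = 1.0
    phi: float = 0.08
    eps: float = 1e-4
    literal_eps_on_v: bool = True

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FHRParams:
    """Parameters of the FHR variant

        eps * du/dt = f(u) - v + w + I
              dv/dt = u - b*v - c
              dw/dt = eps * (-u - w)

    Defaults match the ODE analysis sections: soft cubic, b = 0.8, c = 0,
    eps = 0.1, with I the bifurcation parameter to vary.
    """

    I: float = 1.45
    b: float = 0.8
    c: float = 0.0
    eps: float = 0.1
    cubic: Cubic = Cubic.soft

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.b < 0:
            raise ValueError("b must be non-negative")
        object.__setattr__(self, "cubic", Cubic(self.cubic))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cubic"] = self.cubic.value
        return d


@dataclass(frozen=True)
class FHN2DParams:
    """Parameters of the planar FHN system

        eps * du/dt = f(u) - v + I + drive_w
              dv/dt = u - b*v

    ``drive_w`` is an additive constant standing for a frozen value of the
    super-slow variable of the three-dimensional model; with drive_w = w0
    this is exactly the frozen-w subsystem of the FHR variant (c = 0).
    """

    I: float = 0.5
    b: float = 0.8
    eps: float = 0.1
    cubic: Cubic = Cubic.soft
    drive_w: float = 0.0

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        object.__setattr__(self, "cubic", Cubic(self.cubic))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cubic"] = self.cubic.value
        return d


def fhr_rhs(s, p: FHRParams):
    """Time derivatives of the FHR variant at state ``s = (u, v, w)``."""
    _check_finite(s)
    u, v, w = s
    f, _ = cubic_eval(u, p.cubic)
    du = (f - v + w + p.I) / p.eps
    dv = u - p.b * v - p.c
    dw = p.eps * (-u - w)
    return np.array([du, dv, dw])


def fhr_original_rhs(s, p: FHROriginalParams):
    """Time derivatives of the original FHR model at ``s = (u, v, w)``.

    Slots: u is the voltage, v the recovery variable, w the super-slow
    variable (the (v, w, y) of the usual notation).
    """
    _check_finite(s)
    u, v, w = s
    f = -u * u * u / 3.0 + u
    du = f - v + w + p.I
    if p.literal_eps_on_v:
        du /= p.eps
    dv = p.phi * (p.a + u - p.b * v)
    dw = p.eps * (p.c - u - p.d * w)
    return np.array([du, dv, dw])


def fhn2d_rhs(s, p: FHN2DParams):
    """Time derivatives of the planar FHN system at ``s = (u, v)``."""
    _check_finite(s)
    u, v = s
    f, _ = cubic_eval(u, p.cubic)
    du = (f - v + p.I + p.drive_w) / p.eps
    dv = u - p.b * v
    return np.array([du, dv])


def solve_depressed_cubic_real(p: float, q: float) -> float:
    """Unique real root of t**3 + p*t + q = 0 when p > 0.

    For p > 0 the map t -> t**3 + p*t is strictly increasing, so the root
    is unique; the hyperbolic form of Cardano's formula gives it in closed
    form and is numerically robust for all magnitudes of q.
    """
    if p <= 0:
        raise ValueError("closed form requires p > 0 (monotone cubic)")
    s = math.sqrt(p / 3.0)
    arg = 1.5 * q / (p * s)
    return -2.0 * s * math.sinh(math.asinh(arg) / 3.0)
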