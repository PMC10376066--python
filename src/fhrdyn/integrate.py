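"""Fixed-step RK4 integration, extrema extraction and section crossings.

The time discretization throughout the package is the classical
fourth-order Runge-Kutta scheme with a fixed step; the final step is
shortened so the trajectory lands exactly on the requested end time.
Orbits that leave the bounded region of interest (the canard blow-up
system has genuine finite-time escape orbits) are truncated and flagged
rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Trajectory",
    "Extremum",
    "ExtremumKind",
    "rk4_solve",
    "rk4_step",
    "find_extrema",
    "section_crossings",
    "BLOWUP_THRESHOLD",
]

#: States with any component exceeding this magnitude are treated as blown
#: up: far above any bounded orbit of these models, far below overflow.
BLOWUP_THRESHOLD = 1e8


@dataclass
class Trajectory:
    """A sampled solution: strictly increasing times and one state per time.

    ``blew_up`` is set when integration was truncated because the state
    left the ball of radius ``BLOWUP_THRESHOLD`` (or became non-finite);
    ``times``/``states`` then end at the last finite sample.
    """

    times: np.ndarray
    states: np.ndarray
    blew_up: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.states):
            raise ValueError("times and states must have equal leading length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def component(self, i: int) -> np.ndarray:
        return self.states[:, i]

    def to_text(self, path, header: str = "t u v w") -> None:
        """Write as delimited text, one row per sample."""
        data = np.column_stack([self.times, self.states])
        np.savetxt(path, data, header=header)

    def to_npz(self, path) -> None:
        np.savez(path, times=self.times, states=self.states,
                 blew_up=self.blew_up)


def rk4_step(rhs: Callable, y: np.ndarray, dt: float) -> np.ndarray:
    """One classical RK4 step for an autonomous system ``y' = rhs(y)``."""
    k1 = rhs(y)
    k2 = rhs(y + 0.5 * dt * k1)
    k3 = rhs(y + 0.5 * dt * k2)
    k4 = rhs(y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def rk4_solve(
    rhs: Callable,
    y0,
    t0: float,
    t1: float,
    dt: float,
    blowup_threshold: float = BLOWUP_THRESHOLD,
) -> Trajectory:
    """Integrate ``y' = rhs(y)`` from t0 to t1 with fixed-step RK4.

    The last step is shortened to land exactly on ``t1``.  If the state
    becomes non-finite or exceeds ``blowup_threshold`` in magnitude the
    trajectory is truncated at the last good sample and flagged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    y = np.asarray(y0, dtype=float).copy()
    n_full = int((t1 - t0) / dt)
    rem = (t1 - t0) - n_full * dt
    # guard against float-roundoff producing a zero-length last step
    steps = [dt] * n_full
    if rem > 1e-12 * max(1.0, abs(t1)):
        steps.append(rem)
    times = [t0]
    states = [y.copy()]
    t = t0
    blew_up = False
    with np.errstate(over="ignore", invalid="ignore"):
        for h in steps:
            y = rk4_step(rhs, y, h)
            t += h
            if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > blowup_threshold:
                blew_up = True
                break
            times.append(t)
            states.append(y.copy())
    return Trajectory(np.array(times), np.array(states), blew_up=blew_up)


class ExtremumKind(str, Enum):
    max = "max"
    min = "min"


@dataclass(frozen=True)
class Extremum:
    time: float
    value: float
    kind: ExtremumKind
    series: str = ""


def _refine_quadratic(t: np.ndarray, x: np.ndarray, i: int) -> tuple[float, float]:
    """Three-point parabolic refinement of an interior extremum at index i."""
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    # fit x = a*(s-s*)^2 + c on the local coordinate s = t - t1
    h1, h2 = t1 - t0, t2 - t1
    denom = h1 * h2 * (h1 + h2)
    if denom == 0:
        return t1, x1
    a = (h1 * (x2 - x1) - h2 * (x1 - x0)) / denom
    b = (h1 * h1 * (x2 - x1) + h2 * h2 * (x1 - x0)) / denom
    if a == 0:
        return t1, x1
    s_star = -b / (2.0 * a)
    # do not leave the bracketing interval
    s_star = min(max(s_star, -h1), h2)
    return t1 + s_star, x1 + b * s_star + a * s_star * s_star


def find_extrema(
    t,
    x,
    min_prominence: float | None = None,
    series: str = "",
) -> list[Extremum]:
    """Interior strict local extrema of a sampled series.

    Extremum times and values are refined by a three-point parabola.
    Extrema with topographic prominence below ``min_prominence`` are
    discarded (default: 1e-3 of the series range).  The returned list is
    time-sorted and strictly alternates max/min: of any run of same-kind
    extrema only the most extreme one is kept.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.shape != x.shape or t.ndim != 1 or len(t) < 3:
        raise ValueError("need equal-length 1-D arrays with at least 3 samples")
    rng = float(np.ptp(x))
    if rng == 0.0:
        return []
    if min_prominence is None:
        min_prominence = 1e-3 * rng
    out: list[Extremum] = []
    for sign, kind in ((1.0, ExtremumKind.max), (-1.0, ExtremumKind.min)):
        idx, _ = find_peaks(sign * x, prominence=min_prominence)
        for i in idx:
            ti, xi = _refine_quadratic(t, x, i)
            out.append(Extremum(ti, xi, kind, series))
    out.sort(key=lambda e: e.time)
    # enforce alternation: within a same-kind run keep the most extreme
    cleaned: list[Extremum] = []
    for e in out:
        if cleaned and cleaned[-1].kind is e.kind:
            prev = cleaned[-1]
            better = (e.value > prev.value) if e.kind is ExtremumKind.max \
                else (e.value < prev.value)
            if better:
                cleaned[-1] = e
        else:
            cleaned.append(e)
    return cleaned


def section_crossings(
    traj: Trajectory,
    component: int,
    level: float,
    direction: str = "both",
) -> list[tuple[float, np.ndarray]]:
    """Linearly interpolated crossings of ``state[component] == level``.

    ``direction`` selects the sign of the component's derivative at the
    crossing: "up" (increasing through the level), "down", or "both".
    Samples lying exactly on the level are attributed to the following
    interval.  Returned times are sorted and strictly inside the span.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    x = traj.states[:, component] - level
    t = traj.times
    out: list[tuple[float, np.ndarray]] = []
    s0 = x[:-1]
    s1 = x[1:]
    cross = (s0 * s1 < 0) | ((s0 == 0) & (s1 != 0))
    for i in np.nonzero(cross)[0]:
        going_up = x[i + 1] > x[i]
        if direction == "up" and not going_up:
            continue
        if direction == "down" and going_up:
            continue
        frac = x[i] / (x[i] - x[i + 1])
        tc = t[i] + frac * (t[i + 1] - t[i])
        sc = traj.states[i] + frac * (traj.states[i + 1] - traj.states[i])
        sc = sc.copy()
        sc[component] = level
        out.append((float(tc), sc))
    return out


# ---------------------------------------------------------------------------
# Fast scalar path for three-dimensional systems.
#
# The Poincare-map and canard modules integrate millions of steps of small
# (2- or 3-dimensional) systems; running those through numpy arrays costs
# ~10x in interpreter overhead.  rhs callables here work on plain floats.
# ---------------------------------------------------------------------------

def rk4_path3(
    rhs3: Callable,
    y0: Sequence[float],
    t0: float,
    t1: float,
    dt: float,
    store_stride: int = 1,
    blowup_threshold: float = BLOWUP_THRESHOLD,
) -> Trajectory:
    """Fixed-step RK4 for a 3-D system with a plain-float rhs.

    ``rhs3(u, v, w) -> (du, dv, dw)``.  Mathematically identical to
    :func:`rk4_solve`; only every ``store_stride``-th sample is kept (the
    initial and final samples always are).
    """
    if dt <= 0 or t1 <= t0:
        raise ValueError("need dt > 0 and t1 > t0")
    u, v, w = (float(c) for c in y0)
    n_full = int((t1 - t0) / dt)
    rem = (t1 - t0) - n_full * dt
    times = [t0]
    states = [(u, v, w)]
    t = t0
    blew_up = False
    thr = blowup_threshold
    n_steps = n_full + (1 if rem > 1e-12 * max(1.0, abs(t1)) else 0)
    for k in range(n_steps):
        h = dt if k < n_full else rem
        try:
            a1, b1, c1 = rhs3(u, v, w)
            a2, b2, c2 = rhs3(u + 0.5 * h * a1, v + 0.5 * h * b1, w + 0.5 * h * c1)
            a3, b3, c3 = rhs3(u + 0.5 * h * a2, v + 0.5 * h * b2, w + 0.5 * h * c2)
            a4, b4, c4 = rhs3(u + h * a3, v + h * b3, w + h * c3)
            u += h * (a1 + 2.0 * (a2 + a3) + a4) / 6.0
            v += h * (b1 + 2.0 * (b2 + b3) + b4) / 6.0
            w += h * (c1 + 2.0 * (c2 + c3) + c4) / 6.0
        except OverflowError:
            blew_up = True
            break
        t = t0 + (k + 1) * dt if k < n_full else t1
        if not (abs(u) <= thr and abs(v) <= thr and abs(w) <= thr):
            blew_up = True
            break
        if (k + 1) % store_stride == 0 or k == n_steps - 1:
            times.append(t)
            states.append((u, v, w))
    return Trajectory(np.array(times), np.array(states), blew_up=blew_up)
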