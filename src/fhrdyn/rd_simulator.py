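"""Method-of-lines simulation of the non-homogeneous FHN reaction-diffusion
system and its stationary-solution solver and wave diagnostics.

The PDE, on an interval or a square with no-flux (Neumann) boundaries:

    eps*u_t = f(u) - v + I(x) + d_u * Lap(u)
        v_t = u - b*v - c(x) + d_v * Lap(v)

The excitability profile c(x) makes a central region oscillatory
(c = 0, the steep cubic's fixed point u* = 0 is unstable) and the
surround excitable (c near -1.21: stable but close to the Hopf point at
u* = -1).  Waves of depolarization then propagate outward from the core;
depending on the profile they propagate fully, die at a "death spot", or
the whole medium settles to the stationary solution.

Space: second-order central differences, cell-centred uniform grid,
ghost-point reflection at the boundary.  Time: fixed-step RK4 subject to
the explicit-diffusion constraint dt <= eps*dx^2/(4*n*d_u) (the 1/eps on
the u-equation sharpens the usual bound).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .core_models import Cubic, cubic_eval

__all__ = [
    "Grid",
    "NhFHNParams",
    "SpaceTimeSolution",
    "laplacian_neumann",
    "laplacian_matrix",
    "c_profile_ball",
    "c_profile_quartic",
    "default_initial_condition",
    "stable_dt",
    "simulate_nhfhn",
    "stationary_solve",
    "local_dynamics_extract",
    "propagation_diagnostics",
    "PropagationReport",
]


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centred grid on an interval (1D) or square (2D).

    ``extent`` is (lo, hi) per axis; points sit at lo + (i + 1/2)*dx.
    """

    npoints: int
    extent: tuple[float, float]
    dimension: int = 1

    def __post_init__(self):
        if self.dimension not in (1, 2):
            raise ValueError("only 1D and 2D grids are supported")
        if self.npoints < 3:
            raise ValueError("need at least 3 points per axis")
        lo, hi = self.extent
        if not hi > lo:
            raise ValueError("invalid extent")

    @property
    def dx(self) -> float:
        lo, hi = self.extent
        return (hi - lo) / self.npoints

    @property
    def x(self) -> np.ndarray:
        lo, _ = self.extent
        return lo + (np.arange(self.npoints) + 0.5) * self.dx

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.npoints,) * self.dimension

    @property
    def center(self) -> tuple[float, ...]:
        lo, hi = self.extent
        return (0.5 * (lo + hi),) * self.dimension

    def center_index(self):
        i = self.npoints // 2
        return i if self.dimension == 1 else (i, i)

    def radial_distance(self) -> np.ndarray:
        """Euclidean distance of each point from the domain center."""
        cx = 0.5 * (self.extent[0] + self.extent[1])
        if self.dimension == 1:
            return np.abs(self.x - cx)
        X, Y = np.meshgrid(self.x, self.x, indexing="ij")
        return np.hypot(X - cx, Y - cx)


@dataclass(frozen=True)
class NhFHNParams:
    """Reaction and diffusion parameters plus the space-dependent profiles.

    ``I_profile`` and ``c_profile`` may be scalars (homogeneous) or arrays
    on the grid.  eps is not printed with the PDE parameter sets; the
    package default 0.1 matches the ODE sections.
    """

    eps: float = 0.1
    b: float = 0.0
    d_u: float = 1.0
    d_v: float = 1.0
    cubic: Cubic = Cubic.steep
    I_profile: object = 0.0
    c_profile: object = 0.0

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.d_u < 0 or self.d_v < 0:
            raise ValueError("diffusivities must be non-negative")
        object.__setattr__(self, "cubic", Cubic(self.cubic))

    def fields_on(self, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
        I = np.broadcast_to(np.asarray(self.I_profile, float), grid.shape).copy()
        c = np.broadcast_to(np.asarray(self.c_profile, float), grid.shape).copy()
        return I, c


def laplacian_neumann(field: np.ndarray, dx: float) -> np.ndarray:
    """Second-order Laplacian with zero-flux (ghost reflection) boundaries."""
    f = np.asarray(field, dtype=float)
    out = np.zeros_like(f)
    for axis in range(f.ndim):
        upper = np.concatenate([np.take(f, range(1, f.shape[axis]), axis),
                                np.take(f, [-1], axis)], axis)
        lower = np.concatenate([np.take(f, [0], axis),
                                np.take(f, range(0, f.shape[axis] - 1), axis)],
                               axis)
        out += upper - 2.0 * f + lower
    return out / (dx * dx)


def laplacian_matrix(grid: Grid) -> sp.csr_matrix:
    """Sparse matrix of :func:`laplacian_neumann` on the flattened grid."""
    n = grid.npoints
    e = np.ones(n)
    L1 = sp.diags([e[:-1], -2.0 * e, e[:-1]], [-1, 0, 1], format="lil")
    L1[0, 0] = -1.0
    L1[-1, -1] = -1.0
    L1 = (L1 / grid.dx ** 2).tocsr()
    if grid.dimension == 1:
        return L1
    I = sp.identity(n, format="csr")
    return (sp.kron(L1, I) + sp.kron(I, L1)).tocsr()


def c_profile_ball(grid: Grid, radius: float, c_inside: float = 0.0,
                   c_outside: float = -1.21) -> np.ndarray:
    """Oscillatory ball: c = c_inside within ``radius`` of the center."""
    lo, hi = grid.extent
    if not 0 < radius < 0.5 * (hi - lo):
        raise ValueError("radius must be positive and below the half-extent")
    r = grid.radial_distance()
    return np.where(r <= radius, c_inside, c_outside)


def c_profile_quartic(grid: Grid, p: float, beta: float | None = None) -> np.ndarray:
    """Quartic well c(x) = p*(x/beta)^4 - 2*p*(x/beta)^2 on (-beta, beta).

    c(0) = 0 (oscillatory center) and c(+-beta) = -p (excitable border);
    for p > 0 it decreases monotonically in |x|.
    """
    if grid.dimension != 1:
        raise ValueError("quartic profile is defined on 1D grids")
    if beta is None:
        beta = grid.extent[1]
    s = grid.x / beta
    return p * s ** 4 - 2.0 * p * s ** 2


def default_initial_condition(params: NhFHNParams, grid: Grid):
    """Deterministic default IC: u = c(x), v = f(c) + I (the b = 0
    stationary formula with the Laplacian term dropped)."""
    I, c = params.fields_on(grid)
    f, _ = cubic_eval(c, params.cubic)
    return c.copy(), f + I


def stable_dt(params: NhFHNParams, grid: Grid) -> float:
    """Explicit-diffusion step bound dt <= eps*dx^2/(4*n*d_u)."""
    d = max(params.d_u, params.d_v * params.eps)
    if d == 0:
        return 0.1 * params.eps  # reaction-limited
    return params.eps * grid.dx ** 2 / (4.0 * grid.dimension * d)


def _reaction_dt(params: NhFHNParams, grid: Grid) -> float:
    """Step bound from the reaction stiffness |f'(u)|/eps.

    The solution stays within the union of the cubic's orbit range and the
    excitable rest states u = c(x); the local rate is bounded by the
    largest |f'| there (RK4 real-axis stability interval ~2.78, with a
    safety factor).
    """
    _, c = params.fields_on(grid)
    umax = max(2.0, float(np.max(np.abs(c))) * 1.05)
    _, fp = cubic_eval(umax, params.cubic)
    rate = max(abs(fp), 1.0) / params.eps
    return 2.0 / rate


@dataclass
class SpaceTimeSolution:
    grid: Grid
    times: np.ndarray
    u: np.ndarray  # (ntimes, *grid.shape)
    v: np.ndarray
    params: NhFHNParams
    blew_up: bool = False

    def save_npz(self, path) -> None:
        np.savez_compressed(path, times=self.times, x=self.grid.x,
                            u=self.u, v=self.v, blew_up=self.blew_up)

    def series_at(self, index) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(t, u(t), v(t)) at one grid location."""
        if self.grid.dimension == 1:
            return self.times, self.u[:, index], self.v[:, index]
        i, j = index
        return self.times, self.u[:, i, j], self.v[:, i, j]


def simulate_nhfhn(
    params: NhFHNParams,
    grid: Grid,
    ic=None,
    T: float = 100.0,
    dt: float | None = None,
    store_stride: int | None = None,
    store_every: float | None = None,
) -> SpaceTimeSolution:
    """Method-of-lines RK4 simulation of the reaction-diffusion system.

    ``store_every`` (time units) or ``store_stride`` (steps) controls
    output subsampling; default stores ~2000 frames.  Raises if ``dt``
    violates the explicit-diffusion stability bound, proposing a
    compliant value.
    """
    bound = stable_dt(params, grid)
    if dt is None:
        dt = min(0.9 * bound, _reaction_dt(params, grid))
    elif dt > bound * (1 + 1e-12):
        raise ValueError(
            f"dt={dt:g} violates the explicit stability bound "
            f"{bound:g}; use dt <= {bound:g}")
    n_steps = max(1, int(round(T / dt)))
    dt = T / n_steps
    if store_stride is None:
        if store_every is not None:
            store_stride = max(1, int(round(store_every / dt)))
        else:
            store_stride = max(1, n_steps // 2000)

    I, c = params.fields_on(grid)
    if ic is None:
        u, v = default_initial_condition(params, grid)
    else:
        u = np.array(ic[0], dtype=float)
        v = np.array(ic[1], dtype=float)
        u = np.broadcast_to(u, grid.shape).copy()
        v = np.broadcast_to(v, grid.shape).copy()

    eps, b, du_, dv_ = params.eps, params.b, params.d_u, params.d_v
    cubic = params.cubic
    dx = grid.dx

    def rhs(uf, vf):
        f, _ = cubic_eval(uf, cubic)
        dudt = (f - vf + I + du_ * laplacian_neumann(uf, dx)) / eps
        dvdt = uf - b * vf - c
        if dv_ != 0.0:
            dvdt = dvdt + dv_ * laplacian_neumann(vf, dx)
        return dudt, dvdt

    times = [0.0]
    us = [u.copy()]
    vs = [v.copy()]
    blew_up = False
    t = 0.0
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n_steps):
            k1u, k1v = rhs(u, v)
            k2u, k2v = rhs(u + 0.5 * dt * k1u, v + 0.5 * dt * k1v)
            k3u, k3v = rhs(u + 0.5 * dt * k2u, v + 0.5 * dt * k2v)
            k4u, k4v = rhs(u + dt * k3u, v + dt * k3v)
            u = u + (dt / 6.0) * (k1u + 2.0 * (k2u + k3u) + k4u)
            v = v + (dt / 6.0) * (k1v + 2.0 * (k2v + k3v) + k4v)
            t = (k + 1) * dt
            if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
                blew_up = True
                break
            if (k + 1) % store_stride == 0 or k == n_steps - 1:
                times.append(t)
                us.append(u.copy())
                vs.append(v.copy())
    return SpaceTimeSolution(grid, np.array(times), np.array(us),
                             np.array(vs), params, blew_up=blew_up)


def stationary_solve(
    params: NhFHNParams,
    grid: Grid,
    tol: float = 1e-10,
    max_iter: int = 200,
    initial_guess: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary solution of the PDE with d_u > 0, d_v = 0.

    b = 0: the recovery equation forces u = c(x) exactly and
    v = f(c) + I + d_u*Lap(u) (discrete Laplacian).

    b > 0: damped Newton on the discretized elliptic problem

        0 = f(u) - u/b + c(x)/b + I(x) + d_u*Lap(u),
        v = (u - c(x))/b,

    to residual sup-norm below ``tol``; restarts from a homogeneous guess
    if the first initial guess stalls.
    """
    if params.d_v != 0.0:
        raise ValueError("stationary solver requires d_v = 0")
    if params.d_u <= 0.0:
        raise ValueError("stationary solver requires d_u > 0")
    I, c = params.fields_on(grid)
    if params.b == 0.0:
        u = c.copy()
        f, _ = cubic_eval(u, params.cubic)
        v = f + I + params.d_u * laplacian_neumann(u, grid.dx)
        return u, v

    L = laplacian_matrix(grid) * params.d_u
    b = params.b
    I_flat, c_flat = I.ravel(), c.ravel()

    def residual(u_flat):
        f, _ = cubic_eval(u_flat, params.cubic)
        return f - u_flat / b + c_flat / b + I_flat + L @ u_flat

    guesses = []
    if initial_guess is not None:
        guesses.append(np.broadcast_to(np.asarray(initial_guess, float),
                                       grid.shape).ravel().copy())
    guesses += [c_flat.copy(), np.zeros_like(c_flat),
                np.full_like(c_flat, -1.0)]
    last_err = None
    for u_flat in guesses:
        try:
            for _ in range(max_iter):
                r = residual(u_flat)
                rn = np.max(np.abs(r))
                if rn < tol:
                    u = u_flat.reshape(grid.shape)
                    v = (u - c) / b
                    return u, v
                _, fp = cubic_eval(u_flat, params.cubic)
                J = sp.diags(fp - 1.0 / b) + L
                step = sp.linalg.spsolve(J.tocsc(), -r)
                # damping: halve until the residual norm decreases
                lam = 1.0
                for _ in range(30):
                    trial = u_flat + lam * step
                    if np.max(np.abs(residual(trial))) < rn:
                        u_flat = trial
                        break
                    lam *= 0.5
                else:
                    raise ArithmeticError("line search stalled")
            raise ArithmeticError("Newton did not converge")
        except ArithmeticError as err:
            last_err = err
    raise ArithmeticError(
        f"stationary solve failed from all initial guesses: {last_err}")


def local_dynamics_extract(sol: SpaceTimeSolution, location):
    """Per-location time series (t, u, v, Lap_u) plus the local manifold.

    Lap_u is the discrete Laplacian of the stored u-field evaluated at the
    location for every stored frame.  The returned dict also carries the
    'critical-manifold' surface v = f(u) + d_u*Lap_u as a callable, for
    plotting the local three-dimensional dynamics.
    """
    t = sol.times
    lap = np.array([laplacian_neumann(frame, sol.grid.dx) for frame in sol.u])
    if sol.grid.dimension == 1:
        u = sol.u[:, location]
        v = sol.v[:, location]
        lap_u = lap[:, location]
    else:
        i, j = location
        u = sol.u[:, i, j]
        v = sol.v[:, i, j]
        lap_u = lap[:, i, j]

    def manifold(u_val, lap_val):
        f, _ = cubic_eval(u_val, sol.params.cubic)
        return f + sol.params.d_u * lap_val

    return {"t": t, "u": u, "v": v, "lap_u": lap_u, "manifold": manifold}


@dataclass
class PropagationReport:
    """Wave-propagation diagnostics along a 1D line of cells."""

    x: np.ndarray
    large_counts: np.ndarray
    total_counts: np.ndarray
    frequencies: np.ndarray  # large-oscillation events per unit time
    center_index: int
    death_spot: float | None
    filtering_ratio: float
    stationary: bool


def _line_series(sol: SpaceTimeSolution):
    """u time series along a line through the center (middle row in 2D)."""
    if sol.grid.dimension == 1:
        return sol.grid.x, sol.u
    mid = sol.grid.npoints // 2
    return sol.grid.x, sol.u[:, mid, :]


def propagation_diagnostics(
    sol: SpaceTimeSolution,
    amplitude_threshold: float = 1.5,
    t_min: float | None = None,
) -> PropagationReport:
    """Count oscillation events per location and locate propagation failure.

    For each cell on the center line, oscillation events (adjacent
    min->max pairs of u after the transient window) are counted; events
    with peak-to-trough amplitude above ``amplitude_threshold`` count as
    large (relaxation) oscillations.  The death spot is the smallest
    distance from the center at which the large count falls below half
    the center's; ``None`` when propagation is full.  filtering_ratio is
    the total event count at the center over that at the border (inf when
    the border is quiescent, 1.0 when both are).
    """
    from .integrate import find_extrema
    from .mmo_analysis import classify_oscillations

    x, useries = _line_series(sol)
    t = sol.times
    if t_min is None:
        t_min = 0.25 * t[-1]
    mask = t >= t_min
    tm = t[mask]
    n = len(x)
    large = np.zeros(n, dtype=int)
    total = np.zeros(n, dtype=int)
    for i in range(n):
        xi = useries[mask, i]
        if np.ptp(xi) < 1e-6:
            continue
        ext = find_extrema(tm, xi, min_prominence=0.05)
        seq = classify_oscillations(ext) if len(ext) >= 2 else None
        if seq is None:
            continue
        amps = [e.amplitude for e in seq.events]
        total[i] = len(amps)
        large[i] = int(sum(a >= amplitude_threshold for a in amps))
    window = tm[-1] - tm[0]
    freqs = large / window if window > 0 else np.zeros(n)

    ci = n // 2
    center_large = large[ci]
    stationary = bool(total.max() == 0)
    death = None
    if stationary:
        dist = np.abs(x - x[ci])
        off = dist > 0
        death = float(dist[off].min()) if off.any() else None
    elif center_large > 0:
        dist = np.abs(x - x[ci])
        failing = large < 0.5 * center_large
        if failing.any() and not failing.all():
            cand = dist[failing]
            cand = cand[cand > 0]
            if cand.size:
                death = float(cand.min())
    border_total = max(total[0], total[-1])
    center_total = total[ci]
    if border_total == 0:
        ratio = float("inf") if center_total > 0 else 1.0
    else:
        ratio = center_total / border_total
    return PropagationReport(
        x=x, large_counts=large, total_counts=total, frequencies=freqs,
        center_index=ci, death_spot=death, filtering_ratio=float(ratio),
        stationary=stationary)
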