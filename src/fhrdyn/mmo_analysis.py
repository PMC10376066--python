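"""Mixed-mode-oscillation detection and the moving-focus approximation.

Two layers:

* Symbolic encoding.  A trajectory's oscillation events (adjacent
  min->max pairs of the voltage) are labelled Small / Medium / Large by
  their peak-to-trough amplitude relative to the largest event, and the
  resulting letter string is compressed into a motif such as "LLS×4 LM".

* Moving focus.  With the super-slow variable w treated as a drifting
  parameter, the planar subsystem has a fixed point u*(w) (root of
  f(u) - u/b + w + I = 0) which, in the MMO regime, is a focus.  In
  coordinates centred on the moving focus the dynamics linearize to the
  2x2 matrix

      A(u*) = [[(1 - u*^2)/eps, -1/eps], [1, -b]]          (soft cubic)

  with complex eigenvalues alpha +- i*beta where alpha = Tr(A)/2 and
  beta = 0.5*sqrt(4*det(A) - Tr(A)^2).  The number of small oscillations
  during a focus passage of duration T is the winding integral

      n_o = (1/(2*pi)) * integral_0^T beta(t) dt,

  with beta set to 0 wherever the eigenvalues are real (no rotation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_models import Cubic, FHRParams, cubic_eval, solve_depressed_cubic_real

__all__ = [
    "OscillationEvent",
    "SymbolSequence",
    "classify_oscillations",
    "motif_compress",
    "u_star_of_w",
    "focus_matrix",
    "alpha_beta",
    "transformed_rhs",
    "moving_focus_rhs",
    "count_small_oscillations",
    "alpha_sign_profile",
]

DEFAULT_THRESHOLDS = (0.3, 0.7)


@dataclass(frozen=True)
class OscillationEvent:
    time: float
    amplitude: float
    label: str  # "S", "M" or "L"


@dataclass
class SymbolSequence:
    events: list[OscillationEvent]
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS

    @property
    def string(self) -> str:
        return "".join(e.label for e in self.events)

    def to_rows(self) -> list[tuple[float, float, str]]:
        return [(e.time, e.amplitude, e.label) for e in self.events]


def classify_oscillations(
    extrema,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> SymbolSequence:
    """Label oscillation events S/M/L from an alternating extrema list.

    One event per adjacent (min, max) pair; its amplitude is max - min and
    its time the time of the max.  Labels are assigned relative to the
    largest amplitude: below thresholds[0] of it -> S, below
    thresholds[1] -> M, else L.  Classification is therefore invariant
    under uniform rescaling of the signal.
    """
    th_sm, th_ml = thresholds
    if not (0 < th_sm < th_ml < 1):
        raise ValueError("need 0 < theta_SM < theta_ML < 1")
    pairs: list[tuple[float, float]] = []
    for a, b in zip(extrema[:-1], extrema[1:]):
        if a.kind.value == "min" and b.kind.value == "max":
            pairs.append((b.time, b.value - a.value))
    if not pairs:
        return SymbolSequence([], thresholds)
    amp_max = max(amp for _, amp in pairs)
    events = []
    for t, amp in pairs:
        rel = amp / amp_max
        label = "S" if rel < th_sm else ("M" if rel < th_ml else "L")
        events.append(OscillationEvent(t, amp, label))
    return SymbolSequence(events, thresholds)


def motif_compress(seq) -> str:
    """Greedy run-length compression of a symbol string.

    At each position the smallest unit that repeats at least twice and
    maximizes covered length is emitted as "UNIT×k"; stretches with no
    repetition are emitted verbatim.  A string with no repetition at all
    compresses to itself with "×1".

    Accepts a SymbolSequence or a plain string.
    """
    s = seq.string if isinstance(seq, SymbolSequence) else str(seq)
    n = len(s)
    if n == 0:
        return ""
    tokens: list[str] = []
    plain: list[str] = []
    i = 0
    while i < n:
        best = None  # (coverage, -unit_len, unit, k)
        for L in range(1, (n - i) // 2 + 1):
            unit = s[i:i + L]
            k = 1
            while s[i + k * L:i + (k + 1) * L] == unit:
                k += 1
            if k >= 2:
                cand = (k * L, -L, unit, k)
                if best is None or cand > best:
                    best = cand
        if best is None:
            plain.append(s[i])
            i += 1
        else:
            if plain:
                tokens.append("".join(plain))
                plain = []
            _, _, unit, k = best
            tokens.append(f"{unit}×{k}")
            i += k * len(unit)
    if plain:
        tokens.append("".join(plain))
    if len(tokens) == 1 and "×" not in tokens[0]:
        return tokens[0] + "×1"
    return " ".join(tokens)


# ---------------------------------------------------------------------------
# Moving focus
# ---------------------------------------------------------------------------

def u_star_of_w(w, p: FHRParams):
    """Root u*(w) of f(u) - u/b + w + I = 0 (the frozen-w fixed point).

    For the soft cubic with 0 < b < 1 the root is unique and computed in
    closed form; works on scalars and arrays.  The recovery offset c acts
    through I + c/b as in the three-variable fixed point.
    """
    if p.cubic is not Cubic.soft:
        raise NotImplementedError("moving-focus machinery assumes the soft cubic")
    if not 0 < p.b < 1:
        raise ValueError("uniqueness of u*(w) requires 0 < b < 1")
    I_eff = p.I + p.c / p.b
    # -u^3/3 + (1 - 1/b) u + (w + I_eff) = 0
    #  -> u^3 + 3(1/b - 1) u - 3 (w + I_eff) = 0
    pc = 3.0 * (1.0 / p.b - 1.0)
    q = -3.0 * (np.asarray(w, dtype=float) + I_eff)
    if np.ndim(q) == 0:
        return solve_depressed_cubic_real(pc, float(q))
    s = np.sqrt(pc / 3.0)
    return -2.0 * s * np.sinh(np.arcsinh(1.5 * q / (pc * s)) / 3.0)


def focus_matrix(u_star, p: FHRParams) -> np.ndarray:
    """The 2x2 linearization A(u*) of the planar subsystem at the focus."""
    return np.array([
        [(1.0 - u_star * u_star) / p.eps, -1.0 / p.eps],
        [1.0, -p.b],
    ])


def alpha_beta(u_star, p: FHRParams):
    """Real and imaginary parts (alpha, beta) of A(u*)'s eigenvalues.

    beta = 0.5*sqrt(4 det A - (Tr A)^2) where the eigenvalues are complex,
    and 0 where they are real.  Vectorized over u_star.
    """
    u_star = np.asarray(u_star, dtype=float)
    tr = (1.0 - u_star * u_star) / p.eps - p.b
    det = (1.0 - p.b * (1.0 - u_star * u_star)) / p.eps
    disc = 4.0 * det - tr * tr
    alpha = 0.5 * tr
    beta = 0.5 * np.sqrt(np.maximum(disc, 0.0))
    if u_star.ndim == 0:
        return float(alpha), float(beta)
    return alpha, beta


def _correction_factor(u_star: float, p: FHRParams) -> float:
    _, fp = cubic_eval(u_star, p.cubic)
    denom = fp - 1.0 / p.b
    if abs(denom) < 1e-12:
        raise ZeroDivisionError(
            "change of variables singular: f'(u*) = 1/b along the path")
    return denom


def g_expansion(u_star, u):
    """g(u*, u) = f(u* + u) - f(u*) for the soft cubic, expanded:

        g(u*, u) = (1 - u*^2) u - u* u^2 - u^3/3.
    """
    return (1.0 - u_star * u_star) * u - u_star * u * u - u ** 3 / 3.0


def transformed_rhs(s, p: FHRParams):
    """Exact dynamics in coordinates centred on the moving focus.

    State (u, v, w): deviations from (u*(w), v*(w)) in the first two
    slots, w itself in the third.  Derived from the full model by the
    change of variables U = u*(w) + u, V = v*(w) + v:

        eps u' = g(u*, u) - v - eps^2 (u* + u + w) / (f'(u*) - 1/b)
            v' = u - b v + eps (u* + u + w) / (1 - b f'(u*))
            w' = -eps (w + u* + u)

    Trajectories, mapped back through the change of variables, coincide
    with trajectories of the full model.
    """
    u, v, w = s
    us = u_star_of_w(w, p)
    denom = _correction_factor(us, p)
    drive = us + u + w
    du = (g_expansion(us, u) - v - p.eps ** 2 * drive / denom) / p.eps
    dv = u - p.b * v + p.eps * drive / (1.0 - p.b * cubic_eval(us, p.cubic)[1])
    dw = -p.eps * (w + us + u)
    return np.array([du, dv, dw])


def moving_focus_rhs(s, p: FHRParams):
    """Linearized moving-focus model:

        eps u' = (1 - u*^2) u - v,   v' = u - b v,   w' = -eps (w + u* + u)

    with u* = u*(w).  Keeps only the linear part of g; mimics the small
    oscillations of the full model during a focus passage.
    """
    u, v, w = s
    us = u_star_of_w(w, p)
    du = ((1.0 - us * us) * u - v) / p.eps
    dv = u - p.b * v
    dw = -p.eps * (w + us + u)
    return np.array([du, dv, dw])


def focus_coordinates(w, p: FHRParams):
    """The frozen-w fixed point (u*(w), v*(w)) of the planar subsystem."""
    us = u_star_of_w(w, p)
    return us, (us - p.c) / p.b


def count_small_oscillations(times, u_star_path, p: FHRParams) -> float:
    """Winding-number estimate of the number of small oscillations.

    Composite-trapezoid quadrature of beta(t)/(2*pi) along the sampled
    focus path; beta is zero wherever the local eigenvalues are real.
    Accepts a callable u_star_path(t) or an array sampled at ``times``.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return 0.0
    us = u_star_path(times) if callable(u_star_path) else np.asarray(u_star_path)
    _, beta = alpha_beta(us, p)
    if times.size == 1:
        return 0.0
    return float(np.trapezoid(beta, times) / (2.0 * np.pi))


def alpha_sign_profile(times, u_star_path, p: FHRParams):
    """Partition of the time span by the sign of alpha(u*(t)).

    Returns a list of (t_start, t_end, sign) with sign in {-1, 0, +1};
    alpha < 0 means shrinking oscillations, alpha > 0 growing ones.
    """
    times = np.asarray(times, dtype=float)
    us = u_star_path(times) if callable(u_star_path) else np.asarray(u_star_path)
    alpha, _ = alpha_beta(us, p)
    alpha = np.atleast_1d(alpha)
    signs = np.sign(alpha).astype(int)
    out = []
    start = 0
    for i in range(1, len(signs)):
        if signs[i] != signs[start]:
            out.append((float(times[start]), float(times[i - 1]), int(signs[start])))
            start = i
    out.append((float(times[start]), float(times[-1]), int(signs[start])))
    return out
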