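# Methods

This note records the models implemented by `fhrdyn`, the numerical
choices behind them, and the design decisions taken where more than one
reasonable convention exists.  All quantities are dimensionless; time is
the model's own unit.

## Models

**FitzHugh–Rinzel (original form).**  A planar FitzHugh–Nagumo (FHN)
oscillator plus a super-slow drive:

    eps*u' = f(u) - v + w + I        f(u) = -u^3/3 + u
        v' = phi*(a + u - b*v)
        w' = eps*(c - u - d*w)

with defaults I = 0.3125, a = 0.7, b = 0.8, c = -0.775, d = 1, phi = 0.08,
eps = 1e-4 (the bursting regime).  Two conventions coexist in the
literature for the placement of eps on the voltage equation; the
`literal_eps_on_v` flag selects between them (default: eps divides the
voltage equation).  The classical convention is the same system without
the 1/eps factor, which changes the time scale of the fast dynamics but
not the bursting mechanism.

**FHR variant.**  The workhorse of the analysis modules:

    eps*u' = f(u) - v + w + I,   v' = u - b*v - c,   w' = eps*(-u - w)

with the soft cubic, b = 0.8, c = 0, eps = 0.1, and I the bifurcation
parameter.  The fixed point is unique for b > 0 (the defining map
f(u) - (1 + 1/b)u + I is strictly decreasing for the soft cubic) and is
computed in closed form by the hyperbolic Cardano formula for monotone
depressed cubics; the same solver serves the frozen-w focus path u*(w).

**Two cubics.**  The ODE analysis uses f(u) = -u^3/3 + u ("soft"); the
fold/blow-up computation and the PDE use f(u) = -u^3 + 3u ("steep").
The steep cubic is the one for which the expansion about the fold u = 1
is exactly f(1 + u) - f(1) = -3u^2 - u^3.  The `Cubic` enum makes the
choice explicit everywhere; there is no silent default conversion.

## Stability and Hopf location

The characteristic polynomial of the Jacobian at the fixed point is
normalized monic, lambda^3 + a2 lambda^2 + a1 lambda + a0, with

    a2 = eps + b - f'(u*)/eps
    a1 = -(f'(u*) + b f'(u*)/eps - b eps - 1/eps - 1)
    a0 = b u*^2 + 1  (> 0 always)

so the Routh–Hurwitz conditions take their standard form (a2 > 0, a0 > 0,
a2 a1 - a0 > 0).  The Cardan discriminant convention is
Delta = -4p^3 - 27q^2 for the depressed cubic t^3 + pt + q: Delta < 0
means one real root plus a complex-conjugate pair.

The Hopf point I* is located by bisection on the real part of the
complex-conjugate eigenvalue pair (tolerance 1e-10 in I; eigenvalue real
parts counted with tolerance 1e-9).  Two independent routes — eigenvalue
bisection and a Brent root of the Hurwitz margin a2 a1 - a0 — agree to
1e-10 and give I* = 1.5006917... for the default parameters.  For the
planar system the Hopf condition f'(u*) = b*eps gives
u* = sqrt(1 - b*eps) for the soft cubic (the square root is forced by
f'(u) = 1 - u^2).

## Mixed-mode oscillations

Oscillation events are adjacent (min, max) pairs of the voltage, with
peak-to-trough amplitude.  Labels S/M/L are assigned relative to the
largest event with thresholds (0.3, 0.7); these cutoffs are a package
choice (the amplitude bands of the two MMO mechanisms are widely
separated, so the encoding is insensitive to the exact values) and are
configurable.  Motif compression greedily emits the smallest unit that
repeats at least twice and covers the most symbols ("LLSLLSLLSLLSLM" ->
"LLS×4 LM").

The moving-focus machinery centres coordinates on the frozen-w fixed
point (u*(w), u*(w)/b).  Two forms are provided: the exact transformed
system (whose trajectories, mapped back, coincide with the full flow to
integration accuracy — this is tested at 1e-10), and the linearized
moving-focus model that keeps only the linear part of
g(u*, u) = f(u* + u) - f(u*).  The transformed system was re-derived from
the change of variables; the correction terms are

    eps*u' = g(u*, u) - v - eps^2 (u* + u + w)/(f'(u*) - 1/b)
        v' = u - b*v + eps (u* + u + w)/(1 - b f'(u*))

(the derivative of the focus path is du*/dw = -1/(f'(u*) - 1/b), which is
where the denominators originate; the change of variables is singular
where f'(u*) = 1/b and the implementation raises there).

Small-oscillation counting uses the winding integral
n_o = (1/2π) ∫ β(t) dt with β = ½ sqrt(4 det A - (Tr A)^2) on the
stretches where the local eigenvalues are complex and β = 0 elsewhere;
quadrature is the composite trapezoid on the solver grid.  The count is
validated against directly counted maxima (agreement within ±1 on focus
passages).

## Fold blow-up and canards

Near the fold (1, f(1)) of the steep cubic the system is shifted by
(1, v~, w~) with v~ = 1/b, f(1) - v~ + w~ + I = 0, and
mu = 1 + w~ = -1 + 1/b - I.  The blow-up rescaling is

    u = delta*u_,  v = delta^2*v_,  w = delta^2*w_,  t = delta*t_,
    delta = sqrt(eps)

— the unique power combination under which the shifted system converges
(as delta -> 0) to the integrable limit u' = -3u^2 - v + w, v' = u,
w' = 0.  This is verified symbolically in the test suite, and a
round-trip test maps full-model arcs near the fold into blow-up
coordinates: the discrepancy against the blow-up trajectory decays at the
sqrt(eps) rate implied by the first neglected term (-delta*u^3).

The first integral G(u, v) = (-3u^2 - (v - w) + 1/6) e^{6(v - w)} is
constant along blow-up flows (drift is pure RK4 error, fourth-order in
dt and below 1e-6 per revolution at dt = 1e-4).  Orbit classification at
launch (0, c): fixed point at c = w; periodic iff
0 < G(0, c, w) < G(0, w, w) = 1/6; escape otherwise (c >= w + 1/6), with
u, v -> -inf.  The integration-based classifier detects escape via the
blow-up guard |state| > 1e8 (far above any bounded orbit, far below
overflow) and periodicity via a return to the launch point on the
half-line {u = 0, v > w} within 1e-4; the bisection between a periodic
and an escaping seed reproduces the analytic threshold to the requested
tolerance (1e-4 by default).

## Poincaré map and the relaxation periodic orbit

The return map is computed on M = {u = 0, v < 0} with departures and
returns both taken in the du/dt > 0 direction (the jump off the left
branch); the abstract construction does not fix an orientation, so this
is a package convention.  Crossings are refined by Newton iteration
on a partial RK4 step, placing the image on the section to near machine
precision.  The return-time budget is 50/eps time units (one relaxation
loop is O(1)).

The periodic-orbit finder mirrors the slow-fast structure: the v-return
is a strong contraction (the loop passes both folds and re-enters near
v = f(-1) + w + I), so the inner fixed point phi(w) converges by plain
iteration (tolerance 1e-10); the outer equation F3(0, phi(w), w) = w is
solved by Brent's method on a bracket around w = 0, where the map
provably changes sign.  At I = 0, eps = 0.01, b = 0.8 the orbit found is
(v*, w*) = (-0.70421, 0.00781) with period 2.0718 and section residual
at round-off level; its period matches the frozen-w planar relaxation
period to within 10%.

## Reaction-diffusion simulation

Space is a uniform cell-centred grid (interval or square) with the
standard second-order Laplacian and ghost-point reflection (no-flux);
time stepping is classical RK4 under the explicit-diffusion bound
dt <= eps*dx^2/(4*n*d_u) (the 1/eps on the voltage equation sharpens the
usual constraint; the bound is enforced with an error suggesting a
compliant step).  The default step additionally respects the reaction
stiffness |f'(u)|/eps evaluated at the largest rest state |c(x)| on the
grid — relevant when the excitability well is deep.  The default initial
condition is the deterministic rest profile u = c(x),
v = f(c) + I (the b = 0 stationary formula with the Laplacian dropped).

The stationary solver handles d_u > 0, d_v = 0: at b = 0 the recovery
equation pins u = c(x) exactly and v = f(c) + I + d_u*Lap(u) with the
same discrete Laplacian as the simulator (so the state is an exact
discrete equilibrium); for b > 0 a damped Newton iteration on the
discretized elliptic problem converges to residual sup-norm 1e-10, with
homogeneous restart guesses as a fallback.  Uniqueness is probed by
converging from distinct initial guesses.

**Parameter sets.**  The two wave experiments use b = 0, the steep cubic,
I = 0 and eps = 0.1 (eps is not part of the printed PDE parameter sets;
0.1 matches the ODE analysis and keeps the fast/slow separation).  The
oscillatory-ball experiment uses d_u = d_v = 1, c = 0 inside a ball at
the centre and c0 = -1.21 outside — the surround is excitable and close
to its Hopf point at u* = -1.  The quartic-well experiment uses
d_u = 1, d_v = 0 and c(x) = p(x/β)^4 - 2p(x/β)^2, taken with p > 0 so
the well decreases from 0 at the centre (oscillatory) to -p at the
border.

**Domain sizes.**  Grids and run lengths are package choices.  The 2D
preset uses a 64×64 grid on a square of side 40 with ball radius 5 and
T = 80: large enough for several relaxation wavelengths between core and
border, small enough to run in seconds.  The 1D quartic preset uses 25
cells on (-3, 3) with T = 80 and the sweep p ∈ {1.05, 2, 15}: this
compact domain is chosen deliberately, because the stationary regime
requires the oscillatory core (where c > -1) to be narrower than the
critical width of the localized unstable mode of d∂xx + f'(c(x)) — the
linearization at b = 0 is unstable iff that Schrödinger-type operator
has a positive eigenvalue, a condition independent of eps.  On wide
domains that requires extremely deep (and numerically stiff) wells, so
the full propagation → death spot → stationary path is demonstrated on a
domain where all three regimes occur at moderate p.  Larger domains are
available through scenario overrides.

**Diagnostics.**  Per-cell oscillation events are counted after a
transient window (first quarter of the run discarded); events with
peak-to-trough amplitude above 1.5 count as large relaxation events (the
steep-cubic relaxation amplitude is ~3.5, the focus-type small
oscillations are well below 1).  The death spot is the smallest distance
from the centre at which the large-event count falls below half the
centre's count; the filtering ratio is the total event count at the
centre over that at the border.

## What the presets do and do not show

The preset experiments reproduce the qualitative phenomena — the MMO
signature of the fixed point, symbolic motifs with repeated LLS blocks
and a single M per cycle (seen near I = 1.3 in the scan), frequency
filtering by the excitable surround (2:1 in the 2D preset), death spots
and the stationary collapse — not any particular published waveform:
initial conditions, grids and run lengths for the original figures are
not part of the model definition, so exact traces are not reproducible
and are not targeted.  Oscillation counts depend on the run length and
transient window and are reported as raw counts, not rates, except for
the per-cell frequency estimate.

## Known limitations

* The reduced (slow) subsystem is undefined at folds; the implementation
  raises rather than regularizing (the desingularized flow is out of
  scope).
* The stationary solver covers d_v = 0 only; simultaneous d_u, d_v > 0
  stationary theory is not implemented.
* 3D domains, damaged-tissue geometries and spiral-wave studies are out
  of scope.
* The S/M/L thresholds are amplitude heuristics; signals whose amplitude
  bands are not well separated may be encoded ambiguously.
* `find_periodic_orbit` assumes the relaxation regime (small eps, small
  |I|); it reports a bracketing failure otherwise instead of attempting
  continuation.
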