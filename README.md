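# fhrdyn

Slow-fast dynamical-systems toolkit for the FitzHugh–Rinzel (FHR) family of
neuron models and for non-homogeneous FitzHugh–Nagumo (Nh-FHN)
reaction-diffusion media.

## What it is for

Excitable-cell models built on a cubic fast nullcline produce a remarkable
range of dynamics once a super-slow variable or a space-dependent
excitability is added: bursting, mixed-mode oscillations (MMOs), canard
segments that track the repulsive branch of the critical manifold, and —
in spatially extended tissue — waves that propagate, filter out the small
oscillations of their oscillatory core, or die at a fixed location
("death spots").  `fhrdyn` implements these models together with the
analysis machinery used to characterize them:

* **Models** (`core_models`): the original FHR system

  `eps*u' = f(u) - v + w + I,  v' = phi*(a + u - b*v),  w' = eps*(c - u - d*w)`

  with `f(u) = -u^3/3 + u`; a rotated variant whose super-slow variable
  feeds back into the voltage equation (`eps*u' = f(u) - v + w + I`,
  `v' = u - b*v - c`, `w' = eps*(-u - w)`); and the planar FHN system.
  Two cubics are supported: the soft `-u^3/3 + u` (ODE analysis) and the
  steep `-u^3 + 3u` (PDE and fold analysis).

* **Integration** (`integrate`): fixed-step classical RK4, prominence-
  filtered extrema extraction, and interpolated Poincaré-section crossings.

* **Stability** (`stability`): unique fixed point `v* = u*/b, w* = -u*`
  with `u*` the root of `f(u) - (1 + 1/b)u + I = 0`; the Jacobian, its
  monic characteristic coefficients `(a2, a1, a0)` with
  `a0 = b*u*^2 + 1`, the Cardan discriminant, Routh–Hurwitz stability
  (`a2 > 0, a0 > 0, a2*a1 - a0 > 0`), and bisection location of the Hopf
  point `I*`.

* **MMO analysis** (`mmo_analysis`): S/M/L symbolic encoding of
  oscillation events with motif compression (e.g. `LLS×4 LM`); the exact
  change of variables onto the moving focus `u*(w)`; its linearization
  `A = [[(1 - u*^2)/eps, -1/eps], [1, -b]]`; and the winding-number
  estimate of the number of small oscillations,
  `n_o = (1/2π) ∫ β(t) dt` with `β = ½√(4 det A - (Tr A)^2)`.

* **Canard/fold machinery** (`canard_reduced`): the reduced, layer and
  super-slow singular limits; the fold blow-up system
  `u' = -3u^2 - v + w, v' = u, w' = 0` with first integral
  `G(u, v) = (-3u^2 - (v - w) + 1/6) e^{6(v - w)}`, whose zero level set
  separates periodic canard loops from orbits escaping to `u, v → -∞`
  (threshold `c* = w + 1/6` for launches at `(0, c)`).

* **Periodic orbits** (`poincare_map`): the return map on
  `M = {u = 0, v < 0}` and a two-stage fixed-point construction (inner
  contraction in `v`, outer scalar root in `w`) that finds the relaxation
  periodic orbit at small `I`.

* **Reaction-diffusion** (`rd_simulator`): method-of-lines RK4 for

  `eps*u_t = f(u) - v + I(x) + d_u Δu,  v_t = u - b*v - c(x) + d_v Δv`

  on intervals and squares with no-flux boundaries, the stationary-state
  solver (exact `u = c(x)` branch at `b = 0`, damped Newton for `b > 0`),
  and wave diagnostics: per-cell oscillation counts, frequency filtering
  ratio, and death-spot location.

## Worked example

```python
from fhrdyn import FHRParams, stability

p = FHRParams(I=1.45, b=0.8, c=0.0, eps=0.1)   # soft cubic by default
s = stability.eig_signature(p)
print(s.fixed_point.u_star)     # 0.9391272735920216
print(s.eigenvalues)            # [ 0.2247+3.1691j  0.2247-3.1691j -0.1690+0.j ]
print(s.n_unstable, s.n_stable) # 2 1
print(stability.hopf_locate(p, (0.5, 2.5)))    # 1.5006917231658008
```

At `I = 1.45` the fixed point has an unstable complex pair and one stable
real eigenvalue — the signature of the MMO window — and the oscillation
dies in a Hopf bifurcation at `I* ≈ 1.5007`, inside the interval `(1, 2)`.

The same analysis from the command line, together with the MMO encoding
and the canard threshold:

```bash
$ fhrdyn run fig2-mmo          # "motif": "SSSSSSSSL×7": 8 small
                               # oscillations per large relaxation event
$ fhrdyn threshold --w 0.0
c* = 0.166687  (analytic 0.166667)
$ fhrdyn run theorem1-periodic-orbit
# v_star = -0.70421, w_star = 0.00781, period = 2.0718, residual < 1e-12
$ fhrdyn pde --preset ball2d-filtering
# "filtering_ratio": 2.17 — the oscillatory core fires 13 times while the
# excitable border fires 6 times, all of them large relaxation events
$ fhrdyn list                  # all presets
```

The `fig2-mmo` motif shows the focus mechanism: small oscillations whose
amplitudes first shrink and then grow (a dynamic Hopf passage) before each
large relaxation excursion.  The `quartic1d-deathspot` preset sweeps the
depth `p` of the quartic excitability well `c(x) = p(x/β)^4 - 2p(x/β)^2`
and reports the regime at each depth: full propagation, a death spot at a
finite distance from the core, or global convergence to the stationary
state.

## Layout

```
src/fhrdyn/        library modules (see module docstrings)
tests/             pytest suite (unit, property and end-to-end checks)
scripts/           acceptance script
docs/methods.md    modelling and numerical-methods note
```
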