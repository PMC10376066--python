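"""Preset scenario registry tying the analysis modules together.

Each scenario resolves to concrete parameters with no user input, runs a
simulation and/or analysis, and returns a flat JSON-serializable summary
(plus optional artifact files).  All computations are deterministic; the
resolved configuration is echoed in the summary for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import canard_reduced, mmo_analysis, poincare_map, rd_simulator, stability
from .core_models import Cubic, FHN2DParams, FHROriginalParams, FHRParams
from .integrate import find_extrema, rk4_path3

__all__ = ["Scenario", "SCENARIOS", "list_scenarios", "run_scenario"]


@dataclass(frozen=True)
class Scenario:
    name: str
    description: str
    defaults: dict
    runner: Callable


def _mmo_summary(I: float, eps: float, b: float, T: float, dt: float,
                 transient: float, thresholds) -> dict:
    """Simulate the three-variable model and encode its oscillations."""
    p = FHRParams(I=I, b=b, c=0.0, eps=eps, cubic=Cubic.soft)
    fp = stability.fixed_point_3d(p)

    def rhs(u, v, w):
        return ((-u * u * u / 3.0 + u - v + w + I) / eps,
                u - b * v,
                eps * (-u - w))

    # start off the fixed point, on the left branch
    y0 = (fp.u_star - 2.0, fp.v_star, fp.w_star)
    traj = rk4_path3(rhs, y0, 0.0, T, dt, store_stride=5)
    keep = traj.times >= transient
    t, u = traj.times[keep], traj.states[keep, 0]
    ext = find_extrema(t, u, min_prominence=0.01)
    seq = mmo_analysis.classify_oscillations(ext, thresholds)
    return {
        "I": I,
        "symbols": seq.string,
        "motif": mmo_analysis.motif_compress(seq),
        "n_events": len(seq.events),
        "amplitudes": [round(e.amplitude, 4) for e in seq.events],
    }


def _run_fig2_mmo(cfg: dict, out_dir: Path | None) -> dict:
    s = _mmo_summary(cfg["I"], cfg["eps"], cfg["b"], cfg["T"], cfg["dt"],
                     cfg["transient"], tuple(cfg["thresholds"]))
    s["labels_present"] = sorted(set(s["symbols"]))
    return s


def _run_motif_scan(cfg: dict, out_dir: Path | None) -> dict:
    """Scan I over the MMO window and report the motif at each value."""
    rows = []
    for I in np.arange(cfg["I_start"], cfg["I_stop"] + 1e-12, cfg["I_step"]):
        s = _mmo_summary(float(I), cfg["eps"], cfg["b"], cfg["T"], cfg["dt"],
                         cfg["transient"], tuple(cfg["thresholds"]))
        rows.append({"I": round(float(I), 6), "motif": s["motif"],
                     "symbols": s["symbols"]})
    return {"scan": rows}


def _run_fig4_signature(cfg: dict, out_dir: Path | None) -> dict:
    out = {}
    for I in cfg["I_values"]:
        p = FHRParams(I=I, b=cfg["b"], c=0.0, eps=cfg["eps"], cubic=Cubic.soft)
        out[f"I={I}"] = stability.eig_signature(p).to_dict()
    return out


def _run_hopf(cfg: dict, out_dir: Path | None) -> dict:
    p = FHRParams(I=1.0, b=cfg["b"], c=0.0, eps=cfg["eps"], cubic=Cubic.soft)
    I_star = stability.hopf_locate(p, tuple(cfg["bracket"]))
    return {"I_star": I_star, "bracket": list(cfg["bracket"]),
            "eps": cfg["eps"], "b": cfg["b"]}


def _run_prop7_threshold(cfg: dict, out_dir: Path | None) -> dict:
    w = cfg["w"]
    c_star = canard_reduced.escape_threshold(w, tol=cfg["tol"])
    g_at = float(canard_reduced.first_integral_G(0.0, c_star, w))
    return {"w": w, "c_star": c_star, "analytic": w + 1.0 / 6.0,
            "G_at_threshold": g_at}


def _run_canard_sweep(cfg: dict, out_dir: Path | None) -> dict:
    w = cfg["w"]
    table = []
    for c in np.arange(cfg["c_start"], cfg["c_stop"] + 1e-12, cfg["c_step"]):
        cls = canard_reduced.classify_orbit(float(c), w, method="analytic")
        table.append({"c": round(float(c), 6), "class": cls.value})
    thr = canard_reduced.escape_threshold(w, tol=cfg["tol"])
    return {"w": w, "classification": table, "threshold_estimate": thr}


def _run_periodic_orbit(cfg: dict, out_dir: Path | None) -> dict:
    p = FHRParams(I=cfg["I"], b=cfg["b"], c=0.0, eps=cfg["eps"],
                  cubic=Cubic.soft)
    orbit = poincare_map.find_periodic_orbit(p, tuple(cfg["w_bracket"]))
    return {"v_star": orbit.v_star, "w_star": orbit.w_star,
            "period": orbit.period, "residual": orbit.residual}


def _run_fhr_original(cfg: dict, out_dir: Path | None) -> dict:
    p = FHROriginalParams(literal_eps_on_v=cfg["literal_eps_on_v"])

    def rhs(u, v, w):
        du = -u * u * u / 3.0 + u - v + w + p.I
        if p.literal_eps_on_v:
            du /= p.eps
        return (du, p.phi * (p.a + u - p.b * v), p.eps * (p.c - u - p.d * w))

    traj = rk4_path3(rhs, (0.0, 0.0, 0.0), 0.0, cfg["T"], cfg["dt"],
                     store_stride=cfg["store_stride"])
    if out_dir is not None:
        traj.to_text(out_dir / "fhr_original_trajectory.txt")
    u = traj.states[:, 0]
    return {"T": cfg["T"], "dt": cfg["dt"], "u_min": float(u.min()),
            "u_max": float(u.max()), "n_samples": len(u),
            "literal_eps_on_v": p.literal_eps_on_v}


def _run_ball2d(cfg: dict, out_dir: Path | None) -> dict:
    grid = rd_simulator.Grid(cfg["npoints"], (-cfg["half_side"],
                                              cfg["half_side"]), dimension=2)
    params = rd_simulator.NhFHNParams(
        eps=cfg["eps"], b=0.0, d_u=1.0, d_v=1.0, cubic=Cubic.steep,
        I_profile=0.0,
        c_profile=rd_simulator.c_profile_ball(grid, cfg["radius"],
                                              0.0, cfg["c0"]))
    sol = rd_simulator.simulate_nhfhn(params, grid, T=cfg["T"],
                                      store_every=cfg["store_every"])
    report = rd_simulator.propagation_diagnostics(
        sol, amplitude_threshold=cfg["amplitude_threshold"])
    if out_dir is not None:
        sol.save_npz(out_dir / "ball2d_solution.npz")
    return {
        "filtering_ratio": report.filtering_ratio,
        "center_total": int(report.total_counts[report.center_index]),
        "center_large": int(report.large_counts[report.center_index]),
        "border_total": int(report.total_counts[0]),
        "border_large": int(report.large_counts[0]),
        "death_spot": report.death_spot,
        "stationary": report.stationary,
    }


def _quartic_run(p_val: float, cfg: dict):
    grid = rd_simulator.Grid(cfg["npoints"], (-cfg["beta"], cfg["beta"]),
                             dimension=1)
    params = rd_simulator.NhFHNParams(
        eps=cfg["eps"], b=0.0, d_u=1.0, d_v=0.0, cubic=Cubic.steep,
        I_profile=0.0,
        c_profile=rd_simulator.c_profile_quartic(grid, p_val, cfg["beta"]))
    sol = rd_simulator.simulate_nhfhn(params, grid, T=cfg["T"],
                                      store_every=cfg["store_every"])
    return rd_simulator.propagation_diagnostics(
        sol, amplitude_threshold=cfg["amplitude_threshold"])


def _run_quartic1d(cfg: dict, out_dir: Path | None) -> dict:
    rows = []
    for p_val in cfg["p_values"]:
        rep = _quartic_run(float(p_val), cfg)
        if rep.stationary:
            regime = "stationary"
        elif rep.death_spot is None:
            regime = "full_propagation"
        else:
            regime = "death_spot"
        rows.append({"p": float(p_val), "regime": regime,
                     "death_spot": rep.death_spot,
                     "center_large": int(rep.large_counts[rep.center_index]),
                     "border_large": int(rep.large_counts[0])})
    return {"sweep": rows}


SCENARIOS: dict[str, Scenario] = {}


def _register(name, description, defaults, runner):
    SCENARIOS[name] = Scenario(name, description, defaults, runner)


_register(
    "fhr-original-bursting",
    "Original FitzHugh-Rinzel model at its bursting parameter set",
    {"literal_eps_on_v": True, "T": 2.0, "dt": 1e-5, "store_stride": 100},
    _run_fhr_original)
_register(
    "fig2-mmo",
    "Mixed-mode oscillations of the three-variable model at I=1.45",
    {"I": 1.45, "eps": 0.1, "b": 0.8, "T": 200.0, "dt": 1e-3,
     "transient": 60.0, "thresholds": [0.3, 0.7]},
    _run_fig2_mmo)
_register(
    "canard-motif-scan",
    "Scan I over the MMO window and report the symbolic motif per value",
    {"I_start": 1.3, "I_stop": 1.5, "I_step": 0.02, "eps": 0.1, "b": 0.8,
     "T": 300.0, "dt": 1e-3, "transient": 80.0, "thresholds": [0.3, 0.7]},
    _run_motif_scan)
_register(
    "fig4-signature",
    "Eigenvalue signature of the fixed point at I=1.45 and I=1.3",
    {"I_values": [1.45, 1.3], "eps": 0.1, "b": 0.8},
    _run_fig4_signature)
_register(
    "hopf",
    "Bisection-located Hopf point I* of the three-variable model",
    {"eps": 0.1, "b": 0.8, "bracket": [0.5, 2.5]},
    _run_hopf)
_register(
    "prop7-threshold",
    "Periodic/escape threshold of the fold blow-up system at fixed w",
    {"w": 0.0, "tol": 1e-4},
    _run_prop7_threshold)
_register(
    "canard-sweep",
    "Classify blow-up orbits over a grid of launch heights c",
    {"w": 0.0, "c_start": 0.02, "c_stop": 0.3, "c_step": 0.02, "tol": 1e-4},
    _run_canard_sweep)
_register(
    "theorem1-periodic-orbit",
    "Periodic orbit at I=0 via the two-stage Poincare fixed point",
    {"I": 0.0, "eps": 0.01, "b": 0.8, "w_bracket": [-0.05, 0.05]},
    _run_periodic_orbit)
_register(
    "ball2d-filtering",
    "2D oscillatory ball in excitable surround: frequency filtering",
    {"eps": 0.1, "npoints": 64, "half_side": 20.0, "radius": 5.0,
     "c0": -1.21, "T": 80.0, "store_every": 0.05,
     "amplitude_threshold": 1.5},
    _run_ball2d)
_register(
    "quartic1d-deathspot",
    "1D quartic excitability well: propagation, death spot, stationary",
    {"eps": 0.1, "npoints": 25, "beta": 3.0, "p_values": [1.05, 2.0, 15.0],
     "T": 80.0, "store_every": 0.05, "amplitude_threshold": 1.5},
    _run_quartic1d)


def list_scenarios() -> list[tuple[str, str]]:
    """Deterministically ordered (name, description) table."""
    return [(s.name, s.description) for s in SCENARIOS.values()]


def run_scenario(name: str, overrides: dict | None = None,
                 out_dir=None) -> dict:
    """Run a preset scenario, optionally overriding its defaults.

    Returns the summary dict; when ``out_dir`` is given the summary is
    also written there as JSON together with any artifact files.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; see list_scenarios()")
    sc = SCENARIOS[name]
    cfg = dict(sc.defaults)
    for key, val in (overrides or {}).items():
        if key not in cfg:
            raise KeyError(f"unknown override {key!r} for scenario {name!r}")
        default = cfg[key]
        if isinstance(default, bool):
            val = val if isinstance(val, bool) else str(val).lower() in ("1", "true", "yes")
        elif isinstance(default, (int, float)) and not isinstance(val, (list, dict)):
            val = type(default)(float(val))
        cfg[key] = val
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    summary = sc.runner(cfg, out_path)
    result = {"scenario": name, "config": cfg, "units": "dimensionless",
              "summary": summary}
    if out_path is not None:
        with open(out_path / f"{name}.json", "w") as fh:
            json.dump(result, fh, indent=2, default=float)
    return result
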