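"""Structured analysis reports and the end-to-end reproduction pipeline."""

from __future__ import annotations

import json
from typing import Any

import numpy as np

from .model import dissipative_bounds, permanence_condition, positive_equilibrium
from .normal_form import bifurcation_properties
from .params import PRESETS, ModelParameters, load_parameters
from .simulate import SimulationGrid, constant_history, oscillation_summary, simulate
from .spectral import (
    classify,
    critical_delays,
    hopf_frequencies,
    mode_coefficients,
    mode_cutoff,
    minimal_critical_delay,
)

SCHEMA_VERSION = "delogistic-report/1"


def _jsonable(obj: Any) -> Any:
    """Convert report values to JSON-safe types; complex -> {re, im}."""
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def analysis_report(
    params: ModelParameters,
    tau: float | None = None,
    n_max: int = 5,
    j_max: int = 2,
    convention: str = "reduced",
    include_normal_form: bool = True,
) -> dict:
    """Spectral (and optionally normal-form) analysis as a JSON-safe dict."""
    eq = positive_equilibrium(params)
    n0 = mode_cutoff(params, convention=convention)
    modes = []
    for n in range(n_max + 1):
        mc = mode_coefficients(params, n, convention)
        freqs = hopf_frequencies(params, n, convention)
        entry: dict[str, Any] = {
            "n": n,
            "A": mc.A,
            "B": mc.B,
            "C": mc.C,
            "D": mc.D,
            "omega": freqs,
        }
        if freqs:
            entry["tau_crit"] = [hp.tau for hp in critical_delays(params, n, j_max, convention)]
        modes.append(entry)
    minimal = minimal_critical_delay(params, convention)
    report: dict[str, Any] = {
        "schema": SCHEMA_VERSION,
        "convention": convention,
        "parameters": params.to_dict(),
        "equilibria": {"E0": list(eq.e0), "Estar": list(eq.estar)},
        "dissipative_bounds": list(dissipative_bounds(params)),
        "permanent_sufficient": permanence_condition(params).holds,
        "modes": modes,
        "N0": n0,
        "tau0": None if minimal is None else minimal[0],
    }
    if tau is not None:
        cls = classify(params, tau, convention)
        report["classification"] = {
            "tau": tau,
            "regime": cls.regime,
            "verdict": cls.verdict,
            "outside_stated_regime": cls.outside_stated_regime,
        }
    if include_normal_form and minimal is not None:
        nf = bifurcation_properties(params, minimal[1], convention)
        report["normal_form"] = {
            "n": nf.hopf.n,
            "j": nf.hopf.j,
            "omega": nf.hopf.omega,
            "tau_crit": nf.hopf.tau,
            "xi": nf.eigen.xi,
            "eta": nf.eigen.eta,
            "M": nf.eigen.M,
            "g20": nf.g.g20,
            "g11": nf.g.g11,
            "g02": nf.g.g02,
            "g21": nf.g.g21,
            "c1": nf.c1,
            "lambda_prime": nf.lambda_prime,
            "mu2": nf.mu2,
            "beta2": nf.beta2,
            "T2": nf.T2,
            "direction": nf.direction,
            "orbit_stability": nf.orbit_stability,
            "period_trend": nf.period_trend,
            "validated": nf.g.validated,
        }
    return _jsonable(report)


def reproduce(
    include_simulations: bool = True,
    sweep_taus=(2.0, 10.0, 50.0, 130.0),
    grid: SimulationGrid | None = None,
) -> dict:
    """Regenerate every checkable quantity from the shipped reference preset.

    Runs equilibria -> spectral -> normal form on the reference parameter set
    (in both coupling conventions) and, unless disabled, the four standard
    simulations with constant history (N, u)(x, 0) = (0.5, 0.9).
    """
    params = PRESETS["reference"]
    report = analysis_report(params, tau=None, convention="reduced")
    report["exact_convention"] = analysis_report(params, tau=None, convention="exact")
    if include_simulations:
        grid = grid or SimulationGrid(M=101, t_end=600.0)
        history = constant_history(0.5, 0.9)
        sims = []
        for tau in sweep_taus:
            res = simulate(params, tau, grid, history)
            summ = oscillation_summary(res)
            sims.append(
                {
                    "tau": tau,
                    "classification": summ.classification,
                    "amplitude": summ.amplitude,
                    "period": summ.period,
                    "final_midpoint": [
                        float(res.N[summ.probe_index, -1]),
                        float(res.u[summ.probe_index, -1]),
                    ],
                }
            )
        report["simulations"] = sims
    return report


def run_config(config: dict | str) -> dict:
    """Execute the stages requested by a configuration mapping.

    Schema (all sections optional except ``model``)::

        model:        {preset: NAME} or the ten parameter fields
        spectral:     {convention, n_max, j_max, tau}
        normal_form:  {enabled: bool}
        simulation:   {taus: [..], M, dt, t_end, N0, u0}
        output:       {path: report.json}

    Unknown keys anywhere are rejected with the offending path.
    """
    if isinstance(config, str):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    allowed = {"model", "spectral", "normal_form", "simulation", "output"}
    unknown = set(config) - allowed
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    if "model" not in config:
        raise ValueError("config requires a 'model' section")

    model_cfg = dict(config["model"])
    if "preset" in model_cfg:
        extra = set(model_cfg) - {"preset"}
        if extra:
            raise ValueError(f"model.preset cannot be combined with: {sorted(extra)}")
        params = load_parameters(model_cfg["preset"])
    else:
        params = ModelParameters.from_dict(model_cfg)

    spectral_cfg = dict(config.get("spectral", {}))
    unknown = set(spectral_cfg) - {"convention", "n_max", "j_max", "tau"}
    if unknown:
        raise ValueError(f"unknown keys in spectral: {sorted(unknown)}")
    nf_cfg = dict(config.get("normal_form", {}))
    unknown = set(nf_cfg) - {"enabled"}
    if unknown:
        raise ValueError(f"unknown keys in normal_form: {sorted(unknown)}")

    report = analysis_report(
        params,
        tau=spectral_cfg.get("tau"),
        n_max=int(spectral_cfg.get("n_max", 5)),
        j_max=int(spectral_cfg.get("j_max", 2)),
        convention=spectral_cfg.get("convention", "reduced"),
        include_normal_form=bool(nf_cfg.get("enabled", "normal_form" in config)),
    )
    if not nf_cfg.get("enabled", "normal_form" in config):
        report.pop("normal_form", None)

    if "simulation" in config:
        sim_cfg = dict(config["simulation"])
        unknown = set(sim_cfg) - {"taus", "M", "dt", "t_end", "N0", "u0"}
        if unknown:
            raise ValueError(f"unknown keys in simulation: {sorted(unknown)}")
        grid = SimulationGrid(
            M=int(sim_cfg.get("M", 101)),
            dt=float(sim_cfg.get("dt", 0.05)),
            t_end=float(sim_cfg.get("t_end", 600.0)),
        )
        history = constant_history(float(sim_cfg.get("N0", 0.5)), float(sim_cfg.get("u0", 0.9)))
        sims = []
        for tau in sim_cfg.get("taus", []):
            res = simulate(params, float(tau), grid, history)
            summ = oscillation_summary(res)
            sims.append(
                {
                    "tau": float(tau),
                    "classification": summ.classification,
                    "amplitude": summ.amplitude,
                    "period": summ.period,
                }
            )
        report["simulations"] = sims

    if "output" in config:
        out_cfg = dict(config["output"])
        unknown = set(out_cfg) - {"path"}
        if unknown:
            raise ValueError(f"unknown keys in output: {sorted(unknown)}")
        with open(out_cfg["path"], "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
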