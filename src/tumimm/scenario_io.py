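"""Scenario configuration, built-in setups, provenance and output writers.

A scenario is a TOML (or JSON) tree with sections ``[growth]``,
``[division]``, ``[transport]``, ``[sources]``, ``[cytokine]``,
``[numerics]``, ``[ode]``, ``[therapy]`` and ``[output]``; the printed
simulation-table names (``A``, ``xi2``, ``A_sigma``, ``xi_sigma2``, ``a``,
``V``, ``r``, ``b``, ``chi``, ``S``, ``gamma``) appear verbatim as keys.
Every parameter carries a provenance flag: ``paper`` when its value is one
of the printed values, ``default`` otherwise; run manifests record the full
flagged tree so any number in an output is traceable.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coupled_model import ModelParams, Numerics, SimulationResult
from .reduced_ode import OdeParams
from .size_dynamics import DivisionModel, GrowthLaw
from .spatial_fields import GaussianSpec, TransportCoefficients
from .therapy import DoseSchedule

__all__ = [
    "ScenarioConfig",
    "ConfigError",
    "load_config",
    "builtin_scenarios",
    "write_outputs",
    "provenance_tree",
]


class ConfigError(ValueError):
    """Schema violation; the message carries the offending field path."""


# printed values: any parameter currently holding one of these is flagged
# provenance "paper"
_PAPER_VALUES = {
    "sources.A": 1.0, "sources.xi2": 0.02,
    "sources.A_sigma": 0.002, "sources.xi_sigma2": 0.05,
    "division.a": 0.8, "division.z0": 1.0,
    "growth.V": 0.616, "growth.r": 0.616, "growth.b": 10.0,
    "transport.chi": 0.864,
    "sources.S": 5.0, "sources.gamma": 0.18,
    "cytokine.m": 2.0,
    "ode.V": 0.616, "ode.delta": 1.0, "ode.S": 1.5,
    "ode.k_r": 1.25, "ode.k_c": 0.1, "ode.m": 2.0, "ode.gamma": 0.18,
    "therapy.react.pulse_len": 1.0, "therapy.react.period": 7.0,
    "therapy.react.decay": 0.05,
    "therapy.block.pulse_len": 1.0, "therapy.block.period": 7.0,
    "therapy.block.decay": 0.0105,
    "sources.alpha": 0.5,
    "numerics.init_lo": 0.125, "numerics.init_hi": 5.0,
}

_SCHEMA: dict[str, set[str]] = {
    "growth": {"kind", "V", "r", "b"},
    "division": {"rate_kind", "a", "z0"},
    "transport": {"chi", "D", "K"},
    "sources": {"A", "xi2", "A_sigma", "xi_sigma2", "A_theta", "xi_theta2",
                "A_b1", "xi_b1_2", "S", "Sr_amplitude", "Sr_xi2", "Sr_scale",
                "Sr_radius", "gamma", "gamma_r", "gamma_a", "k_c", "k_r",
                "eta", "g_mode", "alpha"},
    "cytokine": {"m", "psi_bar", "tau"},
    "numerics": {"n_axis", "n_size_cells", "z_max", "z_truncation_factor",
                 "dt_max", "init_lo", "init_hi", "init_height", "I0",
                 "escape_stop_factor", "snapshot_times", "eigen_tol"},
    "ode": {"a", "V", "delta", "S", "gamma", "gamma_r", "tau", "k_r", "k_c",
            "b1", "m", "psi_bar", "g_mode"},
    "therapy": {"mode", "react", "block"},
    "output": {"dir", "snapshots"},
}
_SCHED_KEYS = {"t0", "pulse_len", "period", "dose", "decay"}


@dataclass
class ScenarioConfig:
    """Validated scenario: model, numerics, optional ODE and therapy blocks."""

    name: str
    params: ModelParams = field(default_factory=ModelParams)
    numerics: Numerics = field(default_factory=Numerics)
    ode: OdeParams = field(default_factory=OdeParams)
    horizon: float = 100.0
    therapy_mode: str | None = None            # reactivation | blockade | combined
    sched_react: DoseSchedule | None = None
    sched_block: DoseSchedule | None = None
    output_dir: str = "results"

    def tree(self) -> dict:
        """Plain nested-dict view of every parameter (for hashing/manifests)."""
        p, nm = self.params, self.numerics
        t = {
            "name": self.name,
            "horizon": self.horizon,
            "growth": {"kind": p.growth.kind, "V": p.growth.V_const,
                       "r": p.growth.r, "b": p.growth.b},
            "division": {"rate_kind": p.division.rate_kind, "a": p.division.a,
                         "z0": p.division.z0},
            "transport": {"chi": p.transport.chi, "D": p.transport.D,
                          "K": p.transport.K},
            "sources": {"A": p.delta.amplitude, "xi2": p.delta.xi2,
                        "A_sigma": p.sigma.amplitude, "xi_sigma2": p.sigma.xi2,
                        "A_theta": p.theta.amplitude, "xi_theta2": p.theta.xi2,
                        "A_b1": p.b1.amplitude, "xi_b1_2": p.b1.xi2,
                        "S": p.S, "Sr_amplitude": p.Sr_amplitude,
                        "Sr_xi2": p.Sr_xi2, "Sr_scale": p.Sr_scale,
                        "Sr_radius": p.Sr_radius,
                        "gamma": p.gamma, "gamma_r": p.gamma_r,
                        "gamma_a": p.gamma_a, "k_c": p.k_c, "k_r": p.k_r,
                        "eta": p.eta, "g_mode": p.g_mode, "alpha": p.alpha},
            "cytokine": {"m": p.m, "psi_bar": p.psi_bar, "tau": p.tau},
            "numerics": {k: getattr(nm, k) for k in
                         ("n_axis", "n_size_cells", "z_max",
                          "z_truncation_factor", "dt_max", "init_lo",
                          "init_hi", "init_height", "I0",
                          "escape_stop_factor", "eigen_tol")},
            "ode": {k: getattr(self.ode, k) for k in
                    ("a", "V", "delta", "S", "gamma", "gamma_r", "tau",
                     "k_r", "k_c", "b1", "m", "psi_bar", "g_mode")},
        }
        if self.therapy_mode:
            th: dict = {"mode": self.therapy_mode}
            for label, sched in (("react", self.sched_react),
                                 ("block", self.sched_block)):
                if sched is not None:
                    th[label] = {k: getattr(sched, k) for k in _SCHED_KEYS}
            t["therapy"] = th
        return t

    def config_hash(self) -> str:
        blob = json.dumps(self.tree(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def provenance_tree(config: ScenarioConfig) -> dict:
    """Flag every leaf parameter as ``paper`` or ``default``."""
    out = {}

    def walk(prefix: str, node):
        for key, val in node.items():
            path = f"{prefix}.{key}" if prefix else key
            if isinstance(val, dict):
                walk(path, val)
            elif isinstance(val, (int, float)) and not isinstance(val, bool):
                ref = _PAPER_VALUES.get(path)
                flag = ("paper" if ref is not None
                        and math.isclose(float(val), ref) else "default")
                out[path] = flag
            else:
                out[path] = "default"

    walk("", config.tree())
    return out


# --------------------------------------------------------------------------
# loading

def _validate(raw: dict, path: str = "") -> None:
    if "name" not in raw:
        raise ConfigError("missing required field: name")
    for section, body in raw.items():
        if section in ("name", "horizon"):
            continue
        if section not in _SCHEMA:
            raise ConfigError(f"unknown section: {section}")
        if not isinstance(body, dict):
            raise ConfigError(f"section {section} must be a table")
        for key, val in body.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown key: {section}.{key}")
            if section == "therapy" and key in ("react", "block"):
                for k2 in val:
                    if k2 not in _SCHED_KEYS:
                        raise ConfigError(f"unknown key: therapy.{key}.{k2}")


def _build(raw: dict) -> ScenarioConfig:
    g = raw.get("growth", {})
    growth = GrowthLaw(kind=g.get("kind", "gompertz"),
                       V_const=g.get("V", 0.616),
                       r=g.get("r", 0.616), b=g.get("b", 10.0))
    d = raw.get("division", {})
    division = DivisionModel(rate_kind=d.get("rate_kind", "threshold"),
                             a=d.get("a", 0.8), z0=d.get("z0", 1.0))
    tr = raw.get("transport", {})
    transport = TransportCoefficients(chi=tr.get("chi", 0.864),
                                      D=tr.get("D", 0.05), K=tr.get("K", 1.0))
    s = raw.get("sources", {})
    cy = raw.get("cytokine", {})
    base = ModelParams()
    params = ModelParams(
        growth=growth, division=division, transport=transport,
        delta=GaussianSpec(s.get("A", base.delta.amplitude),
                           s.get("xi2", base.delta.xi2)),
        sigma=GaussianSpec(s.get("A_sigma", base.sigma.amplitude),
                           s.get("xi_sigma2", base.sigma.xi2)),
        theta=GaussianSpec(s.get("A_theta", base.theta.amplitude),
                           s.get("xi_theta2", base.theta.xi2)),
        b1=GaussianSpec(s.get("A_b1", base.b1.amplitude),
                        s.get("xi_b1_2", base.b1.xi2)),
        S=s.get("S", base.S),
        Sr_amplitude=s.get("Sr_amplitude", base.Sr_amplitude),
        Sr_xi2=s.get("Sr_xi2", base.Sr_xi2),
        Sr_scale=s.get("Sr_scale", base.Sr_scale),
        Sr_radius=s.get("Sr_radius", base.Sr_radius),
        gamma=s.get("gamma", base.gamma),
        gamma_r=s.get("gamma_r", base.gamma_r),
        gamma_a=s.get("gamma_a", base.gamma_a),
        k_c=s.get("k_c", base.k_c), k_r=s.get("k_r", base.k_r),
        eta=s.get("eta", base.eta), g_mode=s.get("g_mode", base.g_mode),
        alpha=s.get("alpha", base.alpha),
        m=cy.get("m", base.m), psi_bar=cy.get("psi_bar", base.psi_bar),
        tau=cy.get("tau", base.tau),
    )
    nm = raw.get("numerics", {})
    if "snapshot_times" in nm:
        nm = dict(nm)
        nm["snapshot_times"] = tuple(nm["snapshot_times"])
    numerics = replace(Numerics(), **nm)
    ode = replace(OdeParams(), **raw.get("ode", {}))
    th = raw.get("therapy", {})
    mode = th.get("mode")
    sched_react = sched_block = None
    if mode in ("reactivation", "combined"):
        sched_react = DoseSchedule(**{"decay": 0.05, **th.get("react", {})})
    if mode in ("blockade", "combined"):
        sched_block = DoseSchedule(**{"decay": 0.0105, **th.get("block", {})})
    if mode not in (None, "reactivation", "blockade", "combined"):
        raise ConfigError(f"unknown therapy mode: {mode}")
    out = raw.get("output", {})
    return ScenarioConfig(
        name=raw["name"], params=params, numerics=numerics, ode=ode,
        horizon=raw.get("horizon", 100.0), therapy_mode=mode,
        sched_react=sched_react, sched_block=sched_block,
        output_dir=out.get("dir", "results"),
    )


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a TOML (canonical) or JSON scenario file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    else:
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    _validate(raw)
    try:
        return _build(raw)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def apply_overrides(config: ScenarioConfig, overrides: list[str]) -> ScenarioConfig:
    """Apply ``section.key=value`` overrides on top of a loaded scenario."""
    raw = config.tree()
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override must look like section.key=value: {item}")
        dotted, _, text = item.partition("=")
        parts = dotted.strip().split(".")
        node = raw
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        try:
            value = json.loads(text)
        except json.JSONDecodeError:
            value = text
        node[parts[-1]] = value
    _validate(raw)
    return _build(raw)


# --------------------------------------------------------------------------
# built-in paper scenarios

def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """Named configurations reproducing the printed setups.

    ``table2_gompertz``
        The full system with the Gompertz growth law, the threshold binary
        division rate and the printed simulation parameters.
    ``constant_coeff_validation``
        Constant growth and division rates and no protumor growth boost
        (``b1 = 0``): the eigenvalue is ``a`` itself, which validates the
        long-run immune strength against an analytic value.
    ``ode_fig3``
        The reduced ODE system with the printed scenario data.
    ``therapy_react`` / ``therapy_block`` / ``therapy_combined``
        The treatment protocols with the printed pulse constants
        (pulse of length 1 every 7 time units; decay 0.05 resp. 0.0105).
    """
    base = ModelParams()
    constant = replace(
        base,
        growth=GrowthLaw(kind="constant", V_const=0.616),
        division=DivisionModel(rate_kind="constant", a=0.8),
        b1=GaussianSpec(0.0, base.b1.xi2),
    )
    escaping = replace(constant, division=DivisionModel(rate_kind="constant", a=4.0))
    react = DoseSchedule(t0=10.0, pulse_len=1.0, period=7.0, dose=2.0, decay=0.05)
    block = DoseSchedule(t0=10.0, pulse_len=1.0, period=7.0, dose=0.12, decay=0.0105)
    # the combination demonstration point: both doses fail alone at t0 = 10
    block_c = replace(block, dose=0.14)
    return {
        "table2_gompertz": ScenarioConfig(name="table2_gompertz", params=base),
        "constant_coeff_validation": ScenarioConfig(
            name="constant_coeff_validation", params=constant, horizon=150.0),
        "ode_fig3": ScenarioConfig(name="ode_fig3", params=base,
                                   ode=OdeParams(), horizon=200.0),
        "therapy_react": ScenarioConfig(
            name="therapy_react", params=escaping, therapy_mode="reactivation",
            sched_react=react, horizon=100.0),
        "therapy_block": ScenarioConfig(
            name="therapy_block", params=escaping, therapy_mode="blockade",
            sched_block=block, horizon=100.0),
        "therapy_combined": ScenarioConfig(
            name="therapy_combined", params=escaping, therapy_mode="combined",
            sched_react=react, sched_block=block_c, horizon=100.0),
    }


# --------------------------------------------------------------------------
# outputs

def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_outputs(result: SimulationResult, config: ScenarioConfig,
                  outdir: str | Path) -> dict[str, Path]:
    """Write timeseries.csv, outcome.json, manifest.json (and snapshots).

    Floats are printed at 17 significant digits so reruns of the same
    configuration reproduce the CSV byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    ts_path = outdir / "timeseries.csv"
    frame = pd.DataFrame(result.series)
    _atomic_write(ts_path, frame.to_csv(index=False, float_format="%.17g"))
    files["timeseries"] = ts_path

    outcome_path = outdir / "outcome.json"
    outcome = result.outcome
    _atomic_write(outcome_path, json.dumps(
        {"label": outcome.label, "evidence": outcome.evidence,
         "time": outcome.time} if outcome else {"label": "undecided"},
        indent=2))
    files["outcome"] = outcome_path

    manifest = {
        "config": config.tree(),
        "config_hash": config.config_hash(),
        "provenance": provenance_tree(config),
        "run": result.manifest,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest_path = outdir / "manifest.json"
    _atomic_write(manifest_path, json.dumps(manifest, indent=2, default=str))
    files["manifest"] = manifest_path

    if result.snapshots:
        snap_path = outdir / "snapshots.npz"
        arrays = {}
        meta = []
        for i, snap in enumerate(result.snapshots):
            for key in ("n", "c", "c_r"):
                arrays[f"{key}_{i}"] = snap[key]
            meta.append({"index": i, "t": snap["t"]})
        np.savez(snap_path, **arrays)
        _atomic_write(outdir / "snapshots.json", json.dumps(
            {"snapshots": meta,
             "grid": {"n_axis": config.numerics.n_axis,
                      "n_size_cells": config.numerics.n_size_cells}},
            indent=2))
        files["snapshots"] = snap_path
    return files
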