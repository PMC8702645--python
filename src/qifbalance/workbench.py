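"""Experiment configuration, canonical fixtures and scan orchestration.

Configs are YAML files with blocks ``model`` (the physical parameters),
``run`` (integration settings and network sizes), ``scan`` (a control
parameter and its grid), ``analysis`` (which quantities to compute) and
``seeds``.  All randomness is seeded explicitly; a run writes its results
as JSON plus a manifest (config hash, package version, wall time) so that
re-running a manifest reproduces the results byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .params import ModelParams

__all__ = ["ExperimentConfig", "load_config", "dump_config", "fixture", "FIXTURE_NAMES", "run_experiment"]

_RUN_DEFAULTS = {
    "dt_mf": 0.01,  # ms, RK4 step of the neural mass model
    "dt_net": 1e-3,  # ms, Euler step of the spiking network
    "T": 20_000.0,  # ms of recorded dynamics
    "transient": 5_000.0,  # ms discarded
    "N_e": 2500,
    "N_i": 625,
    "v_peak": 100.0,
    "pulse_factor": 1.0,
}

_SEED_DEFAULTS = {"connectivity": 1, "init": 2, "tangent": 3}

_ANALYSES = ("fixed_point", "eigen", "lyapunov", "regime", "peak_map", "network")

_SCAN_CONTROLS = ("I0_e", "K", "delta0_ee", "delta0_ii", "tau_m_i")


@dataclass(frozen=True)
class ExperimentConfig:
    """A validated experiment description."""

    model: ModelParams
    run: dict = field(default_factory=dict)
    scan: dict | None = None
    analysis: tuple = ("fixed_point",)
    seeds: dict = field(default_factory=dict)

    def __post_init__(self):
        run = dict(_RUN_DEFAULTS)
        run.update(self.run)
        unknown = set(self.run) - set(_RUN_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown run keys: {sorted(unknown)}")
        for key in ("dt_mf", "dt_net", "T", "v_peak"):
            if run[key] <= 0:
                raise ValueError(f"run.{key} must be positive")
        if run["transient"] < 0:
            raise ValueError("run.transient must be >= 0")
        object.__setattr__(self, "run", run)
        seeds = dict(_SEED_DEFAULTS)
        seeds.update(self.seeds)
        unknown = set(self.seeds) - set(_SEED_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown seed keys: {sorted(unknown)}")
        object.__setattr__(self, "seeds", seeds)
        if self.scan is not None:
            if set(self.scan) != {"control", "values"}:
                raise ValueError("scan block needs exactly the keys: control, values")
            if self.scan["control"] not in _SCAN_CONTROLS:
                raise ValueError(f"scan.control must be one of {_SCAN_CONTROLS}")
            object.__setattr__(
                self, "scan", {"control": self.scan["control"], "values": [float(v) for v in self.scan["values"]]}
            )
        bad = set(self.analysis) - set(_ANALYSES)
        if bad:
            raise ValueError(f"unknown analyses: {sorted(bad)}")
        object.__setattr__(self, "analysis", tuple(self.analysis))

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "run": dict(self.run),
            "scan": dict(self.scan) if self.scan else None,
            "analysis": list(self.analysis),
            "seeds": dict(self.seeds),
        }

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _config_from_dict(raw: dict) -> ExperimentConfig:
    allowed = {"model", "run", "scan", "analysis", "seeds"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    if "model" not in raw:
        raise ValueError("missing required block: model")
    model_keys = {f.name for f in dataclasses.fields(ModelParams)}
    bad = set(raw["model"]) - model_keys
    if bad:
        raise ValueError(f"unknown model keys: {sorted(bad)}")
    model = ModelParams(**raw["model"])
    return ExperimentConfig(
        model=model,
        run=raw.get("run", {}),
        scan=raw.get("scan"),
        analysis=tuple(raw.get("analysis", ("fixed_point",))),
        seeds=raw.get("seeds", {}),
    )


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return _config_from_dict(raw)


def dump_config(config: ExperimentConfig, path) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# --------------------------------------------------------------------------
# canonical fixtures
#
# One parameter set per published figure of the study the package
# reproduces; scans hold I0_i = I0_e / 1.02 and the canonical couplings.

def _fx(model: dict, scan=None, analysis=("fixed_point",), run=None) -> dict:
    out = {"model": model, "analysis": list(analysis), "seeds": dict(_SEED_DEFAULTS)}
    if scan:
        out["scan"] = scan
    if run:
        out["run"] = run
    return out


def _geomspace(a, b, n):
    return [float(x) for x in np.geomspace(a, b, n)]


_FIXTURES: dict[str, dict] = {
    # bifurcation-diagram cuts in (I0_e, delta0_ee) at K = 1000
    "fig1a_phase_diagram": _fx(
        {"K": 1000.0, "delta0_ii": 0.3, "delta0_ee": 2.0, "I0_e": 0.001, "I0_i": 0.001 / 1.02},
        scan={"control": "I0_e", "values": _geomspace(1e-4, 10.0, 11)},
        analysis=("regime",),
    ),
    "fig1b_phase_diagram": _fx(
        {"K": 1000.0, "delta0_ii": 0.3, "delta0_ee": 2.0, "I0_e": 0.001, "I0_i": 0.001 / 1.02},
        scan={"control": "K", "values": _geomspace(100, 10000, 9)},
        analysis=("regime",),
    ),
    "fig1c_phase_diagram": _fx(
        {"K": 1000.0, "I0_e": 0.1, "I0_i": 0.1 / 1.02, "delta0_ee": 2.0, "delta0_ii": 0.3},
        scan={"control": "delta0_ii", "values": _geomspace(0.1, 3.0, 9)},
        analysis=("regime",),
    ),
    # asynchronous balanced regime, rates vs K
    "fig2_asynchronous": _fx(
        {"I0_e": 0.2, "I0_i": 0.2 / 1.02, "delta0_ee": 2.5, "delta0_ii": 1.0, "K": 1000.0},
        scan={"control": "K", "values": [float(2**k) for k in range(4, 15)]},
        analysis=("fixed_point", "eigen"),
    ),
    "fig3_microscopic": _fx(
        {"I0_e": 0.2, "I0_i": 0.2 / 1.02, "delta0_ee": 2.5, "delta0_ii": 1.0, "K": 16384.0},
        analysis=("fixed_point", "network"),
    ),
    # period-doubling cut: black dashed line of the phase diagram
    "fig4_cut": _fx(
        {"K": 1000.0, "delta0_ii": 0.3, "delta0_ee": 2.0, "I0_e": 0.0009, "I0_i": 0.0009 / 1.02},
        scan={"control": "I0_e", "values": _geomspace(5e-5, 9e-4, 20)},
        analysis=("lyapunov", "peak_map"),
    ),
    "fig5_co_examples": _fx(
        {"K": 1000.0, "delta0_ii": 0.3, "delta0_ee": 2.0, "I0_e": 0.0009, "I0_i": 0.0009 / 1.02},
        scan={"control": "I0_e", "values": [0.00021, 0.0009, 0.006]},
        analysis=("regime",),
    ),
    "fig6_ping_delay": _fx(
        {"K": 1000.0, "delta0_ii": 0.3, "delta0_ee": 2.0, "I0_e": 0.0009, "I0_i": 0.0009 / 1.02},
        scan={"control": "tau_m_i", "values": [19.0, 19.5, 20.0, 20.25]},
        analysis=("regime",),
    ),
    # sub-critical Hopf cut: purple dashed line
    "fig7_cut": _fx(
        {"K": 1000.0, "delta0_ii": 0.3, "delta0_ee": 1.58, "I0_e": 0.128, "I0_i": 0.128 / 1.02},
        scan={"control": "I0_e", "values": _geomspace(0.01, 100.0, 9)},
        analysis=("fixed_point", "eigen"),
    ),
    "fig8_coherence": _fx(
        {"K": 4000.0, "delta0_ii": 0.3, "delta0_ee": 1.58, "I0_e": 0.128, "I0_i": 0.128 / 1.02},
        scan={"control": "I0_e", "values": _geomspace(0.01, 10.0, 7)},
        analysis=("network",),
        run={"N_e": 2500, "N_i": 625, "T": 10_000.0},
    ),
    "fig9_locking": _fx(
        {"K": 8192.0, "delta0_ii": 0.3, "delta0_ee": 1.58, "I0_e": 0.128, "I0_i": 0.128 / 1.02},
        analysis=("eigen", "network"),
    ),
    "fig10_of_scaling": _fx(
        {"K": 1000.0, "delta0_ii": 0.3, "delta0_ee": 1.58, "I0_e": 0.128, "I0_i": 0.128 / 1.02},
        scan={"control": "I0_e", "values": _geomspace(0.01, 10.0, 7)},
        analysis=("eigen",),
    ),
    "fig11_op_scaling": _fx(
        {"K": 1000.0, "delta0_ii": 0.3, "delta0_ee": 2.0, "I0_e": 0.001, "I0_i": 0.001 / 1.02},
        scan={"control": "K", "values": _geomspace(250, 16000, 7)},
        analysis=("regime",),
    ),
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture(name: str) -> ExperimentConfig:
    """A canonical, fully seeded experiment configuration by name."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return _config_from_dict(json.loads(json.dumps(_FIXTURES[name])))


# --------------------------------------------------------------------------
# orchestration


def _scan_params(config: ExperimentConfig):
    base = config.model
    if config.scan is None:
        yield None, base
        return
    control = config.scan["control"]
    ratio = base.I0_e / base.I0_i if base.I0_i else None
    for val in config.scan["values"]:
        changes = {control: val}
        if control == "I0_e" and ratio is not None:
            changes["I0_i"] = val / ratio
        yield val, base.replace(**changes)


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Run every analysis of `config` over its scan grid.

    Writes ``results.json`` (deterministic given the config) and
    ``manifest.json`` (config echo, hash, version, wall time, collected
    warnings) into `out_dir` and returns the results dict.
    """
    from .mean_field import (
        classify_regime,
        jacobian_eigenvalues,
        lyapunov_spectrum,
        peak_map,
        stationary_state,
    )
    from .network import build_connectivity, simulate_network

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    results: dict = {"points": []}
    warnings_log: list[str] = []
    run = config.run
    for val, params in _scan_params(config):
        point: dict = {"control_value": val, "params": params.to_dict()}
        for task in config.analysis:
            try:
                if task == "fixed_point":
                    point["fixed_point"] = stationary_state(params, "exact").to_dict()
                elif task == "eigen":
                    fp = stationary_state(params, "exact")
                    point["eigen"] = jacobian_eigenvalues(params, fp).to_dict()
                elif task == "lyapunov":
                    point["lyapunov"] = lyapunov_spectrum(
                        params,
                        dt=run["dt_mf"],
                        T=run["T"],
                        transient=run["transient"],
                        seed=config.seeds["tangent"],
                    ).to_dict()
                elif task == "regime":
                    point["regime"] = classify_regime(
                        params,
                        dt=run["dt_mf"],
                        T=run["T"],
                        transient=run["transient"],
                        seed=config.seeds["tangent"],
                    ).to_dict()
                elif task == "peak_map":
                    pts = peak_map(
                        params,
                        "I0_e",
                        [params.I0_e],
                        dt=run["dt_mf"],
                        T=run["T"],
                        transient=run["transient"],
                    )
                    point["peak_map"] = {
                        "n_clusters": pts[0].n_clusters,
                        "n_bands": pts[0].n_bands,
                        "escaped": pts[0].escaped,
                    }
                elif task == "network":
                    conn = build_connectivity(
                        run["N_e"],
                        run["N_i"],
                        int(params.K),
                        params.delta0_ee,
                        params.delta0_ii,
                        config.seeds["connectivity"],
                    )
                    raster, traces = simulate_network(
                        conn,
                        params,
                        dt=run["dt_net"],
                        T=run["T"],
                        transient=run["transient"],
                        v_peak=run["v_peak"],
                        seed=config.seeds["init"],
                        pulse_factor=run["pulse_factor"],
                    )
                    point["network"] = {
                        "mean_rate_e_hz": float(traces.R_e.mean() * 1000.0),
                        "mean_rate_i_hz": float(traces.R_i.mean() * 1000.0),
                        "n_spikes": raster.n_spikes,
                    }
            except (ValueError, RuntimeError) as err:
                point.setdefault("errors", {})[task] = str(err)
                warnings_log.append(f"{task}@{val}: {err}")
        results["points"].append(point)
    results_path = out_dir / "results.json"
    with open(results_path, "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "version": __version__,
        "wall_time_s": time.time() - t0,
        "warnings": warnings_log,
        "results_file": results_path.name,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results
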