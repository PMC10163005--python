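"""Scenario configuration and the scenario runner.

A scenario is described by a single YAML document (one file, one
scenario) with four blocks::

    params:       # ModelParams fields, or  preset: <name>
    environment:  # kind: constant|step|pulse|pulse_train + timings
    noise:        # NoiseModel fields (optional)
    simulation:   # mode, t_end, n_cells, seed, output directory

Validation collects *every* problem before failing, and unknown keys are
rejected so typos never silently fall back to defaults.  Outputs are
plain delimited text plus a JSON manifest carrying the config hash, the
seed and the package version, so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import CellState
from .environment import Environment, make_environment
from .errors import ConfigError, SectorSizeError
from .params import ModelParams, PRESETS
from . import steady, stochastic, dynamics, population, observables
from .stochastic import NoiseModel

__all__ = ["ScenarioConfig", "run_scenario", "load_config"]

_MODES = ("deterministic", "lineage", "ensemble", "population",
          "stationary_exit")

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)} | {"preset"}
_NOISE_KEYS = {f.name for f in dataclasses.fields(NoiseModel)}
_ENV_KEYS = {"kind", "kappa_n0", "kappa_n0_low", "kappa_n0_high", "t_shift",
             "tau_feast", "tau_pulse", "pulse_duration", "n_pulses"}
_SIM_KEYS = {"mode", "t_end", "n_cells", "seed", "outdir", "dt",
             "V_init", "V_init_range", "n0", "threshold", "division"}
_TOP_KEYS = {"params", "environment", "noise", "simulation"}


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated scenario: parameters, environment, noise, run settings."""

    params: ModelParams
    env: Environment
    noise: NoiseModel
    mode: str
    t_end: float
    n_cells: int
    seed: int
    outdir: str
    dt: float = 0.01
    V_init: float | None = None
    V_init_range: tuple[float, float] = (0.3, 1.0)
    n0: int = 90
    threshold: float = 1.0
    division: bool = True
    raw: dict = dataclasses.field(default=None, compare=False, repr=False)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build_params(block, problems) -> ModelParams | None:
    block = dict(block or {})
    unknown = set(block) - _PARAM_KEYS
    if unknown:
        problems.append(f"params: unknown keys {sorted(unknown)}")
        return None
    name = block.pop("preset", None)
    try:
        if name is not None:
            if name not in PRESETS:
                problems.append(f"params.preset: unknown preset {name!r}")
                return None
            base = PRESETS[name]["params"]
            return base.evolve(**block) if block else base
        return ModelParams(**block)
    except SectorSizeError as exc:
        problems.append(f"params: {exc}")
        return None


def _build_env(block, params_block, problems) -> Environment | None:
    block = dict(block or {})
    unknown = set(block) - _ENV_KEYS
    if unknown:
        problems.append(f"environment: unknown keys {sorted(unknown)}")
        return None
    kind = block.pop("kind", None)
    preset_name = (params_block or {}).get("preset")
    if preset_name in PRESETS:
        block.setdefault("kappa_n0_low", PRESETS[preset_name]["kn_low"])
        block.setdefault("kappa_n0_high", PRESETS[preset_name]["kn_high"])
    try:
        if kind == "constant":
            return Environment.constant(block["kappa_n0"])
        if kind in ("step", "pulse", "pulse_train"):
            block.pop("kappa_n0", None)
            return make_environment(kind, **block)
        problems.append(f"environment.kind must be one of constant/step/"
                        f"pulse/pulse_train, got {kind!r}")
    except (SectorSizeError, KeyError, TypeError) as exc:
        problems.append(f"environment: {exc}")
    return None


def load_config(source) -> ScenarioConfig:
    """Parse and validate a scenario from a YAML file path or mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    if not isinstance(doc, dict):
        raise ConfigError(["configuration must be a mapping"])

    problems: list[str] = []
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown top-level keys {sorted(unknown)}")

    params = _build_params(doc.get("params"), problems)
    env = _build_env(doc.get("environment"), doc.get("params"), problems)

    noise_block = dict(doc.get("noise") or {})
    unknown_n = set(noise_block) - _NOISE_KEYS
    noise = None
    if unknown_n:
        problems.append(f"noise: unknown keys {sorted(unknown_n)}")
    else:
        try:
            noise = NoiseModel(**noise_block)
        except SectorSizeError as exc:
            problems.append(f"noise: {exc}")

    sim = dict(doc.get("simulation") or {})
    unknown_s = set(sim) - _SIM_KEYS
    if unknown_s:
        problems.append(f"simulation: unknown keys {sorted(unknown_s)}")
    mode = sim.get("mode")
    if mode not in _MODES:
        problems.append(f"simulation.mode must be one of {_MODES}, got {mode!r}")
    t_end = sim.get("t_end")
    if not isinstance(t_end, (int, float)) or t_end <= 0:
        problems.append("simulation.t_end must be a positive number")
    n_cells = sim.get("n_cells", 400)
    if not isinstance(n_cells, int) or n_cells < 1:
        problems.append("simulation.n_cells must be a positive integer")
    seed = sim.get("seed", 0)
    if not isinstance(seed, int):
        problems.append("simulation.seed must be an integer")
    vr = sim.get("V_init_range", (0.3, 1.0))
    try:
        vr = (float(vr[0]), float(vr[1]))
        if not (0 < vr[0] < vr[1]):
            problems.append("simulation.V_init_range must be increasing and positive")
    except (TypeError, ValueError, IndexError):
        problems.append("simulation.V_init_range must be a (lo, hi) pair")

    if problems:
        raise ConfigError(problems)
    return ScenarioConfig(
        params=params, env=env, noise=noise, mode=mode, t_end=float(t_end),
        n_cells=n_cells, seed=seed, outdir=sim.get("outdir", "."),
        dt=float(sim.get("dt", 0.01)), V_init=sim.get("V_init"),
        V_init_range=vr, n0=int(sim.get("n0", 90)),
        threshold=float(sim.get("threshold", 1.0)),
        division=bool(sim.get("division", True)), raw=doc,
    )


def _initial_state(cfg: ScenarioConfig) -> CellState:
    kn0 = cfg.env.segments[0][1]
    if kn0 == 0 and cfg.params.mu_ns > 0:
        V = cfg.V_init if cfg.V_init is not None else 0.5 * cfg.params.V0_max
        return stochastic.stationary_initial_state(cfg.params, V)
    ss = steady.solve(kn0, cfg.params)
    V = cfg.V_init if cfg.V_init is not None else ss.V0_star
    return CellState(a=ss.a_star, phi_R=ss.phi_R_star,
                     phi_X=ss.phi_X_star if cfg.params.separated else 0.0,
                     V=V, X_tilde=0.0, t=0.0)


def run_scenario(cfg: ScenarioConfig) -> dict:
    """Execute a scenario and write its output bundle.

    Returns a manifest dict (also written as ``manifest.json``) listing
    the files produced, the config hash, the seed and the version.
    Identically seeded runs are byte-identical.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    noise = dataclasses.replace(cfg.noise, seed=cfg.seed)
    rng = noise.rng()
    files: list[str] = []
    results: dict = {}

    if cfg.mode == "deterministic":
        initial = _initial_state(cfg)
        traj = dynamics.integrate(initial, cfg.env, cfg.params, cfg.t_end,
                                  division=cfg.division,
                                  threshold=cfg.threshold)
        traj.to_csv(outdir / "trajectory.csv", outdir / "division_events.csv")
        files += ["trajectory.csv", "division_events.csv"]
        results["n_divisions"] = len(traj.division_events)

    elif cfg.mode == "lineage":
        initial = _initial_state(cfg)
        traj, recs = stochastic.simulate_lineage(
            cfg.env, cfg.params, noise, cfg.t_end, initial, rng=rng,
            collect_trajectory=True)
        stochastic.records_to_dataframe(recs).to_csv(
            outdir / "generations.csv", index=False)
        files.append("generations.csv")
        if traj is not None:
            traj.to_csv(outdir / "trajectory.csv")
            files.append("trajectory.csv")
        results["n_generations"] = len(recs)

    elif cfg.mode == "ensemble":
        initial = _initial_state(cfg)
        series, recs = stochastic.ensemble(
            cfg.n_cells, cfg.env, cfg.params, noise, cfg.t_end, initial,
            rng=rng)
        series.to_csv(outdir / "generation_averages.csv", index=False)
        recs.to_csv(outdir / "generations.csv", index=False)
        files += ["generation_averages.csv", "generations.csv"]
        results["n_generations"] = int(len(recs))

    elif cfg.mode == "population":
        rec = population.simulate_population(
            cfg.n0, cfg.env, cfg.params, noise, cfg.t_end, rng=rng, dt=cfg.dt)
        rec.to_csv(outdir / "population.csv")
        files.append("population.csv")
        results["final_count"] = int(rec.P[-1])

    elif cfg.mode == "stationary_exit":
        df = stochastic.stationary_exit_ensemble(
            cfg.n_cells, cfg.params, noise, cfg.env, rng=rng,
            V_init_range=cfg.V_init_range, t_end=cfg.t_end)
        df.to_csv(outdir / "stationary_exit.csv", index=False)
        files.append("stationary_exit.csv")
        try:
            results["sizer_correlation"] = observables.sizer_correlation(df)
        except SectorSizeError:
            results["sizer_correlation"] = None
        results["median_T_lag"] = float(np.nanmedian(df["T_lag"]))

    manifest = dict(version=__version__, config_hash=cfg.config_hash,
                    seed=cfg.seed, mode=cfg.mode, files=files,
                    results=results)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
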