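"""Stochastic single-cell lineage simulations.

Noise enters at the generation level, in three places:

* growth rate — each cell draws an offset ``delta_kappa ~ N(0, sigma)``
  at birth, with ``sigma = a <kappa> + b`` a linear function of the
  population-average growth rate; the offset shifts only the volume
  equation, the intensive (allocation) dynamics follow the population
  average, and mother/daughter offsets are independent;
* division ratio — daughters are born at ``r * V_d`` with
  ``r ~ N(0.5, 0.04)`` truncated to (0.05, 0.95);
* division threshold — cells exiting stationary phase (where growth-rate
  noise is meaningless because kappa = 0) instead draw their division
  threshold from ``N(1, 0.05)``.

Because the intensive state is shared, it is integrated once per scenario
and every cell integrates only its own (V, X_tilde) pair against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import steady
from .core import CellState
from .dynamics import IntensiveTrajectory, Trajectory, integrate_intensive
from .environment import Environment
from .errors import (CensoredObservation, IntegrationFailure, ParameterError)
from .params import ModelParams

__all__ = [
    "NoiseModel",
    "GenerationRecord",
    "sample_growth_offset",
    "sample_division_ratio",
    "sample_threshold",
    "simulate_lineage",
    "simulate_stationary_exit",
    "stationary_exit_ensemble",
    "ensemble",
    "records_to_dataframe",
]

_RATIO_BOUNDS = (0.05, 0.95)


@dataclass(frozen=True)
class NoiseModel:
    """Noise constants for stochastic simulations.

    ``gr_slope_a`` and ``gr_intercept_b`` parameterize the growth-rate
    standard deviation sigma = a <kappa> + b (1/h); defaults give the
    ~15% growth-rate CV typical of E. coli.
    """

    gr_slope_a: float = 0.15
    gr_intercept_b: float = 0.02
    division_ratio_mean: float = 0.5
    division_ratio_sd: float = 0.04
    threshold_mean: float = 1.0
    threshold_sd: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        for name in ("division_ratio_sd", "threshold_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0 < self.division_ratio_mean < 1):
            raise ParameterError("division_ratio_mean must lie in (0, 1)")

    @classmethod
    def quiet(cls, seed=None) -> "NoiseModel":
        """All noise sources switched off (deterministic lineages)."""
        return cls(gr_slope_a=0.0, gr_intercept_b=0.0, division_ratio_sd=0.0,
                   threshold_sd=0.0, seed=seed)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation observables of one tracked cell."""

    lineage_id: int
    generation: int
    t_birth: float
    t_div: float
    V0: float
    Vd: float
    Delta: float
    tau: float
    delta_kappa: float


def records_to_dataframe(records) -> pd.DataFrame:
    cols = ["lineage_id", "generation", "t_birth", "t_div", "V0", "Vd",
            "Delta", "tau", "delta_kappa"]
    return pd.DataFrame([asdict(r) for r in records], columns=cols)


# ---------------------------------------------------------------------------
# noise draws
# ---------------------------------------------------------------------------

def sample_growth_offset(mean_kappa: float, noise: NoiseModel,
                         rng: np.random.Generator) -> float:
    """Draw the per-generation growth-rate offset delta_kappa ~ N(0, sigma)."""
    sigma = noise.gr_slope_a * mean_kappa + noise.gr_intercept_b
    if sigma < 0:
        raise ParameterError(
            f"negative growth-rate noise sd {sigma:g} at <kappa> = {mean_kappa:g}"
        )
    if sigma == 0:
        return 0.0
    return float(rng.normal(0.0, sigma))


def sample_division_ratio(noise: NoiseModel, rng: np.random.Generator) -> float:
    """Draw the division ratio r ~ N(mean, sd) truncated to (0.05, 0.95)."""
    if noise.division_ratio_sd == 0:
        return noise.division_ratio_mean
    lo, hi = _RATIO_BOUNDS
    for _ in range(1000):
        r = float(rng.normal(noise.division_ratio_mean, noise.division_ratio_sd))
        if lo < r < hi:
            return r
    raise ParameterError("division-ratio sampling failed to land in (0.05, 0.95)")


def sample_threshold(noise: NoiseModel, rng: np.random.Generator) -> float:
    """Draw a division threshold ~ N(mean, sd), truncated positive."""
    if noise.threshold_sd == 0:
        return noise.threshold_mean
    for _ in range(1000):
        x = float(rng.normal(noise.threshold_mean, noise.threshold_sd))
        if x > 0.05 * noise.threshold_mean:
            return x
    raise ParameterError("threshold sampling failed to produce a positive draw")


# ---------------------------------------------------------------------------
# per-cell volume/threshold integration against the shared intensive state
# ---------------------------------------------------------------------------

def _integrate_cell(intensive: IntensiveTrajectory, t_birth: float, V0: float,
                    X0: float, delta_kappa: float, threshold: float,
                    t_end: float, rtol: float = 1e-9, atol: float = 1e-12,
                    collect: bool = False):
    """Integrate (V, X_tilde) from birth until division or t_end.

    Returns ``(t_div_or_None, y_final, ts, Vs, Xs)`` where t_div is the
    root-found crossing time of X_tilde with the threshold.
    """
    mu_X = intensive.params.mu_X

    def rhs(t, y):
        kappa, k_P = intensive.rates(t)
        return ((kappa + delta_kappa) * y[0], k_P * y[0] - mu_X * y[1])

    def crossing(t, y):
        return y[1] - threshold

    crossing.terminal = True
    crossing.direction = 1.0

    cuts = [t_birth] + [b for b in intensive.boundaries if t_birth < b < t_end] \
        + [t_end]
    y = np.array([V0, X0])
    ts, Vs, Xs = [], [], []
    for lo, hi in zip(cuts, cuts[1:]):
        sol = solve_ivp(rhs, (lo, hi), y, method="RK45", rtol=rtol, atol=atol,
                        events=[crossing])
        if not sol.success:
            raise IntegrationFailure(
                f"cell integration failed at t = {lo:g}: {sol.message}",
                t=lo, state=y)
        if collect:
            ts.append(sol.t)
            Vs.append(sol.y[0])
            Xs.append(sol.y[1])
        if sol.status == 1:
            t_div = float(sol.t_events[0][0])
            return t_div, sol.y_events[0][0], ts, Vs, Xs
        y = sol.y[:, -1]
    return None, y, ts, Vs, Xs


# ---------------------------------------------------------------------------
# lineage simulation (track one daughter)
# ---------------------------------------------------------------------------

def simulate_lineage(env: Environment, params: ModelParams, noise: NoiseModel,
                     t_end: float, initial: CellState,
                     rng: np.random.Generator | None = None,
                     lineage_id: int = 0, threshold_noise: bool = False,
                     intensive: IntensiveTrajectory | None = None,
                     collect_trajectory: bool = False,
                     ) -> tuple[Trajectory | None, list[GenerationRecord]]:
    """Simulate one lineage, following a single daughter per division.

    The intensive dynamics follow the population average; the cell's
    volume grows at ``<kappa(t)> + delta_kappa`` with the offset redrawn
    at each birth.  Division thresholds are fixed at their mean unless
    ``threshold_noise`` is on (stationary-exit convention).
    """
    if rng is None:
        rng = noise.rng()
    if intensive is None:
        intensive = integrate_intensive(initial, env, params, t_end)

    records: list[GenerationRecord] = []
    t = initial.t
    V = initial.V
    X = initial.X_tilde
    gen = 0
    all_t, all_V, all_X = [], [], []
    while t < t_end - 1e-12:
        dk = sample_growth_offset(max(intensive.kappa(t), 0.0), noise, rng)
        theta = sample_threshold(noise, rng) if threshold_noise \
            else noise.threshold_mean
        t_div, y_fin, ts, Vs, Xs = _integrate_cell(
            intensive, t, V, X, dk, theta, t_end, collect=collect_trajectory)
        if collect_trajectory:
            all_t.extend(ts)
            all_V.extend(Vs)
            all_X.extend(Xs)
        if t_div is None:
            break
        V_d = float(y_fin[0])
        records.append(GenerationRecord(
            lineage_id=lineage_id, generation=gen, t_birth=t, t_div=t_div,
            V0=V, Vd=V_d, Delta=V_d - V, tau=t_div - t, delta_kappa=dk))
        r = sample_division_ratio(noise, rng)
        t, V, X = t_div, r * V_d, 0.0
        gen += 1

    traj = None
    if collect_trajectory and all_t:
        times = np.concatenate(all_t)
        V_arr = np.concatenate(all_V)
        X_arr = np.concatenate(all_X)
        intens = intensive.state(times)
        states = np.column_stack([intens, V_arr, X_arr])
        traj = Trajectory(times=times, states=states, params=params, env=env,
                          division_events=[(r.t_div, r.Vd, math.nan)
                                           for r in records])
    return traj, records


# ---------------------------------------------------------------------------
# stationary-phase exit
# ---------------------------------------------------------------------------

def stationary_initial_state(params: ModelParams, V_init: float) -> CellState:
    """Stationary-phase fixed point (kappa_n0 = 0) scaled to volume V_init.

    In stationary phase cells hold a constant division-protein
    concentration k_P / mu_X, so the initial X_tilde is proportional to
    the cell's volume.
    """
    ss = steady.solve(0.0, params)
    X0 = ss.kP_star * V_init / params.mu_X
    phi_X = ss.phi_X_star if params.separated else 0.0
    return CellState(a=ss.a_star, phi_R=ss.phi_R_star, phi_X=phi_X,
                     V=V_init, X_tilde=X0, t=0.0)


def simulate_stationary_exit(params: ModelParams, noise: NoiseModel,
                             env: Environment, V_init: float,
                             rng: np.random.Generator | None = None,
                             t_end: float = 24.0,
                             intensive: IntensiveTrajectory | None = None,
                             lineage_id: int = 0,
                             ) -> tuple[float, list[GenerationRecord]]:
    """Simulate one cell exiting stationary phase; return (T_lag, records).

    The cell starts at the stationary fixed point with its division
    threshold drawn from N(1, 0.05); no growth-rate noise is applied
    (kappa = 0 initially makes generational growth noise meaningless).
    T_lag is the time from the onset of feeding (first environment
    segment with kappa_n0 > 0) to the first division.
    """
    if rng is None:
        rng = noise.rng()
    if params.mu_ns <= 0:
        raise ParameterError(
            "stationary exit requires mu_ns > 0 (protein turnover sustains "
            "the stationary fixed point)")
    initial = stationary_initial_state(params, V_init)
    if intensive is None:
        intensive = integrate_intensive(initial, env, params, t_end)
    onsets = [t for t, k in env.segments if k > 0]
    if not onsets:
        raise ParameterError("environment never feeds (all kappa_n0 = 0)")
    t_onset = min(onsets)

    theta = sample_threshold(noise, rng)
    t_div, y_fin, *_ = _integrate_cell(
        intensive, initial.t, V_init, initial.X_tilde, 0.0, theta, t_end)
    if t_div is None:
        raise CensoredObservation(
            f"no division within t_end = {t_end:g} h", horizon=t_end)
    V_d = float(y_fin[0])
    rec = GenerationRecord(
        lineage_id=lineage_id, generation=0, t_birth=initial.t, t_div=t_div,
        V0=V_init, Vd=V_d, Delta=V_d - V_init, tau=t_div - initial.t,
        delta_kappa=0.0)
    return t_div - t_onset, [rec]


def stationary_exit_ensemble(n_cells: int, params: ModelParams,
                             noise: NoiseModel, env: Environment,
                             rng: np.random.Generator | None = None,
                             V_init_range: tuple[float, float] = (0.3, 1.0),
                             t_end: float = 24.0) -> pd.DataFrame:
    """Stationary-exit first divisions for n_cells with randomized volumes.

    Initial volumes are uniform on ``V_init_range`` in units of the
    maximum birth volume 1/gamma_beta.  Returns one row per cell with
    (V_init, Vd, Delta, T_lag, threshold-adjusted observables); cells
    whose division is censored at t_end get NaN.
    """
    if rng is None:
        rng = noise.rng()
    lo, hi = V_init_range
    V_inits = rng.uniform(lo, hi, size=n_cells) * params.V0_max
    # intensive state is identical for all cells: integrate once
    probe = stationary_initial_state(params, V_inits[0])
    intensive = integrate_intensive(probe, env, params, t_end)
    rows = []
    for i, V0 in enumerate(V_inits):
        try:
            T_lag, recs = simulate_stationary_exit(
                params, noise, env, float(V0), rng=rng, t_end=t_end,
                intensive=intensive, lineage_id=i)
            r = recs[0]
            rows.append(dict(lineage_id=i, V_init=V0, Vd=r.Vd, Delta=r.Delta,
                             T_lag=T_lag))
        except CensoredObservation:
            rows.append(dict(lineage_id=i, V_init=V0, Vd=math.nan,
                             Delta=math.nan, T_lag=math.nan))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generation-averaged ensembles
# ---------------------------------------------------------------------------

def ensemble(n_cells: int, env: Environment, params: ModelParams,
             noise: NoiseModel, t_end: float, initial: CellState,
             rng: np.random.Generator | None = None,
             bin_width: float = 0.2, bin_step: float = 0.05,
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run independent lineages and average generation observables in time.

    Returns ``(series, records)`` where ``series`` contains sliding-bin
    averages of added volume, interdivision time, volume ratio and the
    realized generation growth rate ln(Vd/V0)/tau, indexed by division
    time (bins of ``bin_width`` stepped by ``bin_step``); empty bins are
    NaN, never interpolated.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if rng is None:
        rng = noise.rng()
    intensive = integrate_intensive(initial, env, params, t_end)
    all_records: list[GenerationRecord] = []
    for i in range(n_cells):
        _, recs = simulate_lineage(env, params, noise, t_end, initial,
                                   rng=rng, lineage_id=i, intensive=intensive)
        all_records.extend(recs)
    rec_df = records_to_dataframe(all_records)
    if rec_df.empty:
        return pd.DataFrame(columns=["t", "Delta", "tau", "ratio", "kappa",
                                     "n"]), rec_df

    t_div = rec_df["t_div"].to_numpy()
    delta = rec_df["Delta"].to_numpy()
    tau = rec_df["tau"].to_numpy()
    ratio = delta / rec_df["V0"].to_numpy()
    kappa_gen = np.log(rec_df["Vd"].to_numpy() / rec_df["V0"].to_numpy()) / tau

    t0 = initial.t
    centers = np.arange(t0 + bin_width / 2, t_end + bin_step / 2, bin_step)
    out = []
    for c in centers:
        mask = np.abs(t_div - c) <= bin_width / 2
        n = int(mask.sum())
        if n:
            out.append(dict(t=c, Delta=delta[mask].mean(),
                            tau=tau[mask].mean(), ratio=ratio[mask].mean(),
                            kappa=kappa_gen[mask].mean(), n=n))
        else:
            out.append(dict(t=c, Delta=math.nan, tau=math.nan,
                            ratio=math.nan, kappa=math.nan, n=0))
    return pd.DataFrame(out), rec_df
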