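"""Branching population simulation and the population growth-rate estimator.

Unlike lineage simulations, every division spawns *two* tracked daughters
with complementary volumes r*V_d and (1-r)*V_d, so the cell count P(t)
grows over time.  All cells share the population-average intensive state
(they see the same environment and allocation dynamics); volume, division
progress and the growth-rate offset are per cell.  The population growth
rate is reported in doublings per hour,

    kappa_pop(t) = [ln P(t+dt) - ln P(t)] / (dt ln 2),

matching the printed estimator; multiply by ln 2 to compare with the
single-cell exponential rate kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import steady
from .dynamics import integrate_intensive
from .environment import Environment
from .errors import DomainError, ParameterError, SectorSizeError
from .core import CellState
from .params import ModelParams
from .stochastic import (NoiseModel, _integrate_cell, sample_division_ratio,
                         sample_growth_offset)

__all__ = ["PopulationRecord", "simulate_population",
           "population_growth_rate", "smooth_series"]

LN2 = np.log(2.0)


class PopulationCapExceeded(SectorSizeError):
    """The population outgrew the configured cap; carries the time reached."""

    def __init__(self, message, t=None):
        super().__init__(message)
        self.t = t


@dataclass
class PopulationRecord:
    """Cell count and population growth rate on a uniform time grid.

    ``events`` logs each division as (t_div, V_d, V_daughter1,
    V_daughter2); daughters partition V_d exactly.
    """

    times: np.ndarray
    P: np.ndarray
    division_times: np.ndarray
    n0: int
    events: list = None

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def kappa_pop(self) -> np.ndarray:
        """Doublings per hour between successive grid points (length N-1)."""
        return population_growth_rate(self.P, self.dt)

    def to_dataframe(self) -> pd.DataFrame:
        kp = np.append(self.kappa_pop, np.nan)
        return pd.DataFrame({"t": self.times, "P": self.P, "kappa_pop": kp})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _cycle_position_X(V, V0, kappa, mu_X, k_P):
    """Steady-state X_tilde of a cell of volume V within its cycle.

    Inverts the closed-form accumulation X(t) with V = V0 e^(kappa t):
    X = k_P V0 ((V/V0) - (V/V0)^(-mu_X/kappa)) / (kappa + mu_X).
    """
    x = V / V0
    return k_P * V0 * (x - x ** (-mu_X / kappa)) / (kappa + mu_X)


def simulate_population(n0: int, env: Environment, params: ModelParams,
                        noise: NoiseModel, t_end: float,
                        rng: np.random.Generator | None = None,
                        dt: float = 0.01, cap: int = 100_000,
                        initial: CellState | None = None) -> PopulationRecord:
    """Simulate a branching population of n0 founder cells.

    Founders start on the steady-state cycle of the initial environment
    with volumes sampled uniformly over one generation (V0*, 2 V0*) and
    the matching division progress.  Each division creates two daughters
    with complementary volumes (their sum is exactly V_d) and fresh
    independent growth offsets.  Raises :class:`PopulationCapExceeded`
    beyond ``cap`` cells.
    """
    if n0 < 1:
        raise ParameterError("n0 must be >= 1")
    if rng is None:
        rng = noise.rng()

    kn0_init = env.segments[0][1]
    ss = steady.solve(kn0_init, params)
    if not np.isfinite(ss.V0_star):
        raise ParameterError(
            "population simulation needs a cycling initial steady state "
            "(kappa_star > 0)")
    if initial is None:
        initial = CellState(a=ss.a_star, phi_R=ss.phi_R_star,
                            phi_X=ss.phi_X_star if params.separated else 0.0,
                            V=ss.V0_star, X_tilde=0.0, t=0.0)
    intensive = integrate_intensive(initial, env, params, t_end)

    # founders spread over one steady-state cycle
    if n0 == 1:
        V_inits = np.array([ss.V0_star])
    else:
        V_inits = rng.uniform(ss.V0_star, 2.0 * ss.V0_star, size=n0)
    division_times: list[float] = []
    events: list[tuple] = []
    theta = noise.threshold_mean
    n_cells = n0

    # depth-first processing; cells are independent given the shared
    # intensive state, so order does not matter
    stack = []
    for V in V_inits:
        X0 = _cycle_position_X(V, ss.V0_star, ss.kappa_star, params.mu_X,
                               ss.kP_star) if n0 > 1 else 0.0
        dk = sample_growth_offset(max(ss.kappa_star, 0.0), noise, rng)
        stack.append((0.0, float(V), float(max(X0, 0.0)), dk))

    while stack:
        t_birth, V0, X0, dk = stack.pop()
        t_div, y_fin, *_ = _integrate_cell(intensive, t_birth, V0, X0, dk,
                                           theta, t_end)
        if t_div is None:
            continue
        V_d = float(y_fin[0])
        division_times.append(t_div)
        n_cells += 1
        if n_cells > cap:
            raise PopulationCapExceeded(
                f"population cap {cap} exceeded at t = {t_div:g}", t=t_div)
        r = sample_division_ratio(noise, rng)
        kap_here = max(intensive.kappa(t_div), 0.0)
        daughters = (r * V_d, (1.0 - r) * V_d)
        events.append((t_div, V_d, daughters[0], daughters[1]))
        for V_birth in daughters:
            dk_child = sample_growth_offset(kap_here, noise, rng)
            stack.append((t_div, V_birth, 0.0, dk_child))

    div_arr = np.sort(np.asarray(division_times))
    times = np.arange(0.0, t_end + dt / 2, dt)
    P = n0 + np.searchsorted(div_arr, times, side="right")
    return PopulationRecord(times=times, P=P.astype(int),
                            division_times=div_arr, n0=n0, events=events)


def population_growth_rate(P, dt: float) -> np.ndarray:
    """Discrete log-derivative of the cell count, in doublings per hour."""
    P_arr = np.asarray(P, dtype=float)
    if np.any(P_arr <= 0):
        raise DomainError("cell counts must be positive")
    if dt <= 0:
        raise DomainError("dt must be > 0")
    return np.diff(np.log(P_arr)) / (dt * LN2)


def smooth_series(x, dt: float, window: float = 0.25) -> np.ndarray:
    """Centered moving average over a time window (hours).

    The discrete-count staircase in kappa_pop is smoothed before
    comparison with the single-cell rate.
    """
    n = max(1, int(round(window / dt)))
    if n % 2 == 0:
        n += 1
    kernel = np.ones(n) / n
    x_arr = np.asarray(x, dtype=float)
    pad = n // 2
    padded = np.concatenate([np.full(pad, x_arr[0]), x_arr,
                             np.full(pad, x_arr[-1])])
    return np.convolve(padded, kernel, mode="valid")
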