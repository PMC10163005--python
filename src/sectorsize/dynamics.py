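"""Deterministic time integration with event-detected division.

Two integration surfaces are provided:

* :func:`integrate` — the full five-variable single-cell system
  (a, phi_R, phi_X, V, X_tilde) with root-found division events and
  piecewise-constant environments, returning a :class:`Trajectory`.
* :func:`integrate_intensive` — only the intensive (per-unit-mass)
  subsystem, whose solution is shared by every cell in the stochastic
  lineage and population simulations (growth-rate noise enters the volume
  equation alone, so the intensive state is integrated once).

Environment switches are handled by segment-wise restarts, never by a
discontinuous right-hand side inside a step.  Division resets X_tilde to
zero (the threshold counts proteins accumulated since birth) and jumps
V to r * V_d; the intensive variables are continuous across division.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import core
from .environment import Environment
from .errors import IntegrationFailure
from .params import ModelParams

__all__ = ["Trajectory", "IntensiveTrajectory", "integrate", "integrate_intensive"]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


def _make_rhs(params: ModelParams, kappa_n0: float):
    """Scalar right-hand side for one constant-environment segment."""
    p = params
    an2, at2 = p.a_n * p.a_n, p.a_t * p.a_t
    sep = p.separated

    def rhs(t, y):
        a, phi_R, phi_X, V, X = y
        u = a * a / an2
        v = a * a / at2
        f_a = 1.0 / (1.0 + u)
        g_a = v / (1.0 + v)
        A = v / (an2 * (1.0 + u))
        B = 1.0 / (at2 * (1.0 + v))
        f_R = (A * p.phi_R_max + B * p.phi_R_min) / (A + B)
        J_t = p.kappa_t0 * g_a * (phi_R - p.phi_R_min)
        kappa = J_t - p.mu_ns
        if sep:
            f_X = p.alpha * (p.phi_R_max - f_R) + p.beta
            phi_P = p.phi_max - phi_R - phi_X
            g_fX = p.gamma * f_X
        else:
            f_X = p.gamma_alpha * (p.phi_R_max - f_R) + p.gamma_beta
            phi_P = p.phi_max - phi_R
            g_fX = f_X
        da = kappa_n0 * f_a * phi_P - J_t + p.mu_ns
        dphi_R = J_t * (f_R - phi_R)
        dphi_X = J_t * (f_X - phi_X) - (p.mu_X - p.mu_ns) * phi_X
        return (da, dphi_R, dphi_X, kappa * V, g_fX * J_t * V - p.mu_X * X)

    return rhs


@dataclass
class Trajectory:
    """Integrated single-cell trajectory with derived series.

    ``states`` has columns (a, phi_R, phi_X, V, X_tilde); division events
    are ``(t, V_d, V0_next)`` triples.  Derived series (growth rate,
    allocation fractions, k_P, implied phi_P) are computed lazily from
    the state arrays.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParams
    env: Environment
    division_events: list = field(default_factory=list)
    threshold: float = 1.0
    r: float = 0.5

    @property
    def a(self): return self.states[:, 0]

    @property
    def phi_R(self): return self.states[:, 1]

    @property
    def phi_X(self): return self.states[:, 2]

    @property
    def V(self): return self.states[:, 3]

    @property
    def X_tilde(self): return self.states[:, 4]

    @property
    def kappa(self):
        return core.growth_rate(self.phi_R, self.a, self.params)

    @property
    def f_R(self):
        return core.allocation_fR(self.a, self.params)

    @property
    def f_X(self):
        """Division allocation (mass fraction if separated, else gamma-scaled)."""
        if self.params.separated:
            return core.allocation_fX(
                np.clip(self.f_R, self.params.phi_R_min, self.params.phi_R_max),
                self.params)
        return core.gamma_fX(self.f_R, self.params)

    @property
    def k_P(self):
        return core.kP_instantaneous(self.f_R, self.kappa, self.params)

    @property
    def phi_P(self):
        if self.params.separated:
            return self.params.phi_max - self.phi_R - self.phi_X
        return self.params.phi_max - self.phi_R

    @property
    def final_state(self) -> core.CellState:
        a, pR, pX, V, X = self.states[-1]
        return core.CellState(a=max(a, 0.0), phi_R=pR, phi_X=max(pX, 0.0), V=V,
                              X_tilde=max(X, 0.0), t=float(self.times[-1]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times, "a": self.a, "phi_R": self.phi_R,
            "phi_X": self.phi_X, "phi_P": self.phi_P, "V": self.V,
            "X_tilde": self.X_tilde, "kappa": self.kappa,
            "f_R": self.f_R, "f_X": self.f_X, "k_P": self.k_P,
        })

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.division_events,
                            columns=["t", "V_d", "V0_next"])

    def to_csv(self, path, events_path=None) -> None:
        self.to_dataframe().to_csv(path, index=False)
        if events_path is not None:
            self.events_dataframe().to_csv(events_path, index=False)

    def generation_table(self) -> pd.DataFrame:
        """Birth/division times and volumes for each completed generation."""
        rows = []
        t_birth = self.times[0]
        V_birth = self.states[0, 3]
        for i, (t_div, V_d, V0_next) in enumerate(self.division_events):
            rows.append(dict(generation=i, t_birth=t_birth, t_div=t_div,
                             V0=V_birth, Vd=V_d, Delta=V_d - V_birth,
                             tau=t_div - t_birth))
            t_birth, V_birth = t_div, V0_next
        return pd.DataFrame(rows)


def integrate(initial: core.CellState, env: Environment, params: ModelParams,
              t_end: float, division: bool = True, threshold: float = 1.0,
              r: float = 0.5, rtol: float = DEFAULT_RTOL,
              atol: float = DEFAULT_ATOL, method: str = "LSODA",
              max_divisions: int = 100_000) -> Trajectory:
    """Integrate the coupled system from ``initial`` until ``t_end``.

    Division events are located by root-finding on X_tilde - threshold
    (only when ``division`` is on); at each event the volume jumps to
    r * V_d and X_tilde resets to zero, while a, phi_R and phi_X remain
    continuous.  Environment switches restart the integrator exactly at
    the segment boundary.
    """
    if t_end <= initial.t:
        raise IntegrationFailure("t_end must exceed the initial time")
    if not (0.0 < r < 1.0):
        raise IntegrationFailure(f"division ratio must lie in (0, 1), got {r}")

    t_cur = initial.t
    y = initial.as_array()
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    events: list[tuple[float, float, float]] = []

    def crossing(t, yy):
        return yy[4] - threshold

    crossing.terminal = True
    crossing.direction = 1.0

    while t_cur < t_end - 1e-14:
        for lo, hi, kn0 in env.pieces(t_cur, t_end):
            rhs = _make_rhs(params, kn0)
            seg_t = lo
            while seg_t < hi - 1e-14:
                sol = solve_ivp(
                    rhs, (seg_t, hi), y, method=method, rtol=rtol, atol=atol,
                    events=[crossing] if division else None, dense_output=False,
                )
                if not sol.success:
                    raise IntegrationFailure(
                        f"integration failed at t = {seg_t:g}: {sol.message}",
                        t=seg_t, state=y)
                if not np.all(np.isfinite(sol.y)):
                    raise IntegrationFailure(
                        f"non-finite state at t = {seg_t:g}", t=seg_t, state=y)
                ts.append(sol.t)
                ys.append(sol.y.T)
                if division and sol.status == 1:  # division event
                    t_div = sol.t_events[0][0]
                    y_div = sol.y_events[0][0]
                    V_d = y_div[3]
                    V0_next = r * V_d
                    if len(events) >= max_divisions:
                        raise IntegrationFailure(
                            "division cap exceeded", t=t_div, state=y_div)
                    events.append((float(t_div), float(V_d), float(V0_next)))
                    y = y_div.copy()
                    y[3] = V0_next
                    y[4] = 0.0
                    seg_t = float(t_div)
                    # record the post-division state sample
                    ts.append(np.array([seg_t]))
                    ys.append(y[None, :])
                else:
                    y = sol.y[:, -1].copy()
                    seg_t = hi
            t_cur = hi

    times = np.concatenate(ts)
    states = np.vstack(ys)
    return Trajectory(times=times, states=states, params=params, env=env,
                      division_events=events, threshold=threshold, r=r)


# ---------------------------------------------------------------------------
# shared intensive dynamics
# ---------------------------------------------------------------------------

class IntensiveTrajectory:
    """Dense solution of the intensive subsystem (a, phi_R, phi_X).

    Division does not alter the intensive variables, so one solve serves
    every cell and generation of a stochastic simulation.  Piecewise
    dense output is kept per environment segment; evaluation snaps to the
    owning segment so the discontinuity in kappa_n0 is honoured exactly.
    """

    def __init__(self, initial, env: Environment, params: ModelParams,
                 t_end: float, rtol: float = DEFAULT_RTOL,
                 atol: float = DEFAULT_ATOL, method: str = "LSODA"):
        self.params = params
        self.env = env
        if isinstance(initial, core.CellState):
            y = np.array([initial.a, initial.phi_R, initial.phi_X])
            self.t0 = initial.t
        else:
            y = np.asarray(initial, dtype=float)[:3].copy()
            self.t0 = 0.0
        self.t_end = float(t_end)
        self._segs: list[tuple[float, float, object]] = []
        for lo, hi, kn0 in env.pieces(self.t0, self.t_end):
            rhs3 = self._rhs3(kn0)
            sol = solve_ivp(rhs3, (lo, hi), y, method=method, rtol=rtol,
                            atol=atol, dense_output=True)
            if not sol.success:
                raise IntegrationFailure(
                    f"intensive integration failed at t = {lo:g}: {sol.message}",
                    t=lo, state=y)
            self._segs.append((lo, hi, sol.sol))
            y = sol.y[:, -1].copy()
        self._ends = np.array([hi for _, hi, _ in self._segs])

    def _rhs3(self, kappa_n0):
        full = _make_rhs(self.params, kappa_n0)

        def rhs(t, y):
            d = full(t, (y[0], y[1], y[2], 1.0, 0.0))
            return d[:3]

        return rhs

    @property
    def boundaries(self) -> list[float]:
        """Interior segment boundaries (environment switch times)."""
        return [lo for lo, _, _ in self._segs[1:]]

    def state(self, t):
        """Intensive state (a, phi_R, phi_X) at scalar or array t."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        t_clip = np.clip(t_arr, self.t0, self.t_end)
        idx = np.minimum(np.searchsorted(self._ends, t_clip, side="left"),
                         len(self._segs) - 1)
        out = np.empty((t_arr.size, 3))
        for i, (tc, j) in enumerate(zip(t_clip, idx)):
            out[i] = self._segs[j][2](tc)
        return out if np.ndim(t) else out[0]

    def rates(self, t: float) -> tuple[float, float]:
        """Fast scalar (kappa, k_P) at time t for per-cell integrators."""
        p = self.params
        tc = min(max(t, self.t0), self.t_end)
        j = min(int(np.searchsorted(self._ends, tc, side="left")),
                len(self._segs) - 1)
        a, phi_R, _ = self._segs[j][2](tc)
        v = (a / p.a_t) ** 2
        u = (a / p.a_n) ** 2
        g_a = v / (1.0 + v)
        A = v / (p.a_n**2 * (1.0 + u))
        B = 1.0 / (p.a_t**2 * (1.0 + v))
        f_R = (A * p.phi_R_max + B * p.phi_R_min) / (A + B)
        J_t = p.kappa_t0 * g_a * (phi_R - p.phi_R_min)
        kappa = J_t - p.mu_ns
        k_P = (p.gamma_alpha * (p.phi_R_max - f_R) + p.gamma_beta) * J_t
        return kappa, k_P

    def kappa(self, t):
        """Population-average growth rate at time t."""
        s = np.atleast_2d(self.state(t))
        out = core.growth_rate(s[:, 1], s[:, 0], self.params)
        return out if np.ndim(t) else float(np.atleast_1d(out)[0])

    def k_P(self, t):
        """Division-protein production rate per volume at time t."""
        s = np.atleast_2d(self.state(t))
        f_R = core.allocation_fR(s[:, 0], self.params)
        kap = core.growth_rate(s[:, 1], s[:, 0], self.params)
        out = core.gamma_fX(f_R, self.params) * (kap + self.params.mu_ns)
        return out if np.ndim(t) else float(np.atleast_1d(out)[0])


def integrate_intensive(initial, env: Environment, params: ModelParams,
                        t_end: float, rtol: float = DEFAULT_RTOL,
                        atol: float = DEFAULT_ATOL) -> IntensiveTrajectory:
    """Integrate only the intensive subsystem; see :class:`IntensiveTrajectory`."""
    return IntensiveTrajectory(initial, env, params, t_end, rtol=rtol, atol=atol)
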