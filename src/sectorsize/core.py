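"""Regulatory functions, allocation rules and state derivatives.

The cell is coarse-grained into four proteome sectors — ribosomal (R),
metabolic (P), division (X) and invariant housekeeping (Q) — plus the
growth-limiting amino-acid pool with mass fraction ``a``.  Nutrients are
imported by the P sector with nutritional efficiency
``kappa_n(a) = kappa_n0 * f(a)`` and consumed by actively translating
ribosomes with translational efficiency ``kappa_t(a) = kappa_t0 * g(a)``.
The instantaneous growth rate is

    kappa = kappa_t(a) * (phi_R - phi_R_min) - mu_ns,

and division is triggered once the normalized number of division proteins
accumulated since birth, ``X_tilde``, reaches a threshold (1 by default).

All functions accept scalars or numpy arrays for the state-like arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConstraintViolation, DomainError, ParameterError
from .params import ModelParams

__all__ = [
    "CellState",
    "f_inhibition",
    "g_attenuation",
    "allocation_fR",
    "allocation_fX",
    "gamma_fX",
    "translational_flux",
    "growth_rate",
    "kP_instantaneous",
    "state_derivatives",
]


@dataclass(frozen=True)
class CellState:
    """Instantaneous intracellular state of one cell.

    ``phi_X`` is the division-sector mass fraction when the parameters
    separate alpha/beta; in composite mode it stores the gamma-scaled
    density ``gamma * phi_X`` (um^-3), a pure diagnostic that does not
    feed back on the dynamics.
    """

    a: float
    phi_R: float
    phi_X: float
    V: float
    X_tilde: float
    t: float = 0.0

    def __post_init__(self):
        if self.a < 0:
            raise DomainError(f"a must be >= 0, got {self.a}")
        if not (0 <= self.phi_R <= 1):
            raise DomainError(f"phi_R must lie in [0, 1], got {self.phi_R}")
        if self.phi_X < 0:
            raise DomainError(f"phi_X must be >= 0, got {self.phi_X}")
        if self.V <= 0:
            raise DomainError(f"V must be > 0, got {self.V}")
        if self.X_tilde < 0:
            raise DomainError(f"X_tilde must be >= 0, got {self.X_tilde}")

    def replace(self, **changes) -> "CellState":
        return replace(self, **changes)

    def as_array(self) -> np.ndarray:
        """State vector (a, phi_R, phi_X, V, X_tilde) for the integrator."""
        return np.array([self.a, self.phi_R, self.phi_X, self.V, self.X_tilde])


# ---------------------------------------------------------------------------
# regulatory functions
# ---------------------------------------------------------------------------

def f_inhibition(a, a_n):
    """Feedback inhibition of nutrient influx, f(a) = 1 / (1 + (a/a_n)^2).

    Strictly decreasing; f(0) = 1, f(a_n) = 1/2.
    """
    if a_n <= 0:
        raise ParameterError(f"a_n must be > 0, got {a_n}")
    x = np.asarray(a, dtype=float) / a_n
    out = 1.0 / (1.0 + x * x)
    return out if out.ndim else float(out)


def g_attenuation(a, a_t):
    """Translational attenuation, g(a) = (a/a_t)^2 / (1 + (a/a_t)^2).

    Strictly increasing; g(0) = 0, g(a_t) = 1/2, g(inf) -> 1.
    """
    if a_t <= 0:
        raise ParameterError(f"a_t must be > 0, got {a_t}")
    x = np.asarray(a, dtype=float) / a_t
    x2 = x * x
    out = x2 / (1.0 + x2)
    return out if out.ndim else float(out)


def allocation_fR(a, params: ModelParams):
    """Flux-maximizing ribosomal allocation fraction f_R*(a).

    Chosen so that the steady-state translational flux is maximal subject
    to flux balance, which gives

        f_R*(a) = (-f' g phi_R_max + f g' phi_R_min) / (-f' g + f g')

    with f, g the regulatory functions above.  Cancelling the common
    factor 2a / ((1+u)(1+v)), u = (a/a_n)^2, v = (a/a_t)^2, reduces this
    to the numerically robust form

        f_R*(a) = (A phi_R_max + B phi_R_min) / (A + B),
        A = v / (a_n^2 (1+u)),  B = 1 / (a_t^2 (1+v)),

    which evaluates to the exact limits phi_R_min at a = 0 and
    phi_R_max as a -> inf with no 0/0 indeterminacy.  Monotonically
    increasing in a.
    """
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < 0):
        raise DomainError("a must be >= 0")
    u = (a_arr / params.a_n) ** 2
    v = (a_arr / params.a_t) ** 2
    A = v / (params.a_n**2 * (1.0 + u))
    B = 1.0 / (params.a_t**2 * (1.0 + v))
    out = (A * params.phi_R_max + B * params.phi_R_min) / (A + B)
    return out if out.ndim else float(out)


def allocation_fX(f_R, params: ModelParams):
    """Division allocation fraction f_X = alpha (phi_R_max - f_R) + beta.

    Requires separated alpha/beta; use :func:`gamma_fX` for the composite
    gamma-scaled version available in every mode.
    """
    if not params.separated:
        raise ParameterError(
            "allocation_fX needs alpha and beta; in composite mode use gamma_fX"
        )
    f_R_arr = np.asarray(f_R, dtype=float)
    lo, hi = params.phi_R_min, params.phi_R_max
    if np.any(f_R_arr < lo - 1e-12) or np.any(f_R_arr > hi + 1e-12):
        raise DomainError(f"f_R must lie in [{lo}, {hi}]")
    out = params.alpha * (params.phi_R_max - f_R_arr) + params.beta
    return out if out.ndim else float(out)


def gamma_fX(f_R, params: ModelParams):
    """Composite gamma * f_X = gamma_alpha (phi_R_max - f_R) + gamma_beta, um^-3."""
    f_R_arr = np.asarray(f_R, dtype=float)
    out = params.gamma_alpha * (params.phi_R_max - f_R_arr) + params.gamma_beta
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fluxes and rates
# ---------------------------------------------------------------------------

def translational_flux(phi_R, a, params: ModelParams):
    """J_t = kappa_t0 g(a) (phi_R - phi_R_min), 1/h."""
    return params.kappa_t0 * g_attenuation(a, params.a_t) * (
        np.asarray(phi_R, dtype=float) - params.phi_R_min
    )


def growth_rate(phi_R, a, params: ModelParams):
    """Instantaneous growth rate kappa = J_t - mu_ns, 1/h.

    May be negative (net shrinkage of protein mass) when translation is
    attenuated or ribosome content is at its inactive floor.
    """
    out = translational_flux(phi_R, a, params) - params.mu_ns
    out = np.asarray(out)
    return out if out.ndim else float(out)


def kP_instantaneous(f_R, kappa, params: ModelParams):
    """Division-protein synthesis rate per unit volume, um^-3 h^-1.

    k_P = gamma f_X (kappa + mu_ns) = [gamma_alpha (phi_R_max - f_R)
    + gamma_beta] (kappa + mu_ns).  In stationary phase (kappa = 0) this
    stays positive through protein turnover, k_P = gamma f_X mu_ns.
    """
    out = gamma_fX(f_R, params) * (np.asarray(kappa, dtype=float) + params.mu_ns)
    out = np.asarray(out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# coupled derivatives
# ---------------------------------------------------------------------------

def state_derivatives(state: CellState, kappa_n0: float, params: ModelParams,
                      check: bool = True) -> np.ndarray:
    """Time derivatives (da/dt, dphi_R/dt, dphi_X/dt, dV/dt, dX_tilde/dt).

    The intensive dynamics are

        dphi_R/dt = J_t (f_R(a) - phi_R)
        dphi_X/dt = J_t (f_X(a) - phi_X) - (mu_X - mu_ns) phi_X
        da/dt     = kappa_n0 f(a) phi_P - J_t + mu_ns

    with J_t = kappa_t0 g(a)(phi_R - phi_R_min) and the metabolic sector
    phi_P = phi_max - phi_R - phi_X implied by the proteome constraint.
    Volume grows exponentially, dV/dt = kappa V, and the normalized
    division-protein count obeys dX_tilde/dt = gamma f_X J_t V
    - mu_X X_tilde (k_P per volume times V, minus degradation).

    In composite mode (alpha/beta absent) the division sector's mass is
    neglected in phi_P and phi_X is carried gamma-scaled (um^-3).
    """
    if kappa_n0 < 0:
        raise DomainError(f"kappa_n0 must be >= 0, got {kappa_n0}")
    a, phi_R, phi_X, V, X_tilde = state.a, state.phi_R, state.phi_X, state.V, state.X_tilde

    f_a = f_inhibition(a, params.a_n)
    J_t = translational_flux(phi_R, a, params)
    kappa = J_t - params.mu_ns
    f_R = allocation_fR(a, params)

    if params.separated:
        f_X = allocation_fX(np.clip(f_R, params.phi_R_min, params.phi_R_max), params)
        phi_P = params.phi_max - phi_R - phi_X
        g_fX = params.gamma * f_X
    else:
        f_X = gamma_fX(f_R, params)  # gamma-scaled, um^-3
        phi_P = params.phi_max - phi_R  # division-sector mass neglected
        g_fX = f_X

    if check and phi_P < -1e-9:
        raise ConstraintViolation(
            f"implied phi_P = {phi_P:g} < 0 at t = {state.t:g} (model misuse)"
        )

    da = kappa_n0 * f_a * phi_P - J_t + params.mu_ns
    dphi_R = J_t * (f_R - phi_R)
    dphi_X = J_t * (f_X - phi_X) - (params.mu_X - params.mu_ns) * phi_X
    dV = kappa * V
    dX = g_fX * (kappa + params.mu_ns) * V - params.mu_X * X_tilde
    return np.array([da, dphi_R, dphi_X, dV, dX])
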