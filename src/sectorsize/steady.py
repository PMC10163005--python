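"""Steady-state analysis: fixed points, the size law, and calibration.

At steady state the allocation fraction equals the mass fraction
(f_R = phi_R), which closes the model into a one-dimensional fixed-point
problem in the amino-acid mass fraction ``a``.  All generation-cycle
quantities (birth volume, added volume, interdivision time) follow from
the threshold-accumulation division rule in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import core
from .errors import DomainError, NoSteadyStateError
from .params import ModelParams

__all__ = [
    "SteadyState",
    "solve",
    "kappa_of_a",
    "a_of_kappa",
    "kP_at_growth_rate",
    "kP_steady",
    "size_law_V0",
    "birth_size_full",
    "calibrate_from_observables",
]

# bracket for the 1-D root search in log10(a)
_A_LO_FACTOR = 1e-3
_A_HI_FACTOR = 1e3


@dataclass(frozen=True)
class SteadyState:
    """Self-consistent fixed point of the intensive dynamics.

    ``V0_star``, ``tau_star`` and ``Delta_star`` are NaN in stationary
    phase (kappa_star = 0), where cells do not cycle; the stationary
    division-protein density per volume is then ``kP_star / mu_X``
    (threshold units per um^3), exposed as :attr:`x_density_star`.
    """

    a_star: float
    phi_R_star: float
    phi_X_star: float  # mass fraction (separated mode) or NaN (composite)
    kappa_star: float
    kP_star: float
    V0_star: float
    tau_star: float
    Delta_star: float
    kappa_n0: float

    @property
    def Vd_star(self) -> float:
        """Division volume at steady state (symmetric division)."""
        return 2.0 * self.V0_star

    @property
    def x_density_star(self) -> float:
        """Stationary X_tilde per unit volume, k_P / mu_X (um^-3)."""
        return self.kP_star / self.mu_X if self.mu_X > 0 else math.nan

    # stashed for convenience
    mu_X: float = math.nan


def _phi_X_fixed(a: float, params: ModelParams) -> float:
    """Fixed point of the division-sector mass balance at given a."""
    f_R = core.allocation_fR(a, params)
    J_t = core.translational_flux(f_R, a, params)
    if params.separated:
        f_X = core.allocation_fX(f_R, params)
    else:
        f_X = core.gamma_fX(f_R, params)
    denom = J_t + params.mu_X - params.mu_ns
    if denom <= 0:
        return f_X  # degenerate: no net relaxation, sector tracks allocation
    return J_t * f_X / denom


def _residual(a: float, kappa_n0: float, params: ModelParams) -> float:
    """da/dt evaluated on the manifold phi_R = f_R(a), phi_X at fixed point."""
    f_R = core.allocation_fR(a, params)
    J_t = core.translational_flux(f_R, a, params)
    if params.separated:
        phi_P = params.phi_max - f_R - _phi_X_fixed(a, params)
    else:
        phi_P = params.phi_max - f_R
    return kappa_n0 * core.f_inhibition(a, params.a_n) * phi_P - J_t + params.mu_ns


def solve(kappa_n0: float, params: ModelParams) -> SteadyState:
    """Solve for the self-consistent steady state at nutrient quality kappa_n0.

    Root-finds da/dt = 0 on a logarithmic bracket in ``a`` (the residual
    is monotone decreasing), then evaluates growth rate, division-protein
    production and the generation cycle.  Raises
    :class:`NoSteadyStateError` when the residual has no root — e.g.
    kappa_n0 = 0 with mu_ns = 0, where translation starves completely.
    """
    if kappa_n0 < 0:
        raise DomainError(f"kappa_n0 must be >= 0, got {kappa_n0}")
    a_lo = params.a_t * _A_LO_FACTOR
    a_hi = params.a_n * _A_HI_FACTOR
    r_lo = _residual(a_lo, kappa_n0, params)
    r_hi = _residual(a_hi, kappa_n0, params)
    if r_lo == 0.0:
        a_star = a_lo
    elif r_lo * r_hi > 0:
        raise NoSteadyStateError(
            f"no steady state for kappa_n0 = {kappa_n0:g}: residual does not "
            f"change sign on [{a_lo:g}, {a_hi:g}] "
            f"(r_lo = {r_lo:g}, r_hi = {r_hi:g})"
        )
    else:
        # bisect in log-space for robustness across four decades
        a_star = 10 ** brentq(
            lambda la: _residual(10**la, kappa_n0, params),
            math.log10(a_lo), math.log10(a_hi), xtol=1e-15, rtol=8.9e-16,
        )

    phi_R = core.allocation_fR(a_star, params)
    J_t = core.translational_flux(phi_R, a_star, params)
    kappa = J_t - params.mu_ns
    kP = core.kP_instantaneous(phi_R, kappa, params)
    phi_X = _phi_X_fixed(a_star, params) if params.separated else math.nan

    if kappa > 1e-12:
        V0 = birth_size_full(kappa, params, k_P=kP)
        tau = math.log(2.0) / kappa
        Delta = V0  # V_d - V_0 = 2 V_0 - V_0 under symmetric division
    else:
        kappa = max(kappa, 0.0)
        V0 = tau = Delta = math.nan
    return SteadyState(
        a_star=a_star, phi_R_star=phi_R, phi_X_star=phi_X,
        kappa_star=kappa, kP_star=kP, V0_star=V0, tau_star=tau,
        Delta_star=Delta, kappa_n0=kappa_n0, mu_X=params.mu_X,
    )


# ---------------------------------------------------------------------------
# the steady-state map kappa <-> a and exact k_P(kappa)
# ---------------------------------------------------------------------------

def kappa_of_a(a, params: ModelParams):
    """Steady-state growth rate at amino-acid level a (monotone increasing)."""
    f_R = core.allocation_fR(a, params)
    return core.growth_rate(f_R, a, params)


def a_of_kappa(kappa: float, params: ModelParams) -> float:
    """Invert the monotone steady-state map kappa(a) (no kappa_n0 needed)."""
    a_lo = params.a_t * _A_LO_FACTOR
    a_hi = params.a_n * _A_HI_FACTOR
    k_lo = kappa_of_a(a_lo, params)
    k_hi = kappa_of_a(a_hi, params)
    if not (k_lo <= kappa <= k_hi):
        raise DomainError(
            f"kappa = {kappa:g} outside the attainable steady-state range "
            f"[{k_lo:g}, {k_hi:g}]"
        )
    la = brentq(lambda la: kappa_of_a(10**la, params) - kappa,
                math.log10(a_lo), math.log10(a_hi), xtol=1e-15, rtol=8.9e-16)
    return 10**la


def kP_at_growth_rate(kappa: float, params: ModelParams) -> float:
    """Exact steady-state k_P at growth rate kappa, um^-3 h^-1.

    Uses the steady-state relation phi_R = f_R(a(kappa)) rather than the
    printed quadratic approximation (:func:`kP_steady`), which assumes
    full translational activation g(a) = 1.
    """
    a = a_of_kappa(kappa, params)
    return core.kP_instantaneous(core.allocation_fR(a, params), kappa, params)


def kP_steady(kappa, params: ModelParams):
    """Division-protein production rate vs growth rate (printed form).

    k_P(kappa) = [gamma_alpha (delta_phi - (kappa + mu_ns)/kappa_t0)
    + gamma_beta] (kappa + mu_ns): a downward quadratic in kappa + mu_ns,
    non-monotonic with a unique interior maximum.
    """
    y = np.asarray(kappa, dtype=float) + params.mu_ns
    out = (params.gamma_alpha * (params.delta_phi - y / params.kappa_t0)
           + params.gamma_beta) * y
    return out if out.ndim else float(out)


def kP_steady_argmax(params: ModelParams) -> float:
    """Location of the interior maximum of :func:`kP_steady` (vertex)."""
    y_star = (params.gamma_alpha * params.delta_phi + params.gamma_beta) \
        * params.kappa_t0 / (2.0 * params.gamma_alpha)
    return y_star - params.mu_ns


def size_law_V0(kappa, params: ModelParams):
    """Steady-state birth volume (size law, degradation neglected), um^3.

    V_0(kappa) = 1 / (gamma_alpha (delta_phi - kappa/kappa_t0)
    + gamma_beta), increasing in kappa on the physical range
    [0, kappa_t0 * delta_phi]; V_0(kappa_max) = 1/gamma_beta.
    """
    k = np.asarray(kappa, dtype=float)
    denom = params.gamma_alpha * (params.delta_phi - k / params.kappa_t0) \
        + params.gamma_beta
    if np.any(denom <= 0):
        raise DomainError(
            "kappa outside the physical size-law range (denominator <= 0); "
            f"upper growth-rate limit is kappa_t0*delta_phi + "
            f"gamma_beta*kappa_t0/gamma_alpha = "
            f"{params.kappa_max + params.gamma_beta * params.kappa_t0 / params.gamma_alpha:g}"
        )
    out = 1.0 / denom
    return out if out.ndim else float(out)


def birth_size_full(kappa: float, params: ModelParams,
                    k_P: float | None = None) -> float:
    """Steady-state birth volume with division-protein degradation, um^3.

    With symmetric division, X_tilde reset to 0 at birth, exponential
    volume growth V(t) = V_0 e^(kappa t) and e^(kappa tau) = 2, the
    threshold condition integrates to

        X_tilde(tau) = k_P V_0 (e^(kappa tau) - e^(-mu_X tau)) / (kappa + mu_X) = 1

    giving V_0 = (kappa + mu_X) / [k_P (2 - 2^(-mu_X/kappa))].  The
    mu_X -> 0 limit recovers the adder expression V_0 = kappa / k_P; for
    mu_X >> kappa the division size approaches the sizer set point
    V_d = mu_X / k_P.
    """
    if kappa <= 0:
        raise DomainError(
            "birth_size_full requires kappa > 0; use solve() for the "
            "stationary branch"
        )
    if k_P is None:
        k_P = kP_at_growth_rate(kappa, params)
    return (kappa + params.mu_X) / (k_P * (2.0 - 2.0 ** (-params.mu_X / kappa)))


# ---------------------------------------------------------------------------
# calibration from observables
# ---------------------------------------------------------------------------

def calibrate_kappa_n0(kappa_target: float, params: ModelParams,
                       bracket: tuple[float, float] = (1e-6, 1e6)) -> float:
    """Nutrient quality kappa_n0 whose steady state grows at kappa_target."""
    kappa_ceiling = kappa_of_a(params.a_n * _A_HI_FACTOR, params)
    if kappa_target >= kappa_ceiling:
        raise DomainError(
            f"target growth rate {kappa_target:g} unreachable; physical "
            f"limit is kappa_t0*delta_phi - mu_ns = "
            f"{params.kappa_max - params.mu_ns:g}"
        )
    if kappa_target <= 0 and params.mu_ns == 0:
        return 0.0

    def h(log_kn):
        return solve(10**log_kn, params).kappa_star - kappa_target

    lo, hi = math.log10(bracket[0]), math.log10(bracket[1])
    if params.mu_ns > 0 and kappa_target <= solve(0.0, params).kappa_star:
        return 0.0
    return 10 ** brentq(h, lo, hi, xtol=1e-13)


def calibrate_from_observables(kappa_low: float, kappa_high: float,
                               V0_low: float, V0_high: float,
                               kappa_t0: float, mu_X: float,
                               base_params: ModelParams | None = None,
                               ) -> tuple[float, float, float, float]:
    """Infer (kappa_n0_low, kappa_n0_high, gamma_alpha, gamma_beta).

    For each growth condition, root-finds the nutrient quality that
    reproduces the observed steady-state growth rate; the two observed
    birth volumes then determine the composite division-allocation
    constants through the linear system

        gamma_alpha * s_j + gamma_beta = k_P,j / (kappa_j + mu_ns),
        k_P,j = (kappa_j + mu_X) / (V0_j (2 - 2^(-mu_X/kappa_j))),

    where s_j = phi_R_max - f_R(a*_j) is the co-regulated allocation head
    room in condition j.
    """
    if not (kappa_low < kappa_high) and not (kappa_low == kappa_high):
        raise DomainError("need kappa_low <= kappa_high")
    if V0_low <= 0 or V0_high <= 0:
        raise DomainError("birth volumes must be positive")
    base = base_params if base_params is not None else ModelParams()
    params = base.evolve(kappa_t0=kappa_t0, mu_X=mu_X)

    kn = [calibrate_kappa_n0(k, params) for k in (kappa_low, kappa_high)]

    rows, rhs = [], []
    for kappa_j, V0_j in ((kappa_low, V0_low), (kappa_high, V0_high)):
        a_j = a_of_kappa(kappa_j, params)
        s_j = params.phi_R_max - core.allocation_fR(a_j, params)
        D_j = 2.0 - 2.0 ** (-mu_X / kappa_j)
        kP_j = (kappa_j + mu_X) / (V0_j * D_j)
        rows.append([s_j, 1.0])
        rhs.append(kP_j / (kappa_j + params.mu_ns))
    A = np.asarray(rows)
    b = np.asarray(rhs)
    if abs(np.linalg.det(A)) > 1e-12 * np.abs(A).max() ** 2:
        ga, gb = np.linalg.solve(A, b)
    else:
        # identical conditions: minimum-norm solution of the single equation
        ga, gb = np.linalg.lstsq(A, b, rcond=None)[0]
    return kn[0], kn[1], float(ga), float(gb)
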