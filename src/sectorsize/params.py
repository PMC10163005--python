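"""Model parameters and literature presets.

Units are fixed package-wide: time in hours, volume in um^3, rates in 1/h;
all proteome mass/allocation fractions are dimensionless.

The division-protein machinery enters through the composite constants
``gamma_alpha = gamma * alpha`` and ``gamma_beta = gamma * beta`` (um^-3),
where ``gamma = rho_c / (X0 * m_X)`` converts division-sector mass per
volume into threshold units.  Only the composites are observable from cell
size data, so they are the primary parameters; ``alpha`` and ``beta`` may
optionally be supplied to separate the division sector's mass fraction in
the proteome balance (see :mod:`sectorsize.core`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, fields

from .errors import ParameterError

__all__ = ["ModelParams", "PRESETS", "preset"]


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and allocation constants of the four-sector model.

    Attributes
    ----------
    phi_R_min : float
        Inactive (non-translating) ribosome mass fraction.
    phi_R_max : float
        Maximum flux allocation to ribosome production (phi^max - beta).
    a_t : float
        Amino-acid mass fraction below which translation attenuates.
    a_n : float
        Amino-acid mass fraction above which nutrient influx is
        feedback-inhibited.
    kappa_t0 : float
        Translational efficiency rate constant, 1/h.
    mu_ns : float
        Nonspecific protein degradation rate, 1/h.
    mu_X : float
        Division-protein degradation rate, 1/h.
    gamma_alpha : float
        Composite gamma*alpha, um^-3: co-regulated contribution to k_P.
    gamma_beta : float
        Composite gamma*beta, um^-3: basal contribution to k_P.
    alpha, beta : float or None
        Optional separation of the division allocation fraction
        f_X = alpha*(phi_R_max - f_R) + beta.  When absent the model runs
        in composite mode and the division sector's mass is neglected in
        the amino-acid balance.
    """

    phi_R_min: float = 0.049
    phi_R_max: float = 0.55
    a_t: float = 1e-4
    a_n: float = 1e-3
    kappa_t0: float = 2.6
    mu_ns: float = 0.0
    mu_X: float = 2.5
    gamma_alpha: float = 4.5
    gamma_beta: float = 1.1
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.phi_R_min < self.phi_R_max < 1.0):
            raise ParameterError(
                f"need 0 < phi_R_min < phi_R_max < 1, got "
                f"({self.phi_R_min}, {self.phi_R_max})"
            )
        if not (0.0 < self.a_t < self.a_n):
            raise ParameterError(f"need 0 < a_t < a_n, got ({self.a_t}, {self.a_n})")
        for name in ("kappa_t0", "mu_ns", "mu_X"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.gamma_alpha <= 0 or self.gamma_beta <= 0:
            raise ParameterError("gamma_alpha and gamma_beta must be > 0")
        if (self.alpha is None) != (self.beta is None):
            raise ParameterError("alpha and beta must be supplied together")
        if self.alpha is not None:
            if not (0 < self.alpha <= 1) or not (0 < self.beta < 1):
                raise ParameterError("need 0 < alpha <= 1 and 0 < beta < 1")
            # composites must describe one and the same gamma
            g1 = self.gamma_alpha / self.alpha
            g2 = self.gamma_beta / self.beta
            if not math.isclose(g1, g2, rel_tol=1e-6):
                raise ParameterError(
                    f"inconsistent separation: gamma_alpha/alpha = {g1:g} "
                    f"but gamma_beta/beta = {g2:g}"
                )

    # ---- derived constants -------------------------------------------------

    @property
    def delta_phi(self) -> float:
        """phi_R_max - phi_R_min: dynamic range of the ribosomal sector."""
        return self.phi_R_max - self.phi_R_min

    @property
    def separated(self) -> bool:
        """True when alpha/beta are supplied (full mass balance mode)."""
        return self.alpha is not None

    @property
    def gamma(self) -> float:
        """gamma = gamma_alpha / alpha (separated mode only)."""
        if not self.separated:
            raise ParameterError("gamma is only defined when alpha, beta are given")
        return self.gamma_alpha / self.alpha

    @property
    def phi_max(self) -> float:
        """Total dynamic proteome budget phi^max = phi_R_max + beta.

        In composite mode beta's mass is absorbed into the metabolic
        sector, so phi_max == phi_R_max.
        """
        return self.phi_R_max + (self.beta if self.separated else 0.0)

    @property
    def kappa_max(self) -> float:
        """Physical upper limit of the growth rate, kappa_t0 * delta_phi."""
        return self.kappa_t0 * self.delta_phi

    @property
    def V0_max(self) -> float:
        """Maximum birth volume 1 / gamma_beta, um^3."""
        return 1.0 / self.gamma_beta

    def evolve(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Literature parameter sets for E. coli.  ``kn_low``/``kn_high`` are the
#: nutrient-quality constants (1/h) that accompany each set.
PRESETS: dict[str, dict] = {
    # poor/rich exponential growth, moderate shift
    "baseline": dict(
        params=ModelParams(kappa_t0=2.6, mu_ns=0.0, mu_X=2.5,
                           gamma_alpha=4.5, gamma_beta=1.1),
        kn_low=4.8, kn_high=10.0,
    ),
    # steady-state size-law strain (slow division-protein turnover)
    "sizelaw": dict(
        params=ModelParams(kappa_t0=4.8, mu_ns=0.0, mu_X=0.1,
                           gamma_alpha=3.6, gamma_beta=0.34),
        kn_low=4.8, kn_high=10.0,
    ),
    # strong upshift experiments (minimal -> rich medium)
    "upshift": dict(
        params=ModelParams(kappa_t0=2.6, mu_ns=0.0, mu_X=2.5,
                           gamma_alpha=4.5, gamma_beta=1.1),
        kn_low=4.8, kn_high=160.0,
    ),
    # stationary phase and exit (protein turnover matters)
    "stationary": dict(
        params=ModelParams(kappa_t0=2.6, mu_ns=0.1, mu_X=2.5,
                           gamma_alpha=4.5, gamma_beta=1.1),
        kn_low=0.0, kn_high=160.0,
    ),
}


def preset(name: str) -> tuple[ModelParams, float, float]:
    """Return ``(params, kn_low, kn_high)`` for a named preset."""
    try:
        entry = PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return entry["params"], entry["kn_low"], entry["kn_high"]
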