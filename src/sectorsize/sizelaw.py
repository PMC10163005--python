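"""Size-law fitting: birth volume versus growth rate.

The steady-state size law links nutrient-limited growth rate to birth
volume,

    V0(kappa) = 1 / (gamma_alpha (delta_phi - kappa/kappa_t0) + gamma_beta),

optionally corrected for division-protein degradation (mu_X > 0) through
the threshold-accumulation cycle closure (see
:func:`sectorsize.steady.birth_size_full`).

A structural note on identifiability: inverting the size law gives
1/V0 = (gamma_alpha*delta_phi + gamma_beta) - (gamma_alpha/kappa_t0)*kappa,
which is *linear* in kappa — only the intercept and slope are
identifiable, so (gamma_alpha, gamma_beta, kappa_t0) cannot all be
recovered from (kappa, V0) data alone; the same ridge persists in the
degradation-corrected form.  kappa_t0 is therefore treated as a fixed,
independently measured input by default, and the fit estimates
(gamma_alpha, gamma_beta[, mu_X]).  ``fit_kappa_t=True`` opts into the
full fit and flags the ridge in the results.

The fitting surface follows the statsmodels convention: build a
:class:`SizeLawModel` from data, call :meth:`~SizeLawModel.fit`, inspect
the returned :class:`SizeLawResults` (estimates, standard errors,
residuals, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, FitConvergenceError, NonIdentifiableError
from .params import ModelParams
from . import steady

__all__ = ["SizeLawData", "SizeLawModel", "SizeLawResults", "fit_size_law",
           "generate_sizelaw_fixture"]

CSV_COLUMNS = ("kappa_per_h", "V0_um3")


@dataclass(frozen=True)
class SizeLawData:
    """A table of steady-state (growth rate, birth volume) observations."""

    kappa: np.ndarray
    V0: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        k = np.asarray(self.kappa, float)
        v = np.asarray(self.V0, float)
        if k.shape != v.shape or k.ndim != 1:
            raise DomainError("kappa and V0 must be equal-length 1-D arrays")
        if np.any(k <= 0) or np.any(v <= 0):
            raise DomainError("kappa and V0 must be positive")
        w = self.weights
        if w is not None:
            w = np.asarray(w, float)
            if w.shape != k.shape or np.any(w < 0):
                raise DomainError("weights must be non-negative, same length")
        object.__setattr__(self, "kappa", k)
        object.__setattr__(self, "V0", v)
        object.__setattr__(self, "weights", w)

    def __len__(self):
        return self.kappa.size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SizeLawData":
        w = df["weight"].to_numpy() if "weight" in df.columns else None
        return cls(df["kappa_per_h"].to_numpy(), df["V0_um3"].to_numpy(), w)

    @classmethod
    def from_csv(cls, path) -> "SizeLawData":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"kappa_per_h": self.kappa, "V0_um3": self.V0})
        if self.weights is not None:
            out["weight"] = self.weights
        return out

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class SizeLawModel:
    """Nonlinear least-squares model for the size law.

    Parameters
    ----------
    data : SizeLawData
    include_degradation : bool
        Fit the degradation-corrected birth size (adds mu_X).
    kappa_t0 : float
        Fixed translational efficiency constant (1/h).
    mu_ns : float
        Fixed nonspecific degradation rate (default 0; exponential data).
    log_space : bool
        Minimize residuals of log V0 instead of V0.
    fit_kappa_t : bool
        Opt into the structurally non-identifiable 3-parameter fit.
    """

    def __init__(self, data: SizeLawData, include_degradation: bool = False,
                 kappa_t0: float = 2.6, mu_ns: float = 0.0,
                 delta_phi: float = ModelParams().delta_phi,
                 log_space: bool = False, fit_kappa_t: bool = False):
        self.data = data
        self.include_degradation = include_degradation
        self.kappa_t0 = float(kappa_t0)
        self.mu_ns = float(mu_ns)
        self.delta_phi = float(delta_phi)
        self.log_space = log_space
        self.fit_kappa_t = fit_kappa_t
        self.param_names = ["gamma_alpha", "gamma_beta"]
        if fit_kappa_t:
            self.param_names.append("kappa_t0")
        if include_degradation:
            self.param_names.append("mu_X")
        n_distinct = np.unique(self.data.kappa).size
        if n_distinct < len(self.param_names):
            raise NonIdentifiableError(
                f"{len(self.param_names)}-parameter fit needs >= "
                f"{len(self.param_names)} distinct growth rates, got "
                f"{n_distinct}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SizeLawModel":
        return cls(SizeLawData.from_dataframe(df), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SizeLawModel":
        return cls(SizeLawData.from_csv(path), **kwargs)

    # ---- model curve -------------------------------------------------------

    def _unpack(self, theta):
        ga, gb = theta[0], theta[1]
        i = 2
        kt = theta[i] if self.fit_kappa_t else self.kappa_t0
        if self.fit_kappa_t:
            i += 1
        mx = theta[i] if self.include_degradation else 0.0
        return ga, gb, kt, mx

    def predict(self, theta, kappa=None):
        """Model birth volume at the given growth rates."""
        k = self.data.kappa if kappa is None else np.asarray(kappa, float)
        ga, gb, kt, mx = self._unpack(theta)
        y = k + self.mu_ns
        kP = (ga * (self.delta_phi - y / kt) + gb) * y
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.include_degradation:
                V0 = (k + mx) / (kP * (2.0 - 2.0 ** (-mx / k)))
            else:
                V0 = k / kP
        return V0

    def _residuals(self, theta):
        pred = self.predict(theta)
        bad = ~np.isfinite(pred) | (pred <= 0)
        if self.log_space:
            res = np.where(bad, 1e6, np.log(np.where(bad, 1.0, pred))
                           - np.log(self.data.V0))
        else:
            res = np.where(bad, 1e6, pred - self.data.V0)
        if self.data.weights is not None:
            res = res * np.sqrt(self.data.weights)
        return res

    def _start(self):
        # linearized start: 1/V0 ~ c0 - c1 * kappa
        k, v = self.data.kappa, self.data.V0
        coef = np.polyfit(k, 1.0 / v, 1)
        c1, c0 = -coef[0], coef[1]
        ga0 = max(c1 * self.kappa_t0, 1e-3)
        gb0 = max(c0 - ga0 * self.delta_phi, 1e-3)
        theta = [ga0, gb0]
        if self.fit_kappa_t:
            theta.append(self.kappa_t0)
        if self.include_degradation:
            theta.append(0.5)
        return np.array(theta)

    def fit(self, start=None, max_nfev: int = 2000) -> "SizeLawResults":
        theta0 = np.asarray(start, float) if start is not None else self._start()
        lower = np.zeros(len(self.param_names)) + 1e-12
        res = least_squares(self._residuals, theta0, bounds=(lower, np.inf),
                            max_nfev=max_nfev, xtol=1e-14, ftol=1e-14,
                            gtol=1e-14)
        if not res.success:
            raise FitConvergenceError(
                f"size-law fit did not converge: {res.message}",
                last_params=dict(zip(self.param_names, res.x)))
        rss = float(res.cost * 2.0)
        dof = max(len(self.data) - len(self.param_names), 1)
        J = res.jac
        JTJ = J.T @ J
        # covariance from the Gauss-Newton approximation; singular on the
        # kappa_t ridge, flagged rather than hidden
        ridge = False
        try:
            cov = np.linalg.inv(JTJ) * rss / dof
            cond = np.linalg.cond(JTJ)
            ridge = cond > 1e10
        except np.linalg.LinAlgError:
            cov = np.full((len(res.x), len(res.x)), np.nan)
            ridge = True
        return SizeLawResults(model=self, params=res.x, cov=cov, rss=rss,
                              converged=True, n_obs=len(self.data),
                              ridge_flag=ridge and self.fit_kappa_t)


@dataclass
class SizeLawResults:
    """Fit results: estimates, uncertainties, diagnostics."""

    model: SizeLawModel
    params: np.ndarray
    cov: np.ndarray
    rss: float
    converged: bool
    n_obs: int
    ridge_flag: bool = False

    @property
    def param_dict(self) -> dict:
        return dict(zip(self.model.param_names, self.params))

    @property
    def bse(self) -> np.ndarray:
        """Approximate standard errors of the estimates."""
        return np.sqrt(np.diag(self.cov))

    def predict(self, kappa):
        return self.model.predict(self.params, kappa)

    @property
    def residuals(self) -> np.ndarray:
        return self.model.predict(self.params) - self.model.data.V0

    def summary(self) -> str:
        lines = ["Size-law fit", "=" * 44,
                 f"observations: {self.n_obs}",
                 f"degradation term: {self.model.include_degradation}",
                 f"residual sum of squares: {self.rss:.6g}",
                 f"converged: {self.converged}"]
        if not self.model.fit_kappa_t:
            lines.append(f"kappa_t0 (fixed): {self.model.kappa_t0:g} 1/h")
        if self.ridge_flag:
            lines.append("WARNING: kappa_t0 fitted jointly; estimates lie on "
                         "a structural ridge (see module docstring)")
        lines.append("-" * 44)
        lines.append(f"{'parameter':<14}{'estimate':>12}{'std err':>12}")
        for name, est, se in zip(self.model.param_names, self.params, self.bse):
            lines.append(f"{name:<14}{est:>12.5g}{se:>12.3g}")
        return "\n".join(lines)


def fit_size_law(data: SizeLawData, include_degradation: bool = False,
                 **kwargs) -> SizeLawResults:
    """Convenience wrapper: build a :class:`SizeLawModel` and fit it."""
    return SizeLawModel(data, include_degradation=include_degradation,
                        **kwargs).fit()


def generate_sizelaw_fixture(params: ModelParams, n: int = 50,
                             noise_cv: float = 0.0,
                             seed: int | None = None,
                             kappa_range: tuple[float, float] | None = None,
                             include_degradation: bool = True) -> SizeLawData:
    """Synthetic (kappa, V0) dataset drawn from the model itself.

    Growth rates are sampled uniformly over the physical range (by
    default 10-90% of kappa_max) and birth volumes computed from the
    degradation-corrected cycle closure (or the bare size law), then
    multiplied by lognormal noise with the stated coefficient of
    variation.
    """
    if n < 3:
        raise DomainError("need n >= 3")
    rng = np.random.default_rng(seed)
    if kappa_range is None:
        kappa_range = (0.1 * params.kappa_max, 0.9 * params.kappa_max)
    kappa = rng.uniform(*kappa_range, size=n)
    if include_degradation:
        kP = steady.kP_steady(kappa, params)
        V0 = (kappa + params.mu_X) / (kP * (2.0 - 2.0 ** (-params.mu_X / kappa)))
    else:
        V0 = steady.size_law_V0(kappa, params)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        V0 = V0 * rng.lognormal(-sigma**2 / 2, sigma, size=n)
    return SizeLawData(kappa, V0)
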