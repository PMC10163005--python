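"""Scalar measurement procedures on simulated series.

These are deterministic functions of their inputs (no hidden randomness):
recovery time after a nutrient downshift, overshoot/undershoot amplitude,
and the birth-size/added-volume correlation that distinguishes adder from
sizer behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CensoredObservation, DomainError, UndefinedObservable

__all__ = ["RecoverySpec", "recovery_time", "overshoot_amplitude",
           "sizer_correlation", "pre_shift_level"]


@dataclass(frozen=True)
class RecoverySpec:
    """Definition of a recovery measurement.

    ``tolerance_fraction`` is the half-width of the acceptance band
    around the pre-shift level (0.01 = "within 99% of the pre-shift
    level").  The band is applied to the level itself,
    |x - x0| <= tol * |x0|.
    """

    t_downshift: float
    pre_shift_level: float
    tolerance_fraction: float = 0.01

    def __post_init__(self):
        if not (0 < self.tolerance_fraction < 1):
            raise DomainError("tolerance_fraction must lie in (0, 1)")


def pre_shift_level(times, values, t_shift: float, window: float = 1.0) -> float:
    """Time-average of a series over the final ``window`` hours before a shift."""
    t = np.asarray(times, float)
    x = np.asarray(values, float)
    mask = (t >= t_shift - window) & (t < t_shift)
    if not mask.any():
        raise DomainError("no samples in the pre-shift window")
    return float(np.mean(x[mask]))


def recovery_time(times, values, spec: RecoverySpec) -> float:
    """Time for a series to return *and stay* within the recovery band.

    Returns the first t > t_downshift from which the series remains
    within +/- tolerance_fraction * |pre_shift_level| of the pre-shift
    level at every subsequent sample, minus t_downshift.  Sustained
    re-entry (rather than first touch) makes the measure well defined for
    non-monotonic recoveries.  Raises :class:`CensoredObservation` when
    the series is still outside the band at its last sample.
    """
    t = np.asarray(times, float)
    x = np.asarray(values, float)
    if t.size != x.size or t.size == 0:
        raise DomainError("times and values must be equal-length, non-empty")
    post = t > spec.t_downshift
    if not post.any():
        raise DomainError("series has no samples after t_downshift")
    t_post, x_post = t[post], x[post]
    band = spec.tolerance_fraction * abs(spec.pre_shift_level)
    inside = np.abs(x_post - spec.pre_shift_level) <= band
    if not inside[-1]:
        raise CensoredObservation(
            "series never settles inside the recovery band",
            horizon=float(t_post[-1]))
    if inside.all():
        return 0.0
    last_out = np.max(np.nonzero(~inside)[0])
    return float(t_post[last_out + 1] - spec.t_downshift)


def overshoot_amplitude(times, values, t_event: float, baseline: float,
                        mode: str = "overshoot",
                        window: float | None = None) -> float:
    """Peak excursion of a series from a baseline after an event.

    ``mode='overshoot'`` returns max(series - baseline) over the
    post-event window (positive = overshoot); ``mode='undershoot'``
    returns min(series - baseline) (negative = undershoot).  ``window``
    optionally limits the search to [t_event, t_event + window].
    """
    t = np.asarray(times, float)
    x = np.asarray(values, float)
    mask = t >= t_event
    if window is not None:
        mask &= t <= t_event + window
    if not mask.any():
        raise DomainError("no samples in the post-event window")
    excursion = x[mask] - baseline
    if mode == "overshoot":
        return float(np.nanmax(excursion))
    if mode == "undershoot":
        return float(np.nanmin(excursion))
    raise DomainError(f"unknown mode {mode!r}")


def sizer_correlation(records) -> float:
    """Pearson correlation between initial volume and added volume.

    ``records`` is an iterable of (V_init, Delta) pairs or a DataFrame
    with columns V_init/Delta (V0/Delta also accepted).  A value near -1
    indicates sizer behaviour (division at a set size); near 0, adder
    behaviour.  Raises :class:`UndefinedObservable` on zero variance.
    """
    try:
        v = np.asarray(records["V_init"], float)
        d = np.asarray(records["Delta"], float)
    except (TypeError, IndexError, KeyError):
        try:
            arr = np.asarray(list(records), float)
            v, d = arr[:, 0], arr[:, 1]
        except (TypeError, ValueError, IndexError):
            raise DomainError("records must be (V_init, Delta) pairs") from None
    keep = np.isfinite(v) & np.isfinite(d)
    v, d = v[keep], d[keep]
    if v.size < 3:
        raise DomainError("need at least 3 records")
    if np.std(v) == 0 or np.std(d) == 0:
        raise UndefinedObservable(
            "correlation undefined: zero variance in V_init or Delta")
    return float(stats.pearsonr(v, d).statistic)
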