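"""Piecewise-constant nutrient environments.

The extracellular world enters the model only through the nutrient-quality
constant kappa_n0 (1/h), a function of nutrient concentration which the
model never resolves explicitly.  An :class:`Environment` is an ordered
list of ``(t_start, kappa_n0)`` segments starting at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ScheduleError

__all__ = ["Environment", "make_environment"]


@dataclass(frozen=True)
class Environment:
    """Piecewise-constant nutrient quality kappa_n0(t)."""

    segments: tuple  # of (t_start, kappa_n0)

    def __post_init__(self):
        segs = tuple((float(t), float(k)) for t, k in self.segments)
        if not segs:
            raise ScheduleError("environment needs at least one segment")
        if segs[0][0] != 0.0:
            raise ScheduleError("first segment must start at t = 0")
        starts = [t for t, _ in segs]
        if any(t1 <= t0 for t0, t1 in zip(starts, starts[1:])):
            raise ScheduleError("segment start times must be strictly increasing")
        if any(k < 0 for _, k in segs):
            raise ScheduleError("kappa_n0 must be >= 0")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def constant(cls, kappa_n0: float) -> "Environment":
        return cls(((0.0, kappa_n0),))

    def kappa_n0_at(self, t: float) -> float:
        """Nutrient quality at time t (segments are left-closed)."""
        if t < 0:
            raise DomainError(f"t must be >= 0, got {t}")
        value = self.segments[0][1]
        for t_start, k in self.segments:
            if t >= t_start:
                value = k
            else:
                break
        return value

    def boundaries(self, t0: float, t1: float) -> list[float]:
        """Segment start times strictly inside (t0, t1)."""
        return [t for t, _ in self.segments if t0 < t < t1]

    def pieces(self, t0: float, t1: float) -> list[tuple[float, float, float]]:
        """Decompose [t0, t1] into (start, end, kappa_n0) sub-intervals."""
        cuts = [t0] + self.boundaries(t0, t1) + [t1]
        return [(lo, hi, self.kappa_n0_at(lo)) for lo, hi in zip(cuts, cuts[1:])]


def make_environment(kind: str, kappa_n0_low: float, kappa_n0_high: float,
                     t_shift: float = 0.0, tau_feast: float | None = None,
                     tau_pulse: float | None = None,
                     pulse_duration: float | None = None,
                     n_pulses: int = 1) -> Environment:
    """Build a standard scenario environment.

    Parameters
    ----------
    kind : {"step", "pulse", "pulse_train"}
        ``step``: one permanent switch low -> high at ``t_shift``.
        ``pulse``: high on [t_shift, t_shift + tau_feast), low otherwise.
        ``pulse_train``: ``n_pulses`` pulses of ``pulse_duration`` whose
        starts are separated by ``pulse_duration + tau_pulse``; the
        feedrate is 1 / (tau_pulse + pulse_duration).
    """
    if kind == "step":
        if t_shift < 0:
            raise ScheduleError("t_shift must be >= 0")
        if t_shift == 0:
            return Environment.constant(kappa_n0_high)
        return Environment(((0.0, kappa_n0_low), (t_shift, kappa_n0_high)))

    if kind == "pulse":
        if tau_feast is None or tau_feast < 0:
            raise ScheduleError("pulse needs tau_feast >= 0")
        if tau_feast == 0:
            return Environment.constant(kappa_n0_low)
        return Environment(
            ((0.0, kappa_n0_low), (t_shift, kappa_n0_high),
             (t_shift + tau_feast, kappa_n0_low))
            if t_shift > 0 else
            ((0.0, kappa_n0_high), (tau_feast, kappa_n0_low))
        )

    if kind == "pulse_train":
        if pulse_duration is None or pulse_duration <= 0:
            raise ScheduleError("pulse_train needs pulse_duration > 0")
        if tau_pulse is None or tau_pulse <= 0:
            raise ScheduleError(
                "pulse_train needs tau_pulse > 0 (pulses must not overlap)"
            )
        if n_pulses < 1:
            raise ScheduleError("n_pulses must be >= 1")
        period = pulse_duration + tau_pulse
        segs: list[tuple[float, float]] = []
        if t_shift > 0:
            segs.append((0.0, kappa_n0_low))
        for i in range(int(n_pulses)):
            start = t_shift + i * period
            segs.append((start, kappa_n0_high))
            segs.append((start + pulse_duration, kappa_n0_low))
        if t_shift == 0:
            # pulse starts immediately; drop any duplicate t=0 handling
            pass
        return Environment(tuple(segs))

    raise ScheduleError(f"unknown environment kind {kind!r}")


def feedrate(tau_pulse: float, pulse_duration: float) -> float:
    """Pulses per hour for a pulse train, 1 / (tau_pulse + pulse_duration)."""
    return 1.0 / (tau_pulse + pulse_duration)
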