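"""Periodic trapezoidal pulse signals (ISSF) and their composition.

The core object is :class:`ISSFParams`, a six-parameter description of a
periodic pulse waveform

.. math::

    \\Theta(t) = \\Theta_0 + \\Theta_1 \\cdot s(u), \\qquad
    u = (t + \\varphi) - T_C \\lfloor (t + \\varphi)/T_C \\rfloor

where ``s`` rises linearly from 0 to 1 over ``ramp_duration`` hours, holds
at 1 until ``pulse_duration`` hours into the cycle, falls back to 0 over
another ramp, and stays at 0 for the remainder of the cycle.
``pulse_duration`` is measured between half-maximum crossings, so the
integral of the waveform over one cycle is exactly
``offset * cycle_period + amplitude * pulse_duration`` independent of the
ramp duration.

Signals can be sequenced in time (:class:`SignalSchedule`, e.g. entrainment
cycles followed by constant conditions) and combined across channels
(:class:`CompositeSignal`, e.g. a background light regime plus a single
test pulse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence, Union

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "ISSFParams",
    "ScheduleSegment",
    "SignalSchedule",
    "CompositeSignal",
    "Combiner",
    "SignalLike",
    "validate_params",
    "eval_issf",
    "eval_schedule",
    "eval_composite",
    "eval_signal",
    "period_integral",
    "sample",
    "as_schedule",
]


class InvalidSignalError(ValueError):
    """Raised when signal parameters violate their invariants."""


@dataclass(frozen=True)
class ISSFParams:
    """The six configuration parameters of the step-function waveform.

    Attributes
    ----------
    offset:
        Baseline signal level, returned whenever the pulse is off.
    amplitude:
        Level added to the baseline during the pulse plateau.
    pulse_duration:
        "On" time per cycle in hours, measured between the half-maximum
        points of the up and down ramps.
    cycle_period:
        Forcing period in hours. Must be positive.
    ramp_duration:
        Linear off-to-on transition time in hours. Zero produces a
        right-continuous square wave.
    phase:
        Time translation in hours. ``phase = -t0`` places the start of the
        up-ramp at absolute time ``t0``.
    """

    offset: float
    amplitude: float
    pulse_duration: float
    cycle_period: float
    ramp_duration: float = 0.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        validate_params(self)

    def replace(self, **changes) -> "ISSFParams":
        """Return a copy with the given fields changed (re-validated)."""
        return replace(self, **changes)


def validate_params(candidate: ISSFParams) -> ISSFParams:
    """Check all parameter invariants, returning the params unchanged.

    Raises
    ------
    InvalidSignalError
        Naming the violated invariant and the offending values.
    """
    p = candidate
    for name in ("offset", "amplitude", "pulse_duration", "cycle_period",
                 "ramp_duration", "phase"):
        v = getattr(p, name)
        if not isinstance(v, (int, float)) or not math.isfinite(v):
            raise InvalidSignalError(f"{name} must be a finite number, got {v!r}")
    if p.cycle_period <= 0:
        raise InvalidSignalError(
            f"cycle_period must be > 0, got {p.cycle_period}")
    if p.ramp_duration < 0:
        raise InvalidSignalError(
            f"ramp_duration must be >= 0, got {p.ramp_duration}")
    if p.pulse_duration < p.ramp_duration:
        raise InvalidSignalError(
            "pulse_duration must be >= ramp_duration (non-negative plateau), "
            f"got pulse_duration={p.pulse_duration}, "
            f"ramp_duration={p.ramp_duration}")
    if p.pulse_duration + p.ramp_duration > p.cycle_period:
        raise InvalidSignalError(
            "pulse_duration + ramp_duration must be <= cycle_period "
            "(waveform must return to baseline each cycle), got "
            f"{p.pulse_duration} + {p.ramp_duration} > {p.cycle_period}")
    return candidate


def eval_issf(params: ISSFParams, t):
    """Evaluate the waveform at time(s) ``t`` (hours).

    Accepts a scalar or array-like ``t``; returns a float or ndarray.
    With ``ramp_duration == 0`` the waveform is a right-continuous square
    wave: transition instants evaluate to the post-transition value.
    """
    p = params
    t = np.asarray(t, dtype=float)
    if p.amplitude == 0.0:
        # Degenerate constant signal regardless of the timing parameters.
        out = np.full(t.shape, p.offset)
        return float(out) if out.ndim == 0 else out
    x = t + p.phase
    u = x - p.cycle_period * np.floor(x / p.cycle_period)
    tP, tR = p.pulse_duration, p.ramp_duration
    if tR > 0.0:
        s = np.where(
            u < tR, u / tR,
            np.where(u < tP, 1.0,
                     np.where(u < tP + tR, 1.0 - (u - tP) / tR, 0.0)))
    else:
        s = np.where(u < tP, 1.0, 0.0)
    out = p.offset + p.amplitude * s
    return float(out) if out.ndim == 0 else out


def period_integral(params: ISSFParams) -> float:
    """Exact integral of the waveform over one cycle.

    The two ramps each contribute ``amplitude * ramp_duration / 2``, which
    exactly cancels the plateau shortfall, so the result is independent of
    the ramp duration::

        offset * cycle_period + amplitude * pulse_duration
    """
    validate_params(params)
    return params.offset * params.cycle_period + \
        params.amplitude * params.pulse_duration


@dataclass(frozen=True)
class ScheduleSegment:
    start_time: float
    params: ISSFParams


@dataclass(frozen=True)
class SignalSchedule:
    """A signal that switches waveform parameters at fixed times.

    Each segment owns its full parameter set and becomes active at its
    ``start_time``; segment boundaries are half-open ``[start, next_start)``
    so the later segment wins at the boundary instant.  Time is absolute —
    a segment does not reset the time origin, so phase relationships carry
    across segment boundaries.
    """

    segments: tuple[ScheduleSegment, ...]

    def __init__(self, segments: Sequence) -> None:
        segs = []
        for item in segments:
            if isinstance(item, ScheduleSegment):
                segs.append(item)
            else:
                start, params = item
                segs.append(ScheduleSegment(float(start), params))
        if not segs:
            raise InvalidSignalError("schedule must have at least one segment")
        starts = [s.start_time for s in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise InvalidSignalError(
                f"segment start_times must be strictly increasing: {starts}")
        for s in segs:
            validate_params(s.params)
        object.__setattr__(self, "segments", tuple(segs))

    @property
    def start_time(self) -> float:
        return self.segments[0].start_time

    def active_params(self, t: float) -> ISSFParams:
        """Parameters of the segment active at absolute time ``t``."""
        if t < self.segments[0].start_time:
            raise InvalidSignalError(
                f"t={t} precedes first segment start "
                f"{self.segments[0].start_time}")
        active = self.segments[0]
        for seg in self.segments[1:]:
            if t >= seg.start_time:
                active = seg
            else:
                break
        return active.params


def eval_schedule(schedule: SignalSchedule, t):
    """Evaluate a schedule at scalar or array time(s) ``t``."""
    t_arr = np.asarray(t, dtype=float)
    if t_arr.ndim == 0:
        return eval_issf(schedule.active_params(float(t_arr)), float(t_arr))
    out = np.empty(t_arr.shape)
    starts = np.array([s.start_time for s in schedule.segments])
    idx = np.searchsorted(starts, t_arr, side="right") - 1
    if np.any(idx < 0):
        bad = float(t_arr[idx < 0][0])
        raise InvalidSignalError(
            f"t={bad} precedes first segment start {starts[0]}")
    for k, seg in enumerate(schedule.segments):
        mask = idx == k
        if np.any(mask):
            out[mask] = eval_issf(seg.params, t_arr[mask])
    return out


class Combiner(str, Enum):
    SUM = "sum"
    PRODUCT = "product"
    MAX = "max"


SignalLike = Union[ISSFParams, SignalSchedule, "CompositeSignal"]


def as_schedule(signal: Union[ISSFParams, SignalSchedule]) -> SignalSchedule:
    """Coerce a bare parameter set into a one-segment schedule."""
    if isinstance(signal, SignalSchedule):
        return signal
    if isinstance(signal, ISSFParams):
        return SignalSchedule([(-math.inf, signal)])
    raise TypeError(f"cannot interpret {type(signal).__name__} as a schedule")


@dataclass(frozen=True)
class CompositeSignal:
    """Several signals folded into one value with a combining operator."""

    signals: tuple[SignalSchedule, ...]
    combiner: Combiner = Combiner.SUM

    def __init__(self, signals: Sequence, combiner=Combiner.SUM) -> None:
        if not signals:
            raise InvalidSignalError("composite needs at least one signal")
        object.__setattr__(
            self, "signals", tuple(as_schedule(s) for s in signals))
        object.__setattr__(self, "combiner", Combiner(combiner))


def eval_composite(composite: CompositeSignal, t):
    """Evaluate a composite signal at scalar or array time(s) ``t``."""
    values = [eval_schedule(s, t) for s in composite.signals]
    if composite.combiner is Combiner.SUM:
        out = values[0]
        for v in values[1:]:
            out = out + v
    elif composite.combiner is Combiner.PRODUCT:
        out = values[0]
        for v in values[1:]:
            out = out * v
    else:
        out = values[0]
        for v in values[1:]:
            out = np.maximum(out, v)
        if np.ndim(out) == 0:
            out = float(out)
    return out


def eval_signal(signal: SignalLike, t):
    """Evaluate any signal kind (params, schedule, or composite) at ``t``."""
    if isinstance(signal, ISSFParams):
        return eval_issf(signal, t)
    if isinstance(signal, SignalSchedule):
        return eval_schedule(signal, t)
    if isinstance(signal, CompositeSignal):
        return eval_composite(signal, t)
    raise TypeError(f"not a signal: {type(signal).__name__}")


def sample(signal: SignalLike, grid) -> TimeSeries:
    """Evaluate a signal on a strictly increasing time grid.

    Returns a single-column :class:`~issf.timeseries.TimeSeries` named
    ``signal``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidSignalError("sampling grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise InvalidSignalError("sampling grid must be strictly increasing")
    values = np.asarray(eval_signal(signal, grid), dtype=float)
    return TimeSeries(times=grid, columns={"signal": values})
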