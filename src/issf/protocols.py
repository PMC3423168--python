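"""Simulation protocols: entrainment, photoperiod sweeps, and PRCs.

All protocols take an SBML model (a :class:`~issf.sbml_io.ModelHandle`),
inject signals onto a light parameter, simulate deterministically, and
reduce trajectories to phase statistics.  Everything is reproducible:
there is no randomness anywhere, and integrator settings are explicit.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import libsbml
import numpy as np

from .sbml_io import ModelHandle, SignalAssignment, inject_issf
from .simulator import IntegratorSettings, SimulationError, simulate_model
from .timeseries import TimeSeries
from .waveform import (
    CompositeSignal,
    ISSFParams,
    SignalSchedule,
    as_schedule,
)

__all__ = [
    "PRCResult", "PRCRow", "ShiftClass",
    "simulate", "detect_peaks", "estimate_period",
    "run_photoperiod_experiment", "run_prc",
    "max_step_for_signals", "DEFAULT_SHIFT_THRESHOLD",
]

DEFAULT_SHIFT_THRESHOLD = 0.25  # hours; above interpolation noise
DEFAULT_TRANSIENT_CYCLES = 5


class ShiftClass(str, Enum):
    ADVANCE = "advance"
    DELAY = "delay"
    NONE = "none"


@dataclass(frozen=True)
class PRCRow:
    pulse_phase: float        # the swept phase parameter value
    pulse_start_time: float   # absolute start of the up-ramp (= -phase)
    phase_shift: float        # hours; advance positive, delay negative
    classification: ShiftClass


@dataclass(frozen=True)
class PRCResult:
    rows: tuple[PRCRow, ...]

    def advances(self) -> list[PRCRow]:
        return [r for r in self.rows
                if r.classification is ShiftClass.ADVANCE]

    def delays(self) -> list[PRCRow]:
        return [r for r in self.rows if r.classification is ShiftClass.DELAY]

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame([{
            "pulse_phase": r.pulse_phase,
            "pulse_start_time": r.pulse_start_time,
            "phase_shift": r.phase_shift,
            "classification": r.classification.value,
        } for r in self.rows])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _signal_ramps(signal) -> list[float]:
    if isinstance(signal, ISSFParams):
        return [signal.ramp_duration] if signal.amplitude != 0 else []
    if isinstance(signal, SignalSchedule):
        return [r for seg in signal.segments
                for r in _signal_ramps(seg.params)]
    if isinstance(signal, CompositeSignal):
        return [r for s in signal.signals for r in _signal_ramps(s)]
    return []


def max_step_for_signals(*signals, fallback: float = 0.1) -> float:
    """Half the shortest active ramp, so the solver never steps over a
    transition; square-wave (zero-ramp) signals fall back to a small
    fixed cap."""
    ramps = [r for s in signals for r in _signal_ramps(s)]
    positive = [r for r in ramps if r > 0]
    if not positive:
        return fallback
    return min(min(positive) / 2.0, fallback * 10)


def _clone(handle: ModelHandle) -> ModelHandle:
    return ModelHandle(document=handle.document.clone())


def simulate(model: ModelHandle, t_end: float, output_step: float = 0.1,
             settings: IntegratorSettings | None = None) -> TimeSeries:
    """Deterministic trajectory of all dynamic variables plus every
    rule-assigned parameter (e.g. the injected signal value)."""
    settings = settings or IntegratorSettings()
    times, columns = simulate_model(model, t_end=t_end,
                                    output_step=output_step,
                                    settings=settings)
    return TimeSeries(times=times, columns=columns)


def detect_peaks(series: TimeSeries, column: str, after: float = 0.0,
                 prominence_fraction: float = 0.05) -> list[float]:
    """Local maxima of a column after a transient cutoff.

    Each discrete maximum is refined by fitting a parabola through the
    three samples around it; maxima whose prominence is below
    ``prominence_fraction`` of the column's post-cutoff range are
    discarded.
    """
    from scipy.signal import find_peaks

    if column not in series:
        raise KeyError(f"no column {column!r} "
                       f"(have {sorted(series.columns)})")
    mask = series.times >= after
    t = series.times[mask]
    x = series[column][mask]
    if t.size < 3:
        raise ValueError("fewer than 3 samples after the cutoff")
    span = float(x.max() - x.min())
    if span <= 0:
        raise ValueError(f"column {column!r} is constant after t={after}; "
                         "no peaks")
    idx, _ = find_peaks(x, prominence=prominence_fraction * span)
    if idx.size == 0:
        raise ValueError(f"no peaks found in column {column!r} after "
                         f"t={after}")
    peaks = []
    for i in idx:
        if 0 < i < t.size - 1:
            # quadratic vertex through (t[i-1..i+1], x[i-1..i+1])
            denom = x[i - 1] - 2 * x[i] + x[i + 1]
            if denom < 0:
                delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
                dt = t[i + 1] - t[i]
                peaks.append(float(t[i] + delta * dt))
                continue
        peaks.append(float(t[i]))
    return peaks


def estimate_period(peaks: Sequence[float]) -> float:
    """Median inter-peak interval; robust to one missed/spurious peak."""
    if len(peaks) < 3:
        raise ValueError(f"need at least 3 peaks, got {len(peaks)}")
    return float(np.median(np.diff(np.asarray(peaks, dtype=float))))


def _inject_copy(model: ModelHandle, light_parameter: str,
                 signal) -> ModelHandle:
    clone = _clone(model)
    inject_issf(clone, SignalAssignment(light_parameter, signal))
    return clone


def _wrap_half(delta: float, period: float) -> float:
    """Reduce into [-period/2, period/2); +period/2 maps to -period/2,
    so an exact half-cycle tie is reported as a delay."""
    return (delta + period / 2.0) % period - period / 2.0


def _circular_mean(phases: np.ndarray, period: float) -> float:
    ang = 2 * np.pi * np.asarray(phases) / period
    mean = math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return (mean * period / (2 * np.pi)) % period


def run_photoperiod_experiment(
        model: ModelHandle, light_parameter: str,
        photoperiods: Sequence[float], base_signal: ISSFParams,
        marker: str, *,
        n_cycles: int = 16,
        transient_cycles: int = DEFAULT_TRANSIENT_CYCLES,
        output_step: float = 0.05,
        convergence_tol: float = 0.1,
        settings: IntegratorSettings | None = None,
        ) -> dict[float, float]:
    """Steady-state peak phase of ``marker`` for each photoperiod.

    For each requested photoperiod the base signal's pulse duration is
    substituted, injected onto ``light_parameter``, and the model is
    simulated for ``n_cycles`` forcing cycles.  The returned phase is the
    circular mean peak time of the last three cycles, in hours after the
    up-ramp start ("dawn"), modulo the cycle period.  Raises if the peak
    phases of the last three cycles have not converged to within
    ``convergence_tol`` hours.
    """
    results: dict[float, float] = {}
    for tp in photoperiods:
        params = base_signal.replace(pulse_duration=float(tp))
        sim_settings = settings or IntegratorSettings(
            max_step=max_step_for_signals(params))
        injected = _inject_copy(model, light_parameter, params)
        t_end = n_cycles * params.cycle_period
        series = simulate(injected, t_end=t_end, output_step=output_step,
                          settings=sim_settings)
        after = transient_cycles * params.cycle_period
        peaks = detect_peaks(series, marker, after=after)
        if len(peaks) < 3:
            raise SimulationError(
                f"photoperiod {tp}: only {len(peaks)} post-transient peaks")
        dawn = -params.phase  # up-ramp start (mod cycle period)
        last3 = np.asarray(peaks[-3:])
        phases = (last3 - dawn) % params.cycle_period
        spread = max(abs(_wrap_half(p - phases[0], params.cycle_period))
                     for p in phases)
        if spread > convergence_tol:
            raise SimulationError(
                f"photoperiod {tp}: peak phase not converged "
                f"(spread {spread:.3f} h over last 3 cycles)")
        results[float(tp)] = _circular_mean(phases, params.cycle_period)
    return results


def run_prc(model: ModelHandle, light_parameter: str,
            entrain_schedule: SignalSchedule, pulse_template: ISSFParams,
            pulse_phases: Sequence[float], marker: str, *,
            shift_threshold: float = DEFAULT_SHIFT_THRESHOLD,
            t_end: Optional[float] = None,
            output_step: float = 0.05,
            settings: IntegratorSettings | None = None,
            n_shift_peaks: int = 4,
            ) -> PRCResult:
    """Phase-response curve by sweeping a single pulse's phase parameter.

    One control simulation carries the entrainment schedule only; each
    treated simulation adds the pulse (sum combiner) with the swept phase.
    The pulse template's cycle period must cover the whole simulation so
    the pulse occurs exactly once.  The phase shift at each swept phase is
    the control-minus-treated peak-time difference, measured from the
    first marker peak at least one full cycle after the pulse and averaged
    over ``n_shift_peaks`` peaks, reduced into half a cycle around zero.
    Advances are positive, delays negative; classification uses
    ``shift_threshold``.
    """
    entrain_schedule = as_schedule(entrain_schedule)
    cycle = entrain_schedule.segments[0].params.cycle_period
    release = entrain_schedule.segments[-1].start_time
    if t_end is None:
        t_end = pulse_template.cycle_period
    if pulse_template.cycle_period < t_end:
        raise ValueError(
            "single-pulse protocol requires pulse cycle_period "
            f"({pulse_template.cycle_period}) >= simulation span ({t_end})")
    sim_settings = settings or IntegratorSettings(
        max_step=max_step_for_signals(entrain_schedule, pulse_template))

    control_model = _inject_copy(model, light_parameter,
                                 CompositeSignal([entrain_schedule]))
    control = simulate(control_model, t_end=t_end, output_step=output_step,
                       settings=sim_settings)
    try:
        control_peaks = np.asarray(
            detect_peaks(control, marker, after=release))
    except ValueError as exc:
        raise SimulationError(
            "control run is not rhythmic after release into constant "
            f"conditions: {exc}") from exc
    if control_peaks.size < 4:
        raise SimulationError(
            f"control run has only {control_peaks.size} post-release peaks; "
            "extend the simulation")
    free_period = (estimate_period(control_peaks)
                   if control_peaks.size >= 3 else cycle)
    wrap_period = min(free_period, cycle)

    rows = []
    for phi in pulse_phases:
        pulse = pulse_template.replace(phase=float(phi))
        pulse_start = -pulse.phase
        composite = CompositeSignal([entrain_schedule, pulse])
        treated_model = _inject_copy(model, light_parameter, composite)
        treated = simulate(treated_model, t_end=t_end,
                           output_step=output_step, settings=sim_settings)
        treated_peaks = np.asarray(detect_peaks(treated, marker,
                                                after=release))
        t_min = pulse_start + cycle
        eligible = control_peaks[control_peaks >= t_min][:n_shift_peaks]
        if eligible.size == 0:
            raise SimulationError(
                f"no control peaks at least one cycle after the pulse at "
                f"t={pulse_start}")
        shifts = []
        for c in eligible:
            nearest = treated_peaks[np.argmin(np.abs(treated_peaks - c))]
            shifts.append(_wrap_half(c - nearest, wrap_period))
        shift = float(np.mean(shifts))
        if shift > shift_threshold:
            cls = ShiftClass.ADVANCE
        elif shift < -shift_threshold:
            cls = ShiftClass.DELAY
        else:
            cls = ShiftClass.NONE
        rows.append(PRCRow(pulse_phase=float(phi),
                           pulse_start_time=pulse_start,
                           phase_shift=shift, classification=cls))
    return PRCResult(rows=tuple(rows))
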