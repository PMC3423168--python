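import numpy as np
import pytest

from issf import (
    ISSFParams,
    SignalSchedule,
    make_accumulator_model,
    make_goodwin_oscillator,
)


@pytest.fixture
def fig1_bottom():
    """12-h pulse per 24-h cycle with 1-h ramps (integral 30 per cycle)."""
    return ISSFParams(offset=0.5, amplitude=1.5, pulse_duration=12.0,
                      cycle_period=24.0, ramp_duration=1.0, phase=0.0)


@pytest.fixture
def constant_light():
    return ISSFParams(offset=9.0, amplitude=0.0, pulse_duration=12.0,
                      cycle_period=24.0, ramp_duration=0.0, phase=0.0)


@pytest.fixture
def ld_params():
    """LD 12:12 forcing with short ramps, plateau 2.0, baseline 1.6."""
    return ISSFParams(offset=1.6, amplitude=0.4, pulse_duration=12.0,
                      cycle_period=24.0, ramp_duration=0.1, phase=0.0)


@pytest.fixture
def ld_then_dd(ld_params):
    """10 forcing cycles then release into constant conditions at t=240."""
    return SignalSchedule([(0.0, ld_params),
                           (240.0, ld_params.replace(amplitude=0.0))])


@pytest.fixture
def accumulator():
    return make_accumulator_model()


@pytest.fixture(scope="session")
def goodwin():
    """Calibrated oscillator fixture (session-scoped; injection protocols
    clone before mutating, and tests that inject directly must clone)."""
    return make_goodwin_oscillator(verify=False)


def trapezoid_breakpoints(params, t0, t1):
    """Strictly increasing grid over [t0, t1] containing every waveform
    breakpoint, so trapezoidal quadrature of the piecewise-linear signal
    is exact (independent oracle used across the suite)."""
    p = params
    offsets = np.array([0.0, p.ramp_duration, p.pulse_duration,
                        p.pulse_duration + p.ramp_duration])
    k0 = int(np.floor((t0 + p.phase) / p.cycle_period)) - 1
    k1 = int(np.ceil((t1 + p.phase) / p.cycle_period)) + 1
    pts = [k * p.cycle_period - p.phase + off
           for k in range(k0, k1 + 1) for off in offsets]
    pts = np.array(sorted({t0, t1, *[x for x in pts if t0 < x < t1]}))
    return pts


def piecewise_linear_quadrature(params, t0, t1):
    """Independent quadrature oracle: 2-point Gauss-Legendre on each
    breakpoint-to-breakpoint interval.  Exact for the piecewise-linear
    waveform, and its interior-only nodes make it immune to the jump
    discontinuities of zero-ramp square waves."""
    from issf import eval_issf

    pts = trapezoid_breakpoints(params, t0, t1)
    a, b = pts[:-1], pts[1:]
    half = (b - a) / 2.0
    mid = (a + b) / 2.0
    node = half / np.sqrt(3.0)
    values = eval_issf(params, mid - node) + eval_issf(params, mid + node)
    return float(np.sum(half * values))
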