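# issf — Input Signal Step Function toolkit

A six-parameter, numerically continuous periodic pulse waveform for
forcing SBML model parameters, plus the machinery to use it: injection
into models as pure MathML (piecewise + floor, no events), composition of
multiple signals, and circadian protocols — entrainment, photoperiod
comparison, and phase-response curves — driven by a deterministic ODE
simulator.

## The waveform

`ISSFParams` holds the six configuration parameters (all times in hours):

| field            | meaning                                              |
|------------------|------------------------------------------------------|
| `offset`         | baseline level                                       |
| `amplitude`      | level added during the pulse                         |
| `pulse_duration` | "on" time per cycle (between half-maximum crossings) |
| `cycle_period`   | forcing period                                       |
| `ramp_duration`  | linear off↔on transition time (0 = square wave)      |
| `phase`          | time translation; `phase = -t0` starts the pulse at `t0` |

Setting `amplitude = 0` gives a constant signal; setting `cycle_period`
to the simulation span gives a single pulse. The integral over one cycle
is exactly `offset*cycle_period + amplitude*pulse_duration`, independent
of the ramp. `SignalSchedule` switches parameter sets at fixed absolute
times (e.g. entrainment cycles, then constant darkness);
`CompositeSignal` folds several signals with `sum`, `product`, or `max`.

## Python API

```python
from issf import (ISSFParams, SignalAssignment, inject_issf,
                  make_goodwin_oscillator, run_prc, simulate)

model = make_goodwin_oscillator()          # built-in SBML fixture
ld = ISSFParams(offset=0, amplitude=1, pulse_duration=12,
                cycle_period=24, ramp_duration=0.1)
inject_issf(model, SignalAssignment("L", ld))
ts = simulate(model, t_end=240, output_step=0.1)
```

Injection adds one `FunctionDefinition` (annotated `SBO:0000475`) and one
`AssignmentRule` on the target parameter, clears its `constant` flag, and
leaves everything else untouched. Schedules become nested piecewise
expressions over the time csymbol; any parameter can be driven by any
combination of signals.

Two SBML fixtures ship with the package: a calibrated Goodwin-type
oscillator (free-running period 21.5 h, entrains 1:1 to 24-h light-dark
forcing) and a one-species accumulator `dx/dt = L(t)` whose trajectory is
the exact integral of the injected signal — the analytic oracle used to
validate the MathML encoding end to end. Published BioModels entries
(e.g. BIOMD0000000089) can be used by passing their SBML file as the
model path.

## CLI

Experiments are YAML configurations (see the schema in
`src/issf/config.py`):

```bash
issf validate    --config exp.yaml        # parse + echo normalized form
issf eval        --config exp.yaml        # signals -> CSV
issf inject      --config exp.yaml        # write the injected SBML
issf simulate    --config exp.yaml        # trajectories -> CSV
issf photoperiod --config exp.yaml        # peak phase per photoperiod
issf prc         --config exp.yaml        # phase-response curve -> CSV
issf fixtures goodwin --out goodwin.xml   # emit a built-in model
```

Exit codes: 0 success, 1 user error, 2 runtime failure. Everything is
deterministic; `--seed` is accepted for interface uniformity but unused.

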