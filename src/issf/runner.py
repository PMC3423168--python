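"""Execute a parsed experiment configuration and write its artifacts."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

from . import __version__
from .config import ExperimentConfig, serialize_config
from .fixtures import make_accumulator_model, make_goodwin_oscillator
from .protocols import (
    max_step_for_signals,
    run_photoperiod_experiment,
    run_prc,
    simulate,
)
from .sbml_io import (
    ModelHandle,
    SignalAssignment,
    inject_issf,
    load_model,
    write_model,
)
from .simulator import IntegratorSettings
from .timeseries import TimeSeries
from .waveform import eval_signal

__all__ = ["resolve_model", "apply_assignments", "run"]


def resolve_model(spec: str) -> ModelHandle:
    if spec == "fixture:goodwin":
        return make_goodwin_oscillator(verify=False)
    if spec == "fixture:accumulator":
        return make_accumulator_model()
    return load_model(spec)


def apply_assignments(config: ExperimentConfig,
                      model: ModelHandle) -> ModelHandle:
    for a in config.assignments:
        inject_issf(model, SignalAssignment(a.target,
                                            config.composite_for(a)))
    return model


def _log(outdir: Path, config: ExperimentConfig, lines: list[str]) -> None:
    text = "\n".join([
        f"issf {__version__}",
        "normalized config:",
        serialize_config(config).rstrip(),
        *lines,
        "",
    ])
    (outdir / "run.log").write_text(text)


def run(config: ExperimentConfig, outdir=None, *,
        inject_only: bool = False, echo=print) -> Path:
    """Run the configured protocol; returns the output directory."""
    outdir = Path(outdir or config.output)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    opts = config.options

    if config.protocol == "evaluate" and not inject_only:
        grid = np.arange(opts["t_start"],
                         opts["t_end"] + opts["step"] / 2, opts["step"])
        columns = {name: np.asarray(eval_signal(sched, grid), dtype=float)
                   for name, sched in config.signals.items()}
        ts = TimeSeries(times=grid, columns=columns)
        ts.to_csv(outdir / "signals.csv")
        log.append(f"wrote signals.csv ({len(grid)} samples, "
                   f"{len(columns)} signals)")
        _log(outdir, config, log)
        echo(f"evaluated {len(columns)} signal(s) -> {outdir}/signals.csv")
        return outdir

    model = resolve_model(config.model)
    apply_assignments(config, model)
    write_model(model, outdir / "injected.xml")
    log.append("wrote injected.xml")
    if inject_only:
        _log(outdir, config, log)
        echo(f"injected model -> {outdir}/injected.xml")
        return outdir

    signals = [config.composite_for(a) for a in config.assignments]
    settings = IntegratorSettings(max_step=max_step_for_signals(*signals)
                                  if signals else None)

    if config.protocol == "simulate":
        ts = simulate(model, t_end=opts["t_end"],
                      output_step=opts["output_step"], settings=settings)
        ts.to_csv(outdir / "trajectories.csv")
        log.append(f"wrote trajectories.csv ({ts.times.size} rows)")
        echo(f"simulated to t={opts['t_end']} -> {outdir}/trajectories.csv")
    elif config.protocol == "photoperiod":
        base_model = resolve_model(config.model)  # protocol injects itself
        sched = config.signals[opts["signal"]]
        if len(sched.segments) != 1:
            raise ValueError("photoperiod base signal must have one segment")
        phases = run_photoperiod_experiment(
            base_model, config.assignments[0].target,
            opts["photoperiods"], sched.segments[0].params,
            opts["marker"], n_cycles=int(opts["n_cycles"]),
            transient_cycles=int(opts["transient_cycles"]),
            output_step=opts["output_step"])
        import pandas as pd
        df = pd.DataFrame({"photoperiod": list(phases),
                           "peak_phase": list(phases.values())})
        df.to_csv(outdir / "photoperiod.csv", index=False)
        log.append(f"wrote photoperiod.csv ({len(df)} rows)")
        echo(df.to_string(index=False))
    elif config.protocol == "prc":
        base_model = resolve_model(config.model)
        assignment = config.assignments[0]
        pulse_name = opts["pulse_signal"]
        entrain_names = [n for n in assignment.signal_names
                         if n != pulse_name]
        if not entrain_names:
            raise ValueError("prc assignment must include an entrainment "
                             "signal besides the pulse")
        entrain = config.signals[entrain_names[0]]
        pulse_sched = config.signals[pulse_name]
        if len(pulse_sched.segments) != 1:
            raise ValueError("prc pulse signal must have one segment")
        result = run_prc(
            base_model, assignment.target, entrain,
            pulse_sched.segments[0].params, opts["phases"], opts["marker"],
            shift_threshold=opts["shift_threshold"],
            t_end=opts["t_end"], output_step=opts["output_step"])
        result.to_csv(outdir / "prc.csv")
        log.append(f"wrote prc.csv ({len(result.rows)} rows, "
                   f"{len(result.advances())} advances, "
                   f"{len(result.delays())} delays)")
        echo(result.to_dataframe().to_string(index=False))
    else:
        raise ValueError(f"unknown protocol {config.protocol!r}")

    _log(outdir, config, log)
    return outdir
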