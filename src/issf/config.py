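"""Experiment configuration: YAML mappings describing signals, wiring,
and a protocol to run, so signals can be configured without touching SBML.

Schema (all times in hours)::

    model: fixture:goodwin | fixture:accumulator | path/to/model.xml
    output: results_dir            # optional, CLI --out overrides
    signals:
      <name>:
        - {start: 0, offset: 0, amplitude: 1, pulse_duration: 12,
           cycle_period: 24, ramp_duration: 0.1, phase: 0}
        - {start: 240, ...}        # later segments switch regime
    assignments:
      - {target: L, signals: [<name>, ...], combiner: sum}
    protocol: evaluate | simulate | photoperiod | prc
    evaluate:    {t_start: 0, t_end: 48, step: 0.01}
    simulate:    {t_end: 120, output_step: 0.1}
    photoperiod: {marker: X, photoperiods: [8, 16], signal: <name>,
                  n_cycles: 16, transient_cycles: 5, output_step: 0.05}
    prc:         {marker: X, pulse_signal: <name>,
                  phases: {start: -264, stop: -288, step: -2},
                  shift_threshold: 0.25, t_end: null, output_step: 0.05}

Unknown keys anywhere are an error, not silently ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .waveform import (
    Combiner,
    CompositeSignal,
    ISSFParams,
    InvalidSignalError,
    SignalSchedule,
)

__all__ = ["ExperimentConfig", "ConfigError", "parse_config",
           "normalize_config", "serialize_config"]

PROTOCOLS = ("evaluate", "simulate", "photoperiod", "prc")
FIXTURE_NAMES = ("goodwin", "accumulator")

_SEGMENT_KEYS = {"start", "offset", "amplitude", "pulse_duration",
                 "cycle_period", "ramp_duration", "phase"}
_SEGMENT_DEFAULTS = {"start": 0.0, "ramp_duration": 0.0, "phase": 0.0}


class ConfigError(ValueError):
    pass


def _require_mapping(value, where: str) -> dict:
    if not isinstance(value, dict):
        raise ConfigError(f"{where} must be a mapping, got "
                          f"{type(value).__name__}")
    return value


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {where}: {sorted(unknown)} "
            f"(allowed: {sorted(allowed)})")


def _number(mapping: dict, key: str, where: str, default=None) -> float:
    if key not in mapping:
        if default is None:
            raise ConfigError(f"{where} is missing required key {key!r}")
        return float(default)
    v = mapping[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise ConfigError(f"{where}.{key} must be a number, got {v!r}")
    return float(v)


def _parse_segment(seg: dict, where: str) -> tuple[float, ISSFParams]:
    _require_mapping(seg, where)
    _check_keys(seg, _SEGMENT_KEYS, where)
    start = _number(seg, "start", where, _SEGMENT_DEFAULTS["start"])
    try:
        params = ISSFParams(
            offset=_number(seg, "offset", where),
            amplitude=_number(seg, "amplitude", where),
            pulse_duration=_number(seg, "pulse_duration", where),
            cycle_period=_number(seg, "cycle_period", where),
            ramp_duration=_number(seg, "ramp_duration", where,
                                  _SEGMENT_DEFAULTS["ramp_duration"]),
            phase=_number(seg, "phase", where, _SEGMENT_DEFAULTS["phase"]),
        )
    except InvalidSignalError as exc:
        raise ConfigError(f"{where}: {exc}") from exc
    return start, params


@dataclass(frozen=True)
class AssignmentConfig:
    target: str
    signal_names: tuple[str, ...]
    combiner: Combiner = Combiner.SUM


@dataclass
class ExperimentConfig:
    model: str
    signals: dict[str, SignalSchedule]
    assignments: list[AssignmentConfig]
    protocol: str
    options: dict[str, Any]
    output: str = "issf_out"

    def schedule(self, name: str) -> SignalSchedule:
        return self.signals[name]

    def composite_for(self, assignment: AssignmentConfig) -> CompositeSignal:
        return CompositeSignal(
            [self.signals[n] for n in assignment.signal_names],
            combiner=assignment.combiner)


_PROTOCOL_KEYS = {
    "evaluate": {"t_start", "t_end", "step"},
    "simulate": {"t_end", "output_step"},
    "photoperiod": {"marker", "photoperiods", "signal", "n_cycles",
                    "transient_cycles", "output_step"},
    "prc": {"marker", "pulse_signal", "phases", "shift_threshold",
            "t_end", "output_step"},
}

_PROTOCOL_DEFAULTS = {
    "evaluate": {"t_start": 0.0, "t_end": 48.0, "step": 0.01},
    "simulate": {"t_end": 120.0, "output_step": 0.1},
    "photoperiod": {"n_cycles": 16, "transient_cycles": 5,
                    "output_step": 0.05},
    "prc": {"shift_threshold": 0.25, "t_end": None, "output_step": 0.05},
}


def _parse_phases(spec, where: str) -> list[float]:
    if isinstance(spec, list):
        return [float(x) for x in spec]
    _require_mapping(spec, where)
    _check_keys(spec, {"start", "stop", "step"}, where)
    start = _number(spec, "start", where)
    stop = _number(spec, "stop", where)
    step = _number(spec, "step", where)
    if step == 0 or (stop - start) * step < 0:
        raise ConfigError(f"{where}: step {step} never reaches stop {stop} "
                          f"from start {start}")
    n = int(math.floor((stop - start) / step + 1e-9))
    return [start + k * step for k in range(n + 1)]


def parse_config_dict(raw: dict, source: str = "<dict>") -> ExperimentConfig:
    _require_mapping(raw, source)
    _check_keys(raw, {"model", "output", "signals", "assignments",
                      "protocol"} | set(PROTOCOLS), source)
    for key in ("model", "signals", "protocol"):
        if key not in raw:
            raise ConfigError(f"{source} is missing required key {key!r}")
    model = str(raw["model"])
    if model.startswith("fixture:") and \
            model.split(":", 1)[1] not in FIXTURE_NAMES:
        raise ConfigError(
            f"unknown fixture {model!r} (have "
            f"{['fixture:' + n for n in FIXTURE_NAMES]})")

    signals: dict[str, SignalSchedule] = {}
    for name, segs in _require_mapping(raw["signals"], "signals").items():
        if isinstance(segs, dict):
            segs = [segs]
        if not isinstance(segs, list) or not segs:
            raise ConfigError(
                f"signals.{name} must be a segment or list of segments")
        parsed = [_parse_segment(s, f"signals.{name}[{i}]")
                  for i, s in enumerate(segs)]
        try:
            signals[name] = SignalSchedule(parsed)
        except InvalidSignalError as exc:
            raise ConfigError(f"signals.{name}: {exc}") from exc

    assignments: list[AssignmentConfig] = []
    seen_targets: set[str] = set()
    for i, a in enumerate(raw.get("assignments", []) or []):
        where = f"assignments[{i}]"
        _require_mapping(a, where)
        _check_keys(a, {"target", "signals", "combiner"}, where)
        for key in ("target", "signals"):
            if key not in a:
                raise ConfigError(f"{where} is missing key {key!r}")
        names = a["signals"]
        if isinstance(names, str):
            names = [names]
        for n in names:
            if n not in signals:
                raise ConfigError(
                    f"{where} references undefined signal {n!r} "
                    f"(defined: {sorted(signals)})")
        target = str(a["target"])
        if target in seen_targets:
            raise ConfigError(
                f"{where}: duplicate assignment for target {target!r}; "
                "combine signals in one assignment instead")
        seen_targets.add(target)
        try:
            combiner = Combiner(a.get("combiner", "sum"))
        except ValueError:
            raise ConfigError(
                f"{where}.combiner must be one of "
                f"{[c.value for c in Combiner]}, got {a.get('combiner')!r}")
        assignments.append(AssignmentConfig(
            target=target, signal_names=tuple(str(n) for n in names),
            combiner=combiner))

    protocol = str(raw["protocol"])
    if protocol not in PROTOCOLS:
        raise ConfigError(
            f"protocol must be one of {PROTOCOLS}, got {protocol!r}")
    options = dict(_PROTOCOL_DEFAULTS[protocol])
    block = raw.get(protocol, {}) or {}
    _require_mapping(block, protocol)
    _check_keys(block, _PROTOCOL_KEYS[protocol], protocol)
    options.update(block)

    if protocol in ("photoperiod", "prc"):
        if "marker" not in options:
            raise ConfigError(f"{protocol}.marker is required")
        if not assignments:
            raise ConfigError(f"protocol {protocol!r} needs an assignment "
                              "naming the light parameter")
    if protocol == "photoperiod":
        if "photoperiods" not in options:
            raise ConfigError("photoperiod.photoperiods is required")
        options["photoperiods"] = [float(x)
                                   for x in options["photoperiods"]]
        sig = options.get("signal") or assignments[0].signal_names[0]
        if sig not in signals:
            raise ConfigError(f"photoperiod.signal {sig!r} is undefined")
        options["signal"] = sig
    if protocol == "prc":
        if "phases" not in options:
            raise ConfigError("prc.phases is required")
        options["phases"] = _parse_phases(options["phases"], "prc.phases")
        pulse = options.get("pulse_signal")
        if pulse is None:
            if len(assignments[0].signal_names) != 2:
                raise ConfigError(
                    "prc.pulse_signal is required unless the assignment "
                    "combines exactly two signals")
            pulse = assignments[0].signal_names[-1]
        if pulse not in signals:
            raise ConfigError(f"prc.pulse_signal {pulse!r} is undefined")
        options["pulse_signal"] = pulse

    return ExperimentConfig(
        model=model, signals=signals, assignments=assignments,
        protocol=protocol, options=options,
        output=str(raw.get("output", "issf_out")))


def parse_config(path) -> ExperimentConfig:
    """Parse and fully validate an experiment configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    return parse_config_dict(raw, source=str(path))


def _segment_dict(start: float, p: ISSFParams) -> dict:
    d = {"offset": p.offset, "amplitude": p.amplitude,
         "pulse_duration": p.pulse_duration, "cycle_period": p.cycle_period,
         "ramp_duration": p.ramp_duration, "phase": p.phase}
    if math.isfinite(start):
        d = {"start": start, **d}
    return d


def normalize_config(config: ExperimentConfig) -> dict:
    """Config as a plain dict with every default made explicit; parsing
    the serialized form reproduces an identical normalized dict."""
    out: dict[str, Any] = {
        "model": config.model,
        "output": config.output,
        "signals": {
            name: [_segment_dict(seg.start_time, seg.params)
                   for seg in sched.segments]
            for name, sched in config.signals.items()
        },
        "assignments": [
            {"target": a.target, "signals": list(a.signal_names),
             "combiner": a.combiner.value}
            for a in config.assignments
        ],
        "protocol": config.protocol,
        config.protocol: dict(config.options),
    }
    return out


def serialize_config(config: ExperimentConfig) -> str:
    return yaml.safe_dump(normalize_config(config), sort_keys=False)
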