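"""SBML model handling: loading, validation, and ISSF injection.

Injection adds to an SBML document:

* one ``FunctionDefinition`` with id ``issf`` implementing the waveform as
  pure MathML (piecewise + floor-based wrapping; no events, no ``mod``),
  annotated with SBO:0000475;
* one ``AssignmentRule`` on the target parameter, whose math calls
  ``issf(time, ...)`` once per schedule segment — schedules become nested
  piecewise expressions over the time csymbol, composites are folded with
  the combining operator;
* the target parameter's ``constant`` flag is cleared.

Because SBML forbids the time csymbol inside function definitions, time is
always passed to ``issf`` as its first argument from the rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import libsbml

from .waveform import (
    Combiner,
    CompositeSignal,
    ISSFParams,
    SignalLike,
    SignalSchedule,
    as_schedule,
)

__all__ = [
    "ModelHandle",
    "ParameterInfo",
    "SignalAssignment",
    "SBMLIOError",
    "InjectionError",
    "ISSF_FUNCTION_ID",
    "ISSF_SBO_TERM",
    "load_model",
    "load_model_from_string",
    "list_controllable_parameters",
    "inject_issf",
    "write_model",
    "model_to_string",
]

ISSF_FUNCTION_ID = "issf"
ISSF_SBO_TERM = 475

# Wrapped cycle time u = (t+phi) - tC*floor((t+phi)/tC), inlined because
# MathML lambdas have no local bindings.  Piece order guards the tR=0
# square-wave case: 'u < tR' is never true then, so u/tR is never taken.
_U = "((t + phi) - tC * floor((t + phi) / tC))"
ISSF_LAMBDA_FORMULA = (
    "lambda(t, theta0, theta1, tP, tC, tR, phi, "
    "theta0 + theta1 * piecewise("
    f"{_U} / tR, {_U} < tR, "
    f"1, {_U} < tP, "
    f"1 - ({_U} - tP) / tR, {_U} < tP + tR, "
    "0))"
)


class SBMLIOError(RuntimeError):
    """Raised for unreadable, invalid, or unwritable SBML documents."""


class InjectionError(RuntimeError):
    """Raised when an ISSF cannot be wired onto the requested target."""


@dataclass(frozen=True)
class ParameterInfo:
    value: Optional[float]
    constant: bool
    rule: Optional[str]  # "assignment" | "rate" | "event" | None


@dataclass
class ModelHandle:
    """A parsed SBML document plus an index of its global parameters."""

    document: libsbml.SBMLDocument
    parameter_index: dict[str, ParameterInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.refresh_index()

    @property
    def model(self) -> libsbml.Model:
        return self.document.getModel()

    @property
    def level(self) -> int:
        return self.document.getLevel()

    @property
    def version(self) -> int:
        return self.document.getVersion()

    def refresh_index(self) -> None:
        """Rebuild the parameter index from the document (call after any
        mutation)."""
        model = self.model
        governed: dict[str, str] = {}
        for i in range(model.getNumRules()):
            rule = model.getRule(i)
            var = rule.getVariable()
            if rule.isAssignment():
                governed[var] = "assignment"
            elif rule.isRate():
                governed[var] = "rate"
        for i in range(model.getNumEvents()):
            event = model.getEvent(i)
            for j in range(event.getNumEventAssignments()):
                governed.setdefault(
                    event.getEventAssignment(j).getVariable(), "event")
        index = {}
        for i in range(model.getNumParameters()):
            p = model.getParameter(i)
            index[p.getId()] = ParameterInfo(
                value=p.getValue() if p.isSetValue() else None,
                constant=bool(p.getConstant()) if p.isSetConstant() else True,
                rule=governed.get(p.getId()),
            )
        self.parameter_index = index


@dataclass(frozen=True)
class SignalAssignment:
    """Wiring of a (composite) signal onto one global model parameter."""

    target_parameter: str
    signal: CompositeSignal
    sbo_term: int = ISSF_SBO_TERM

    def __init__(self, target_parameter: str, signal,
                 sbo_term: int = ISSF_SBO_TERM) -> None:
        if isinstance(signal, (ISSFParams, SignalSchedule)):
            signal = CompositeSignal([signal])
        if not isinstance(signal, CompositeSignal):
            raise TypeError("signal must be ISSFParams, SignalSchedule, "
                            "or CompositeSignal")
        object.__setattr__(self, "target_parameter", str(target_parameter))
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "sbo_term", int(sbo_term))


def _check_parse_errors(doc: libsbml.SBMLDocument, source: str) -> None:
    log = doc.getErrorLog()
    fatal = []
    for i in range(log.getNumErrors()):
        err = log.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            fatal.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    if fatal:
        raise SBMLIOError(
            f"failed to parse SBML from {source}:\n" + "\n".join(fatal))


def _consistency_check(doc: libsbml.SBMLDocument, context: str,
                       strict: bool = True) -> None:
    # Unit consistency is advisory only; everything else is enforced.
    doc.setConsistencyChecks(libsbml.LIBSBML_CAT_UNITS_CONSISTENCY, False)
    doc.getErrorLog().clearLog()
    doc.checkConsistency()
    log = doc.getErrorLog()
    errors, warns = [], []
    for i in range(log.getNumErrors()):
        err = log.getError(i)
        msg = f"line {err.getLine()}: {err.getMessage().strip()}"
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            errors.append(msg)
        else:
            warns.append(msg)
    for msg in warns:
        warnings.warn(f"SBML consistency warning ({context}): {msg}",
                      stacklevel=3)
    if errors and strict:
        raise SBMLIOError(
            f"SBML consistency errors ({context}):\n" + "\n".join(errors))


def _wrap_document(doc: libsbml.SBMLDocument, source: str) -> ModelHandle:
    _check_parse_errors(doc, source)
    model = doc.getModel()
    if model is None:
        raise SBMLIOError(f"{source} contains no SBML model")
    if model.getNumParameters() == 0:
        raise SBMLIOError(
            f"model in {source} declares no global parameters; "
            "nothing can be forced")
    _consistency_check(doc, f"loading {source}")
    return ModelHandle(document=doc)


def load_model(path: Union[str, Path]) -> ModelHandle:
    """Read and validate an SBML file (Level 2 or 3)."""
    path = Path(path)
    if not path.exists():
        raise SBMLIOError(f"no such file: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    return _wrap_document(doc, str(path))


def load_model_from_string(xml: str, source: str = "<string>") -> ModelHandle:
    doc = libsbml.readSBMLFromString(xml)
    return _wrap_document(doc, source)


def list_controllable_parameters(handle: ModelHandle) -> list[str]:
    """Global parameters not already governed by a rule or event."""
    handle.refresh_index()
    return [pid for pid, info in handle.parameter_index.items()
            if info.rule is None]


def _fmt(x: float) -> str:
    if x == math.inf:
        return "INF"
    if x == -math.inf:
        return "-INF"
    return repr(float(x))


def _issf_call(params: ISSFParams) -> str:
    p = params
    return (f"{ISSF_FUNCTION_ID}(time, {_fmt(p.offset)}, {_fmt(p.amplitude)}, "
            f"{_fmt(p.pulse_duration)}, {_fmt(p.cycle_period)}, "
            f"{_fmt(p.ramp_duration)}, {_fmt(p.phase)})")


def _schedule_formula(schedule: SignalSchedule) -> str:
    # Later segments take precedence, so wrap earlier ones inside the
    # 'otherwise' branch: piecewise(last, time >= start_last, ...).
    expr = _issf_call(schedule.segments[0].params)
    for seg in schedule.segments[1:]:
        expr = (f"piecewise({_issf_call(seg.params)}, "
                f"time >= {_fmt(seg.start_time)}, {expr})")
    return expr


def signal_formula(signal: SignalLike) -> str:
    """Infix (L3) formula evaluating a signal via ``issf(time, ...)``."""
    if isinstance(signal, (ISSFParams, SignalSchedule)):
        return _schedule_formula(as_schedule(signal))
    if not isinstance(signal, CompositeSignal):
        raise TypeError(f"not a signal: {type(signal).__name__}")
    parts = [_schedule_formula(s) for s in signal.signals]
    if len(parts) == 1:
        return parts[0]
    if signal.combiner is Combiner.SUM:
        return " + ".join(f"({p})" for p in parts)
    if signal.combiner is Combiner.PRODUCT:
        return " * ".join(f"({p})" for p in parts)
    # max: folded pairwise as piecewise to stay inside the L3V1 core
    # MathML subset (no max csymbol before L3V2).
    expr = parts[0]
    for p in parts[1:]:
        expr = f"piecewise({expr}, ({expr}) >= ({p}), {p})"
    return expr


def _parse_formula(formula: str) -> libsbml.ASTNode:
    ast = libsbml.parseL3Formula(formula)
    if ast is None:
        raise SBMLIOError(
            f"internal formula failed to parse: {formula!r}: "
            f"{libsbml.getLastParseL3Error()}")
    return ast


def _ensure_function_definition(model: libsbml.Model,
                                sbo_term: int) -> libsbml.FunctionDefinition:
    existing = model.getFunctionDefinition(ISSF_FUNCTION_ID)
    if existing is not None:
        return existing
    fd = model.createFunctionDefinition()
    fd.setId(ISSF_FUNCTION_ID)
    fd.setName("input signal step function")
    fd.setMath(_parse_formula(ISSF_LAMBDA_FORMULA))
    fd.setSBOTerm(sbo_term)
    return fd


def _find_local_parameter(model: libsbml.Model, pid: str) -> Optional[str]:
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        kl = rxn.getKineticLaw()
        if kl is None:
            continue
        for j in range(kl.getNumParameters()):
            if kl.getParameter(j).getId() == pid:
                return rxn.getId()
    return None


def _promote_local_parameters(handle: ModelHandle) -> None:
    props = libsbml.ConversionProperties()
    props.addOption("promoteLocalParameters", True,
                    "promote local parameters to global")
    if handle.document.convert(props) != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise InjectionError("local parameter promotion failed")
    handle.refresh_index()


def inject_issf(handle: ModelHandle, assignment: SignalAssignment, *,
                replace: bool = False,
                promote_local: bool = False) -> ModelHandle:
    """Wire a signal onto a model parameter via an assignment rule.

    Mutates and returns ``handle``.  Refuses to override an existing rule
    on the target unless ``replace=True``; refuses reaction-local
    parameters unless ``promote_local=True`` promotes them first.
    """
    model = handle.model
    pid = assignment.target_parameter
    if pid not in handle.parameter_index:
        rxn = _find_local_parameter(model, pid)
        if rxn is not None:
            if not promote_local:
                raise InjectionError(
                    f"{pid!r} is a local parameter of reaction {rxn!r}; "
                    "pass promote_local=True to promote it to a global "
                    "parameter first")
            _promote_local_parameters(handle)
            model = handle.model
            pid_global = next(
                (g for g in handle.parameter_index if g.endswith(f"_{pid}")),
                None)
            if pid_global is None:
                raise InjectionError(
                    f"promotion did not produce a global form of {pid!r}")
            pid = pid_global
        else:
            raise InjectionError(
                f"no parameter {pid!r} in model "
                f"(global parameters: {sorted(handle.parameter_index)})")
    info = handle.parameter_index[pid]
    if info.rule is not None:
        if not replace or info.rule != "assignment":
            raise InjectionError(
                f"parameter {pid!r} is already governed by a "
                f"{info.rule} rule; pass replace=True to override an "
                "assignment rule")
        model.removeRuleByVariable(pid)

    fd = _ensure_function_definition(model, assignment.sbo_term)
    if not fd.isSetSBOTerm():
        fd.setSBOTerm(assignment.sbo_term)

    rule = model.createAssignmentRule()
    rule.setVariable(pid)
    rule.setMath(_parse_formula(signal_formula(assignment.signal)))
    rule.setSBOTerm(assignment.sbo_term)

    param = model.getParameter(pid)
    param.setConstant(False)

    _consistency_check(handle.document, f"after injecting onto {pid!r}")
    handle.refresh_index()
    return handle


def model_to_string(handle: ModelHandle) -> str:
    return libsbml.writeSBMLToString(handle.document)


def write_model(handle: ModelHandle, path: Union[str, Path]) -> None:
    """Serialize the document; the result re-loads to an equivalent handle."""
    path = Path(path)
    if not libsbml.writeSBMLToFile(handle.document, str(path)):
        raise SBMLIOError(f"could not write SBML to {path}")
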