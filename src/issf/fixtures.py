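"""Self-contained SBML test models.

Two generators keep the whole toolkit exercisable without downloading
published models:

* :func:`make_goodwin_oscillator` — a three-variable negative-feedback
  (Goodwin-type) oscillator ``X -> Y -> Z --| X`` with Hill repression and
  an additive light input, calibrated so the free-running period sits near
  21.5 h and the oscillator entrains 1:1 to 24-h light-dark forcing of
  modest amplitude.
* :func:`make_accumulator_model` — ``dx/dt = L(t)`` with ``x(0) = 0``, so
  after injecting a signal onto ``L`` the simulated ``x`` equals the exact
  running integral of the signal.  This is the analytic oracle used to
  validate the MathML encoding end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import libsbml
import numpy as np

from .sbml_io import ModelHandle, SBMLIOError
from .simulator import IntegratorSettings, simulate_model

__all__ = ["OscillatorConfig", "CalibrationError",
           "make_goodwin_oscillator", "make_accumulator_model",
           "GOODWIN_DEFAULT_RATES"]


class CalibrationError(RuntimeError):
    """The requested oscillator configuration does not sustain oscillations."""


# Frozen after one-time numerical calibration of the dimensionless Goodwin
# system (unit production/transfer rates, equal degradation rates 0.2,
# Hill n = 10, K = 1: measured period 19.654 time units).  All rates are
# scaled by the common factor 19.654/21.5 = 0.9141 so the free-running
# period lands at 21.5 h; uniform rate scaling is an exact time rescaling
# of this system.  At light_gain = 0.1 the oscillator entrains 1:1 to
# 24-h LD forcing of plateau amplitude 1.
GOODWIN_DEFAULT_RATES = {
    "production_rate": 0.9141,
    "x_to_y_rate": 0.9141,
    "y_to_z_rate": 0.9141,
    "x_degradation": 0.18282,
    "y_degradation": 0.18282,
    "z_degradation": 0.18282,
    "light_gain": 0.1,
}


@dataclass(frozen=True)
class OscillatorConfig:
    """Configuration of the Goodwin-type oscillator fixture."""

    free_running_period: float = 21.5
    light_parameter_id: str = "L"
    light_coupling: str = "production"  # or "degradation"
    hill_coefficient: int = 10
    repression_threshold: float = 1.0
    production_rate: float = GOODWIN_DEFAULT_RATES["production_rate"]
    x_to_y_rate: float = GOODWIN_DEFAULT_RATES["x_to_y_rate"]
    y_to_z_rate: float = GOODWIN_DEFAULT_RATES["y_to_z_rate"]
    x_degradation: float = GOODWIN_DEFAULT_RATES["x_degradation"]
    y_degradation: float = GOODWIN_DEFAULT_RATES["y_degradation"]
    z_degradation: float = GOODWIN_DEFAULT_RATES["z_degradation"]
    light_gain: float = GOODWIN_DEFAULT_RATES["light_gain"]

    def __post_init__(self) -> None:
        if self.light_coupling not in ("production", "degradation"):
            raise ValueError(
                f"light_coupling must be 'production' or 'degradation', "
                f"got {self.light_coupling!r}")
        if self.hill_coefficient < 4:
            raise ValueError("hill_coefficient must be an integer >= 4")
        for name in ("repression_threshold", "production_rate",
                     "x_to_y_rate", "y_to_z_rate", "x_degradation",
                     "y_degradation", "z_degradation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.light_gain < 0:
            raise ValueError("light_gain must be >= 0")


def _new_document() -> tuple[libsbml.SBMLDocument, libsbml.Model]:
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    comp = model.createCompartment()
    comp.setId("cell")
    comp.setSize(1.0)
    comp.setConstant(True)
    comp.setSpatialDimensions(3)
    return doc, model


def _add_species(model: libsbml.Model, sid: str, value: float) -> None:
    s = model.createSpecies()
    s.setId(sid)
    s.setCompartment("cell")
    s.setInitialConcentration(value)
    s.setBoundaryCondition(False)
    s.setHasOnlySubstanceUnits(False)
    s.setConstant(False)


def _add_parameter(model: libsbml.Model, pid: str, value: float,
                   constant: bool = True) -> None:
    p = model.createParameter()
    p.setId(pid)
    p.setValue(value)
    p.setConstant(constant)


def _add_rate_rule(model: libsbml.Model, variable: str, formula: str) -> None:
    rule = model.createRateRule()
    rule.setVariable(variable)
    ast = libsbml.parseL3Formula(formula)
    if ast is None:
        raise SBMLIOError(f"bad fixture formula {formula!r}")
    rule.setMath(ast)


def make_accumulator_model(light_parameter_id: str = "L") -> ModelHandle:
    """One-species model ``dx/dt = L`` with ``x(0) = 0``.

    After injecting a signal onto ``L``, the simulated ``x(t)`` is the
    exact running integral of the signal, giving a closed-form oracle for
    the injected MathML.
    """
    doc, model = _new_document()
    model.setId("issf_accumulator_fixture")
    _add_species(model, "x", 0.0)
    _add_parameter(model, light_parameter_id, 0.0)
    _add_rate_rule(model, "x", light_parameter_id)
    return ModelHandle(document=doc)


def _goodwin_formulas(config: OscillatorConfig) -> dict[str, str]:
    c = config
    n = c.hill_coefficient
    K = c.repression_threshold
    hill = f"{c.production_rate} / (1 + (Z / {K})^{n})"
    light = f"{c.light_gain} * {c.light_parameter_id}"
    dX = f"{hill} - {c.x_degradation} * X"
    dZ = f"{c.y_to_z_rate} * Y - {c.z_degradation} * Z"
    if c.light_coupling == "production":
        dX += f" + {light}"
    else:
        dZ += f" - {light} * Z"
    return {
        "X": dX,
        "Y": f"{c.x_to_y_rate} * X - {c.y_degradation} * Y",
        "Z": dZ,
    }


def verify_sustained_oscillation(handle: ModelHandle, *, species: str = "X",
                                 t_end: float = 400.0,
                                 transient: float = 150.0) -> list[float]:
    """Check that the unforced model oscillates without amplitude decay.

    Returns the post-transient peak times; raises
    :class:`CalibrationError` with diagnostics otherwise.
    """
    from .protocols import detect_peaks  # local import avoids a cycle
    from .timeseries import TimeSeries

    times, cols = simulate_model(
        handle, t_end=t_end, output_step=0.05,
        settings=IntegratorSettings(rtol=1e-7, atol=1e-9))
    series = TimeSeries(times=times, columns={species: cols[species]})
    x = cols[species]
    post = x[times >= transient]
    span = float(post.max() - post.min())
    full_span = float(x.max() - x.min())
    if full_span <= 0 or span < 0.05 * max(full_span, 1e-12) or span < 1e-6:
        raise CalibrationError(
            "no sustained oscillation: post-transient peak-to-peak "
            f"amplitude {span:.3g} vs overall {full_span:.3g} "
            "(damped or fixed point; increase the Hill coefficient)")
    try:
        peaks = detect_peaks(series, species, after=transient)
    except ValueError as exc:
        raise CalibrationError(f"no oscillation peaks found: {exc}") from exc
    if len(peaks) < 5:
        raise CalibrationError(
            f"only {len(peaks)} post-transient peaks in {t_end} h; "
            "oscillation not sustained")
    # Amplitude non-decay: compare peak heights across the window.
    heights = np.interp(peaks, times, x)
    if heights[-1] - post.min() < 0.9 * (heights[0] - post.min()):
        raise CalibrationError(
            "peak amplitude decays across the verification window "
            f"(first {heights[0]:.4g}, last {heights[-1]:.4g})")
    return list(peaks)


def make_goodwin_oscillator(config: OscillatorConfig | None = None, *,
                            verify: bool = True) -> ModelHandle:
    """Emit the Goodwin-type oscillator fixture as an SBML L3V1 model.

    With ``verify=True`` (default) the unforced model is simulated and
    checked for sustained oscillations before being returned.
    """
    config = config or OscillatorConfig()
    doc, model = _new_document()
    model.setId("issf_goodwin_fixture")
    _add_species(model, "X", 0.1)
    _add_species(model, "Y", 0.2)
    _add_species(model, "Z", 1.0)
    _add_parameter(model, config.light_parameter_id, 0.0)
    for var, formula in _goodwin_formulas(config).items():
        _add_rate_rule(model, var, formula)
    handle = ModelHandle(document=doc)
    if verify:
        verify_sustained_oscillation(handle)
    return handle
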