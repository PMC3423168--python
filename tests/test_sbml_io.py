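import numpy as np
import pytest

import libsbml

from issf import (
    Combiner,
    CompositeSignal,
    ISSFParams,
    InjectionError,
    IntegratorSettings,
    SBMLIOError,
    SignalAssignment,
    SignalSchedule,
    eval_composite,
    eval_schedule,
    inject_issf,
    list_controllable_parameters,
    load_model,
    load_model_from_string,
    make_accumulator_model,
    model_to_string,
    simulate,
    write_model,
)
from issf.sbml_io import ISSF_FUNCTION_ID


@pytest.fixture
def ld12(ld_params):
    return ld_params


class TestLoadModel:
    def test_fixture_round_trip(self, goodwin, tmp_path):
        path = tmp_path / "goodwin.xml"
        write_model(goodwin, path)
        handle = load_model(path)
        assert "L" in handle.parameter_index
        assert handle.level == 3 and handle.version == 1

    def test_missing_file(self, tmp_path):
        with pytest.raises(SBMLIOError, match="no such file"):
            load_model(tmp_path / "absent.xml")

    def test_malformed_xml_names_parse_failure(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml><model <<< broken")
        with pytest.raises(SBMLIOError, match="parse"):
            load_model(bad)

    def test_model_without_parameters_rejected(self):
        doc = libsbml.SBMLDocument(3, 1)
        model = doc.createModel()
        c = model.createCompartment()
        c.setId("c")
        c.setSize(1.0)
        c.setConstant(True)
        xml = libsbml.writeSBMLToString(doc)
        with pytest.raises(SBMLIOError, match="no global parameters"):
            load_model_from_string(xml)


class TestControllableParameters:
    def test_fixture_light_parameter_listed(self, goodwin):
        assert "L" in list_controllable_parameters(goodwin)

    def test_all_parameters_ruled_gives_empty_list(self, accumulator, ld12):
        inject_issf(accumulator, SignalAssignment("L", ld12))
        assert list_controllable_parameters(accumulator) == []

    def test_injection_removes_target_from_list(self, ld12):
        handle = make_accumulator_model()
        assert "L" in list_controllable_parameters(handle)
        inject_issf(handle, SignalAssignment("L", ld12))
        assert "L" not in list_controllable_parameters(handle)


class TestInjection:
    def test_adds_exactly_one_funcdef_and_one_rule(self, accumulator, ld12):
        model = accumulator.model
        n_fd, n_rules = model.getNumFunctionDefinitions(), \
            model.getNumRules()
        inject_issf(accumulator, SignalAssignment("L", ld12))
        assert model.getNumFunctionDefinitions() == n_fd + 1
        assert model.getNumRules() == n_rules + 1
        assert model.getRule("L").isAssignment()
        assert model.getParameter("L").getConstant() is False

    def test_funcdef_carries_sbo_475(self, accumulator, ld12):
        inject_issf(accumulator, SignalAssignment("L", ld12))
        fd = accumulator.model.getFunctionDefinition(ISSF_FUNCTION_ID)
        assert fd.getSBOTerm() == 475
        assert 'sboTerm="SBO:0000475"' in model_to_string(accumulator)

    def test_missing_target_errors(self, accumulator, ld12):
        with pytest.raises(InjectionError, match="no parameter 'nope'"):
            inject_issf(accumulator, SignalAssignment("nope", ld12))

    def test_reinjection_errors_without_replace(self, accumulator, ld12):
        inject_issf(accumulator, SignalAssignment("L", ld12))
        with pytest.raises(InjectionError, match="already governed"):
            inject_issf(accumulator, SignalAssignment("L", ld12))

    def test_replace_swaps_rule_without_stacking(self, accumulator, ld12):
        inject_issf(accumulator, SignalAssignment("L", ld12))
        n_rules = accumulator.model.getNumRules()
        inject_issf(accumulator,
                    SignalAssignment("L", ld12.replace(offset=5.0)),
                    replace=True)
        assert accumulator.model.getNumRules() == n_rules

    def test_rate_ruled_target_never_replaced(self, accumulator, ld12):
        # 'x' carries the fixture's rate rule; replace must not touch it
        with pytest.raises(InjectionError):
            inject_issf(accumulator, SignalAssignment("x", ld12),
                        replace=True)

    def test_local_parameter_requires_promotion_flag(self, ld12):
        doc = libsbml.SBMLDocument(3, 1)
        model = doc.createModel()
        c = model.createCompartment()
        c.setId("cell"); c.setSize(1.0); c.setConstant(True)
        s = model.createSpecies()
        s.setId("A"); s.setCompartment("cell")
        s.setInitialConcentration(1.0); s.setConstant(False)
        s.setBoundaryCondition(False); s.setHasOnlySubstanceUnits(False)
        p = model.createParameter()
        p.setId("unrelated"); p.setValue(1.0); p.setConstant(True)
        rxn = model.createReaction()
        rxn.setId("decay"); rxn.setReversible(False); rxn.setFast(False)
        ref = rxn.createReactant()
        ref.setSpecies("A"); ref.setStoichiometry(1.0); ref.setConstant(True)
        kl = rxn.createKineticLaw()
        lp = kl.createParameter()
        lp.setId("kloc"); lp.setValue(0.1)
        kl.setMath(libsbml.parseL3Formula("kloc * A * cell"))
        handle = load_model_from_string(libsbml.writeSBMLToString(doc))
        with pytest.raises(InjectionError, match="promote_local"):
            inject_issf(handle, SignalAssignment("kloc", ld12))
        inject_issf(handle, SignalAssignment("kloc", ld12),
                    promote_local=True)
        ruled = [v for v, i in handle.parameter_index.items()
                 if i.rule == "assignment"]
        assert len(ruled) == 1 and ruled[0].endswith("kloc")

    def test_injection_touches_nothing_else(self, ld12):
        handle = make_accumulator_model()
        before = libsbml.readSBMLFromString(model_to_string(handle))
        inject_issf(handle, SignalAssignment("L", ld12))
        after = handle.model
        bm = before.getModel()
        # untouched collections are serialized identically
        for getter in ("getListOfCompartments", "getListOfSpecies"):
            assert getattr(bm, getter)().toSBML() == \
                getattr(after, getter)().toSBML()
        # the x rate rule survives verbatim
        assert bm.getRule("x").toSBML() == after.getRule("x").toSBML()
        # only documented changes: +1 funcdef, +1 rule, constant flag
        assert after.getNumFunctionDefinitions() == \
            bm.getNumFunctionDefinitions() + 1
        assert after.getNumRules() == bm.getNumRules() + 1
        assert after.getNumParameters() == bm.getNumParameters()

    def test_injected_document_passes_validation(self, accumulator, ld12):
        inject_issf(accumulator, SignalAssignment("L", ld12))
        doc = libsbml.readSBMLFromString(model_to_string(accumulator))
        doc.setConsistencyChecks(libsbml.LIBSBML_CAT_UNITS_CONSISTENCY,
                                 False)
        doc.checkConsistency()
        errors = [doc.getError(i) for i in range(doc.getNumErrors())]
        assert not [e for e in errors
                    if e.getSeverity() >= libsbml.LIBSBML_SEV_ERROR]


class TestWriteModel:
    def test_round_trip_preserves_parameter_index(self, goodwin, tmp_path):
        path = tmp_path / "m.xml"
        write_model(goodwin, path)
        reloaded = load_model(path)
        assert reloaded.parameter_index == goodwin.parameter_index

    def test_injected_model_round_trips(self, ld12, tmp_path):
        handle = make_accumulator_model()
        inject_issf(handle, SignalAssignment("L", ld12))
        path = tmp_path / "inj.xml"
        write_model(handle, path)
        reloaded = load_model(path)
        assert reloaded.parameter_index == handle.parameter_index
        fd = reloaded.model.getFunctionDefinition(ISSF_FUNCTION_ID)
        assert fd is not None and fd.getSBOTerm() == 475
        assert reloaded.model.getRule("L").isAssignment()

    def test_unwritable_path_errors(self, goodwin):
        with pytest.raises(SBMLIOError, match="could not write"):
            write_model(goodwin, "/no/such/directory/model.xml")


class TestSimulatorEquivalence:
    """The central MathML-encoding correctness property: the injected
    rule's trajectory must match direct Python evaluation of the same
    signal."""

    SETTINGS = IntegratorSettings(max_step=0.05)

    def _check(self, signal, t_end=48.0):
        handle = make_accumulator_model()
        inject_issf(handle, SignalAssignment("L", signal))
        ts = simulate(handle, t_end=t_end, output_step=0.1,
                      settings=self.SETTINGS)
        if isinstance(signal, (ISSFParams, SignalSchedule)):
            signal = CompositeSignal([signal])
        direct = eval_composite(signal, ts.times)
        assert np.max(np.abs(ts["L"] - direct)) <= 1e-6

    def test_single_signal(self, fig1_bottom):
        self._check(fig1_bottom)

    def test_zero_ramp_square_wave(self):
        self._check(ISSFParams(offset=1, amplitude=2, pulse_duration=6,
                               cycle_period=24, ramp_duration=0.0))

    def test_negative_phase(self):
        self._check(ISSFParams(offset=6.5, amplitude=1.5, pulse_duration=3,
                               cycle_period=24, ramp_duration=0.1, phase=-3))

    def test_schedule_nested_piecewise(self, ld_then_dd):
        self._check(ld_then_dd, t_end=300.0)

    def test_sum_composite(self, ld_params):
        pulse = ISSFParams(offset=0, amplitude=0.4, pulse_duration=1,
                           cycle_period=360, ramp_duration=0.1, phase=-40)
        self._check(CompositeSignal([ld_params, pulse]), t_end=72.0)

    def test_product_composite(self, ld_params):
        gate = ISSFParams(offset=0, amplitude=1, pulse_duration=12,
                          cycle_period=24, ramp_duration=0.0, phase=6)
        self._check(CompositeSignal([ld_params, gate],
                                    combiner=Combiner.PRODUCT), t_end=48.0)

    def test_max_composite(self, ld_params):
        floor_sig = ISSFParams(offset=1.8, amplitude=0, pulse_duration=1,
                               cycle_period=24)
        self._check(CompositeSignal([ld_params, floor_sig],
                                    combiner=Combiner.MAX), t_end=48.0)
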