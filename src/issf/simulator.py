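"""Deterministic ODE simulation of SBML models via scipy.

Compiles the SBML math (reactions, rate rules, assignment rules, function
definitions) into plain Python expressions and integrates with a
stiff-capable ``solve_ivp`` method.  Supports the MathML subset relevant
here: arithmetic, relational and boolean operators, ``piecewise``,
``floor``/``ceil``/``abs``, exp/log/power/root, trigonometry, and the time
csymbol.  Function definitions are inlined at compile time, so assignment
rules that call the injected step function cost one closed-form expression
per evaluation — no events, no solver restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import libsbml
import numpy as np
from scipy.integrate import solve_ivp

from .sbml_io import ModelHandle

__all__ = ["IntegratorSettings", "SimulationError", "CompiledModel",
           "compile_model", "simulate_model"]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class IntegratorSettings:
    """Solver configuration. ``max_step`` must not exceed half the
    shortest ramp of any injected signal, so ramps are never stepped
    over; ``None`` leaves the solver unconstrained."""

    rtol: float = 1e-7
    atol: float = 1e-9
    max_step: Optional[float] = None
    method: str = "LSODA"


_BINARY_OPS = {
    libsbml.AST_PLUS: "+",
    libsbml.AST_MINUS: "-",
    libsbml.AST_TIMES: "*",
    libsbml.AST_DIVIDE: "/",
}

_RELATIONAL = {
    libsbml.AST_RELATIONAL_LT: "<",
    libsbml.AST_RELATIONAL_LEQ: "<=",
    libsbml.AST_RELATIONAL_GT: ">",
    libsbml.AST_RELATIONAL_GEQ: ">=",
    libsbml.AST_RELATIONAL_EQ: "==",
    libsbml.AST_RELATIONAL_NEQ: "!=",
}

_UNARY_FUNCS = {
    libsbml.AST_FUNCTION_EXP: "exp",
    libsbml.AST_FUNCTION_LN: "log",
    libsbml.AST_FUNCTION_ABS: "abs",
    libsbml.AST_FUNCTION_FLOOR: "floor",
    libsbml.AST_FUNCTION_CEILING: "ceil",
    libsbml.AST_FUNCTION_SIN: "sin",
    libsbml.AST_FUNCTION_COS: "cos",
    libsbml.AST_FUNCTION_TAN: "tan",
    libsbml.AST_FUNCTION_ARCSIN: "asin",
    libsbml.AST_FUNCTION_ARCCOS: "acos",
    libsbml.AST_FUNCTION_ARCTAN: "atan",
    libsbml.AST_FUNCTION_SINH: "sinh",
    libsbml.AST_FUNCTION_COSH: "cosh",
    libsbml.AST_FUNCTION_TANH: "tanh",
}

_MATH_NAMESPACE = {
    "exp": math.exp, "log": math.log, "abs": abs, "floor": math.floor,
    "ceil": math.ceil, "sin": math.sin, "cos": math.cos, "tan": math.tan,
    "asin": math.asin, "acos": math.acos, "atan": math.atan,
    "sinh": math.sinh, "cosh": math.cosh, "tanh": math.tanh,
    "sqrt": math.sqrt, "pi": math.pi, "e": math.e, "nan": math.nan,
    "inf": math.inf,
}


def _ast_to_python(node: libsbml.ASTNode,
                   rename: dict[str, str],
                   funcdefs: dict[str, libsbml.ASTNode]) -> str:
    """Recursively convert a libsbml AST into a Python expression string.

    ``rename`` maps SBML identifiers to Python expressions (state slots,
    numeric literals for local parameters, or lambda argument bindings).
    Calls to model function definitions are inlined with their arguments
    substituted textually.
    """
    t = node.getType()
    if t == libsbml.AST_INTEGER:
        return repr(float(node.getInteger()))
    if t in (libsbml.AST_REAL, libsbml.AST_REAL_E):
        return repr(node.getReal())
    if t == libsbml.AST_RATIONAL:
        return f"({node.getNumerator()}/{node.getDenominator()})"
    if t == libsbml.AST_NAME_TIME:
        return "t"
    if t == libsbml.AST_CONSTANT_PI:
        return "pi"
    if t == libsbml.AST_CONSTANT_E:
        return "e"
    if t == libsbml.AST_CONSTANT_TRUE:
        return "True"
    if t == libsbml.AST_CONSTANT_FALSE:
        return "False"
    if t == libsbml.AST_NAME:
        name = node.getName()
        if name in rename:
            return rename[name]
        raise SimulationError(f"unresolved symbol {name!r} in model math")

    kids = [_ast_to_python(node.getChild(i), rename, funcdefs)
            for i in range(node.getNumChildren())]

    if t in _BINARY_OPS:
        op = _BINARY_OPS[t]
        if t == libsbml.AST_MINUS and len(kids) == 1:
            return f"(-{kids[0]})"
        if t == libsbml.AST_PLUS and not kids:
            return "0.0"
        if t == libsbml.AST_TIMES and not kids:
            return "1.0"
        return "(" + f" {op} ".join(kids) + ")"
    if t == libsbml.AST_POWER or t == libsbml.AST_FUNCTION_POWER:
        return f"({kids[0]} ** {kids[1]})"
    if t == libsbml.AST_FUNCTION_ROOT:
        if len(kids) == 1:
            return f"sqrt({kids[0]})"
        return f"({kids[1]} ** (1.0 / {kids[0]}))"
    if t == libsbml.AST_FUNCTION_LOG:
        if len(kids) == 1:
            return f"(log({kids[0]}) / log(10.0))"
        return f"(log({kids[1]}) / log({kids[0]}))"
    if t in _UNARY_FUNCS:
        return f"{_UNARY_FUNCS[t]}({kids[0]})"
    if t in _RELATIONAL:
        return "(" + f" {_RELATIONAL[t]} ".join(kids) + ")"
    if t == libsbml.AST_LOGICAL_AND:
        return "(" + " and ".join(kids) + ")"
    if t == libsbml.AST_LOGICAL_OR:
        return "(" + " or ".join(kids) + ")"
    if t == libsbml.AST_LOGICAL_NOT:
        return f"(not {kids[0]})"
    if t == libsbml.AST_FUNCTION_PIECEWISE:
        # (v1, c1, v2, c2, ..., [otherwise]) -> lazy chained conditionals,
        # so untaken branches (e.g. a ramp division with tR = 0) are never
        # evaluated.
        otherwise = kids[-1] if len(kids) % 2 == 1 else "nan"
        expr = otherwise
        pairs = list(zip(kids[0:-1:2], kids[1::2]))
        for value, cond in reversed(pairs):
            expr = f"(({value}) if ({cond}) else ({expr}))"
        return expr
    if t == libsbml.AST_FUNCTION:
        fname = node.getName()
        if fname not in funcdefs:
            raise SimulationError(f"call to unknown function {fname!r}")
        lam = funcdefs[fname]
        nargs = lam.getNumChildren() - 1
        if nargs != len(kids):
            raise SimulationError(
                f"{fname!r} called with {len(kids)} args, expects {nargs}")
        bindings = dict(rename)
        for i in range(nargs):
            bindings[lam.getChild(i).getName()] = f"({kids[i]})"
        return _ast_to_python(lam.getChild(nargs), bindings, funcdefs)
    raise SimulationError(
        f"unsupported MathML construct: {libsbml.formulaToL3String(node)!r} "
        f"(AST type {t})")


@dataclass
class CompiledModel:
    state_ids: list[str]
    y0: np.ndarray
    rhs: Callable
    assigned_ids: list[str]
    assigned_fn: Callable  # (t, y) -> list of assigned values


def compile_model(handle_or_model: Union[ModelHandle, libsbml.Model],
                  ) -> CompiledModel:
    """Compile an SBML model into an ODE right-hand side.

    The state vector holds every non-boundary species that participates in
    a reaction or rate rule, plus every rate-ruled parameter.  Assignment
    rules are evaluated (in dependency order) on each call.
    """
    if isinstance(handle_or_model, ModelHandle):
        model = handle_or_model.model
    else:
        model = handle_or_model

    funcdefs: dict[str, libsbml.ASTNode] = {}
    for i in range(model.getNumFunctionDefinitions()):
        fd = model.getFunctionDefinition(i)
        funcdefs[fd.getId()] = fd.getMath()

    compartments: dict[str, float] = {}
    for i in range(model.getNumCompartments()):
        c = model.getCompartment(i)
        compartments[c.getId()] = c.getSize() if c.isSetSize() else 1.0

    species_info = {}
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        size = compartments.get(s.getCompartment(), 1.0)
        if s.isSetInitialConcentration():
            value = s.getInitialConcentration()
        elif s.isSetInitialAmount():
            value = s.getInitialAmount() / size
        else:
            value = 0.0
        species_info[s.getId()] = {
            "value": value, "size": size,
            "boundary": bool(s.getBoundaryCondition()),
        }

    param_values = {}
    for i in range(model.getNumParameters()):
        p = model.getParameter(i)
        param_values[p.getId()] = p.getValue() if p.isSetValue() else 0.0

    assignment_rules: dict[str, libsbml.ASTNode] = {}
    rate_rules: dict[str, libsbml.ASTNode] = {}
    for i in range(model.getNumRules()):
        rule = model.getRule(i)
        if rule.isAssignment():
            assignment_rules[rule.getVariable()] = rule.getMath()
        elif rule.isRate():
            rate_rules[rule.getVariable()] = rule.getMath()
        else:
            raise SimulationError("algebraic rules are not supported")
    if model.getNumEvents():
        raise SimulationError("events are not supported")

    # Net stoichiometry per (species, reaction).
    reaction_fluxes: list[tuple[str, libsbml.ASTNode, dict[str, str]]] = []
    net_stoich: dict[str, list[tuple[int, float]]] = {}
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        kl = rxn.getKineticLaw()
        if kl is None:
            raise SimulationError(
                f"reaction {rxn.getId()!r} has no kinetic law")
        local = {}
        for j in range(kl.getNumParameters()):
            lp = kl.getParameter(j)
            local[lp.getId()] = repr(lp.getValue())
        reaction_fluxes.append((rxn.getId(), kl.getMath(), local))
        for ref, sign in [(rxn.getReactant(j), -1.0)
                          for j in range(rxn.getNumReactants())] + \
                         [(rxn.getProduct(j), +1.0)
                          for j in range(rxn.getNumProducts())]:
            sto = ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0
            net_stoich.setdefault(ref.getSpecies(), []).append((i, sign * sto))

    state_ids: list[str] = []
    for sid, info in species_info.items():
        dynamic = (not info["boundary"]) and (
            sid in rate_rules or sid in net_stoich)
        if dynamic and sid not in assignment_rules:
            state_ids.append(sid)
    for pid in rate_rules:
        if pid in param_values and pid not in state_ids:
            state_ids.append(pid)

    rename: dict[str, str] = {}
    for k, (cid, size) in enumerate(compartments.items()):
        rename[cid] = repr(size)
    for idx, sid in enumerate(state_ids):
        rename[sid] = f"y[{idx}]"
    for pid, value in param_values.items():
        if pid not in rename and pid not in assignment_rules:
            rename[pid] = repr(value)
    for sid, info in species_info.items():
        if sid not in rename and sid not in assignment_rules:
            rename[sid] = repr(info["value"])

    # Assignment rules in dependency order (rules may reference each other).
    def _symbols(node, acc):
        if node.getType() == libsbml.AST_NAME:
            acc.add(node.getName())
        for i in range(node.getNumChildren()):
            _symbols(node.getChild(i), acc)
        return acc

    remaining = dict(assignment_rules)
    ordered: list[str] = []
    while remaining:
        progressed = False
        for var, node in list(remaining.items()):
            deps = _symbols(node, set())
            if not (deps & set(remaining) - {var}):
                ordered.append(var)
                del remaining[var]
                progressed = True
        if not progressed:
            raise SimulationError(
                f"cyclic assignment rules: {sorted(remaining)}")

    lines = ["def _rhs(t, y):"]
    assigned_exprs: list[str] = []
    for var in ordered:
        expr = _ast_to_python(assignment_rules[var], rename, funcdefs)
        pyname = f"_a_{var}"
        rename[var] = pyname
        assigned_exprs.append(expr)
        lines.append(f"    {pyname} = {expr}")
    for k, (rid, node, local) in enumerate(reaction_fluxes):
        local_rename = dict(rename)
        local_rename.update(local)
        expr = _ast_to_python(node, local_rename, funcdefs)
        lines.append(f"    _flux_{k} = {expr}")
    lines.append("    out = [0.0] * %d" % len(state_ids))
    for idx, sid in enumerate(state_ids):
        if sid in rate_rules:
            expr = _ast_to_python(rate_rules[sid], rename, funcdefs)
            lines.append(f"    out[{idx}] = {expr}")
        elif sid in net_stoich:
            size = species_info[sid]["size"]
            terms = " + ".join(f"{coef!r} * _flux_{ridx}"
                               for ridx, coef in net_stoich[sid])
            lines.append(f"    out[{idx}] = ({terms}) / {size!r}")
    lines.append("    return out")
    assigned_ids = list(ordered)
    lines.append("def _assigned(t, y):")
    if assigned_ids:
        for var, expr in zip(assigned_ids, assigned_exprs):
            lines.append(f"    _a_{var} = {expr}")
        lines.append("    return [" +
                     ", ".join(f"_a_{v}" for v in assigned_ids) + "]")
    else:
        lines.append("    return []")

    namespace = dict(_MATH_NAMESPACE)
    exec(compile("\n".join(lines), "<sbml-model>", "exec"), namespace)

    y0 = np.array([
        species_info[sid]["value"] if sid in species_info
        else param_values[sid]
        for sid in state_ids
    ], dtype=float)

    return CompiledModel(
        state_ids=state_ids, y0=y0,
        rhs=namespace["_rhs"],
        assigned_ids=assigned_ids,
        assigned_fn=namespace["_assigned"],
    )


def simulate_model(handle_or_model, t_end: float, output_step: float,
                   settings: IntegratorSettings = IntegratorSettings(),
                   t_start: float = 0.0):
    """Integrate the model and return ``(times, columns)``.

    Columns cover every dynamic species/parameter plus every
    assignment-ruled variable, in declaration order.
    """
    if t_end <= t_start:
        raise SimulationError(f"t_end={t_end} must exceed t_start={t_start}")
    compiled = compile_model(handle_or_model)
    n = int(round((t_end - t_start) / output_step))
    t_eval = t_start + output_step * np.arange(n + 1)
    t_eval = t_eval[t_eval <= t_end + 1e-12]
    kwargs = dict(rtol=settings.rtol, atol=settings.atol,
                  method=settings.method)
    if settings.max_step is not None:
        kwargs["max_step"] = settings.max_step
    sol = solve_ivp(compiled.rhs, (t_start, t_end), compiled.y0,
                    t_eval=t_eval, **kwargs)
    if not sol.success:
        raise SimulationError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else t_start}:"
            f" {sol.message}")
    columns = {sid: sol.y[i] for i, sid in enumerate(compiled.state_ids)}
    if compiled.assigned_ids:
        assigned = np.array([compiled.assigned_fn(t, sol.y[:, j])
                             for j, t in enumerate(sol.t)], dtype=float)
        for i, aid in enumerate(compiled.assigned_ids):
            columns[aid] = assigned[:, i]
    return sol.t, columns
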