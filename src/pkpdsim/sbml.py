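"""SBML-defined PK models: a restricted reader, stepper and fixture writer.

When the built-in one-/two-compartment models are inadequate, the systemic PK
of a substrate can be supplied as an SBML file.  The supported subset is
deliberately small and is validated at load time with explicit errors:

* compartments and species (concentrations),
* constant global parameters,
* rate rules and reactions (kinetic laws restricted to arithmetic MathML),
* events with time-based triggers (``time >= t0``) performing assignments —
  this is how dosing is expressed, e.g. ``circulation_concentration + 10``.

Algebraic rules, assignment rules, function definitions, event delays and
other constructs outside this subset raise :class:`UnsupportedSBMLError`
naming the construct.

The circulation readout — the value that drives the Dirichlet boundary — is
the species named ``circulation_concentration`` when present, otherwise the
first listed species.

Between events the ODE system is integrated with an adaptive high-accuracy
integrator; integration is split exactly at each trigger time, and an event
falling exactly on a step boundary is applied before the ODE step of the
following interval.  File time units are converted to minutes when declared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from lxml import etree
from scipy.integrate import solve_ivp

__all__ = [
    "SBMLError",
    "UnsupportedSBMLError",
    "SBMLEvent",
    "SBMLPKModel",
    "load_sbml_pk",
    "step_sbml_pk",
    "write_linear_pk_sbml",
]

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"
CIRCULATION_SPECIES = "circulation_concentration"

_TIME_UNIT_TO_MIN = {
    "second": 1.0 / 60.0,
    "minute": 1.0,
    "hour": 60.0,
    "day": 1440.0,
    "dimensionless": 1.0,
}


class SBMLError(ValueError):
    """The file is not usable as a PK model."""


class UnsupportedSBMLError(SBMLError):
    """The file uses an SBML construct outside the supported subset."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


# --------------------------------------------------------------------- MathML

_BINARY_OPS = {
    "plus": lambda args: sum(args),
    "times": lambda args: math.prod(args),
    "minus": lambda args: -args[0] if len(args) == 1 else args[0] - args[1],
    "divide": lambda args: args[0] / args[1],
    "power": lambda args: args[0] ** args[1],
}
_RELATIONAL = ("geq", "gt", "leq", "lt", "eq")


def _parse_mathml(node) -> tuple:
    """Parse a MathML element into a small tuple AST.

    Supported: <cn>, <ci>, <csymbol time>, <apply> with plus/minus/times/
    divide/power and (for triggers) geq/gt/leq/lt.
    """
    tag = _local(node.tag)
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise UnsupportedSBMLError("math element must contain one expression")
        return _parse_mathml(children[0])
    if tag == "cn":
        kind = node.get("type", "real")
        if kind in ("real", "integer", "double"):
            return ("num", float(node.text))
        if kind == "e-notation":
            parts = [t.strip() for t in node.itertext() if t.strip()]
            return ("num", float(parts[0]) * 10.0 ** float(parts[1]))
        raise UnsupportedSBMLError(f"cn type {kind!r}")
    if tag == "ci":
        return ("sym", node.text.strip())
    if tag == "csymbol":
        if node.get("definitionURL") == TIME_URL:
            return ("time",)
        raise UnsupportedSBMLError(f"csymbol {node.get('definitionURL')!r}")
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = _local(children[0].tag)
        args = tuple(_parse_mathml(c) for c in children[1:])
        if op in _BINARY_OPS or op in _RELATIONAL:
            return ("op", op, args)
        raise UnsupportedSBMLError(f"MathML operator {op!r}")
    raise UnsupportedSBMLError(f"MathML element {tag!r}")


def _eval_ast(ast: tuple, env: Dict[str, float]) -> float:
    kind = ast[0]
    if kind == "num":
        return ast[1]
    if kind == "sym":
        try:
            return env[ast[1]]
        except KeyError:
            raise SBMLError(f"unknown identifier {ast[1]!r} in math expression")
    if kind == "time":
        return env["__time__"]
    op, args = ast[1], [_eval_ast(a, env) for a in ast[2]]
    return _BINARY_OPS[op](args)


def _trigger_time(ast: tuple) -> float:
    """Extract t0 from a trigger of the form time >= t0 (or t0 <= time)."""
    if ast[0] != "op" or ast[1] not in _RELATIONAL:
        raise UnsupportedSBMLError("event trigger must be a relational expression")
    op, args = ast[1], ast[2]
    if len(args) != 2:
        raise UnsupportedSBMLError("event trigger must compare two quantities")
    a, b = args
    if a[0] == "time" and b[0] == "num" and op in ("geq", "gt"):
        return b[1]
    if a[0] == "num" and b[0] == "time" and op in ("leq", "lt"):
        return a[1]
    raise UnsupportedSBMLError(
        "event trigger must be time-based (time >= constant)"
    )


# ---------------------------------------------------------------------- model


@dataclass
class SBMLEvent:
    """A time-triggered event: at ``time`` apply the listed assignments."""

    time: float
    assignments: List[Tuple[str, tuple]]  # (species/parameter id, math AST)
    fired: bool = False


@dataclass
class _Reaction:
    kinetic: tuple
    # (species id, signed stoichiometry / compartment size)
    changes: List[Tuple[str, float]]
    local_params: Dict[str, float]


class SBMLPKModel:
    """An ODE system parsed from SBML, advanced between time-based events."""

    def __init__(
        self,
        species_ids: Sequence[str],
        initial: Sequence[float],
        parameters: Dict[str, float],
        rate_rules: Dict[str, tuple],
        reactions: List[_Reaction],
        events: List[SBMLEvent],
        circulation_index: int,
        constant_species: Sequence[bool],
        time_scale: float = 1.0,
        rtol: float = 1e-10,
        atol: float = 1e-12,
    ):
        self.species_ids = list(species_ids)
        self.y = np.asarray(initial, dtype=float)
        self.parameters = dict(parameters)
        self.rate_rules = rate_rules
        self.reactions = reactions
        self.events = sorted(events, key=lambda e: e.time)
        self.circulation_index = circulation_index
        self.constant_species = np.asarray(constant_species, dtype=bool)
        self.time_scale = time_scale  # file time unit -> minutes
        self.time = 0.0  # minutes
        self.rtol = rtol
        self.atol = atol

    @property
    def circulation(self) -> float:
        return float(self.y[self.circulation_index])

    def _env(self, t_file: float) -> Dict[str, float]:
        env = dict(self.parameters)
        env.update(zip(self.species_ids, self.y))
        env["__time__"] = t_file
        return env

    def _rhs(self, t_file: float, y: np.ndarray) -> np.ndarray:
        env = dict(self.parameters)
        env.update(zip(self.species_ids, y))
        env["__time__"] = t_file
        dydt = np.zeros_like(y)
        for sid, ast in self.rate_rules.items():
            dydt[self.species_ids.index(sid)] = _eval_ast(ast, env)
        for rxn in self.reactions:
            renv = env if not rxn.local_params else {**env, **rxn.local_params}
            rate = _eval_ast(rxn.kinetic, renv)
            for sid, coeff in rxn.changes:
                dydt[self.species_ids.index(sid)] += coeff * rate
        dydt[self.constant_species] = 0.0
        return dydt

    def _fire_due_events(self) -> None:
        t_file = self.time / self.time_scale
        for ev in self.events:
            if not ev.fired and ev.time <= t_file + 1e-12:
                env = self._env(ev.time)
                for sid, ast in ev.assignments:
                    value = _eval_ast(ast, env)
                    if sid in self.parameters:
                        self.parameters[sid] = value
                    else:
                        self.y[self.species_ids.index(sid)] = value
                ev.fired = True

    def step(self, dt: float) -> None:
        """Advance by ``dt`` minutes, splitting integration at event times.

        Events due at the current time (including exactly at a step boundary)
        are applied before integrating, so a bolus at t0 shapes the interval
        [t0, t0+dt).  Events strictly inside the interval are applied at
        their exact trigger times.
        """
        if not (dt > 0.0):
            raise ValueError(f"dt must be > 0, got {dt}")
        self.advance_to(self.time + dt)

    def advance_to(self, t_target: float) -> None:
        """Advance to the absolute time ``t_target`` (minutes).

        Preferred in stepped loops: the caller keeps an exact clock (e.g.
        ``i * dt``), so boundary-event bookkeeping cannot drift with
        accumulated floating-point step sums.
        """
        if t_target < self.time:
            raise ValueError(f"cannot integrate backwards to {t_target} from {self.time}")
        self._fire_due_events()
        while True:
            t_file = self.time / self.time_scale
            t_target_file = t_target / self.time_scale
            pending = [
                e.time
                for e in self.events
                if not e.fired and t_file < e.time < t_target_file - 1e-12
            ]
            t_stop_file = min(pending) if pending else t_target_file
            if t_stop_file > t_file and (self.rate_rules or self.reactions):
                sol = solve_ivp(
                    self._rhs,
                    (t_file, t_stop_file),
                    self.y,
                    method="LSODA",
                    rtol=self.rtol,
                    atol=self.atol,
                )
                if not sol.success:
                    raise SBMLError(f"SBML ODE integration failed: {sol.message}")
                self.y = sol.y[:, -1]
            self.time = t_stop_file * self.time_scale
            if t_stop_file >= t_target_file:
                # events landing exactly on the boundary wait for the next
                # interval (doses at a step boundary precede that interval)
                break
            self._fire_due_events()
        self.time = t_target


def step_sbml_pk(model: SBMLPKModel, dt: float) -> SBMLPKModel:
    """Advance ``model`` in place by ``dt`` minutes (returned for chaining)."""
    model.step(dt)
    return model


# --------------------------------------------------------------------- loader


def _resolve_time_scale(model_el) -> float:
    unit = model_el.get("timeUnits")
    if unit is None:
        return 1.0  # assume minutes
    if unit in _TIME_UNIT_TO_MIN:
        return _TIME_UNIT_TO_MIN[unit]
    for ud in model_el.findall("{*}listOfUnitDefinitions/{*}unitDefinition"):
        if ud.get("id") != unit:
            continue
        units = ud.findall("{*}listOfUnits/{*}unit")
        if len(units) == 1 and units[0].get("kind") == "second":
            mult = float(units[0].get("multiplier", "1"))
            scale = 10.0 ** float(units[0].get("scale", "0"))
            return mult * scale / 60.0
    raise UnsupportedSBMLError(f"time unit {unit!r}")


def load_sbml_pk(path: str) -> SBMLPKModel:
    """Parse an SBML file (restricted subset) into an :class:`SBMLPKModel`."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLError("not an SBML document (root element is not <sbml>)")
    model_el = root.find("{*}model")
    if model_el is None:
        raise SBMLError("SBML document has no <model>")

    for construct in ("listOfFunctionDefinitions", "listOfConstraints"):
        el = model_el.find("{*}" + construct)
        if el is not None and len(el):
            raise UnsupportedSBMLError(construct)
    rules_el = model_el.find("{*}listOfRules")
    if rules_el is not None:
        for rule in rules_el:
            if not isinstance(rule.tag, str):
                continue
            if _local(rule.tag) != "rateRule":
                raise UnsupportedSBMLError(_local(rule.tag))

    compartments = {
        c.get("id"): float(c.get("size", "1"))
        for c in model_el.findall("{*}listOfCompartments/{*}compartment")
    }

    species_ids: List[str] = []
    initial: List[float] = []
    constant: List[bool] = []
    species_comp_size: Dict[str, float] = {}
    for sp in model_el.findall("{*}listOfSpecies/{*}species"):
        sid = sp.get("id")
        size = compartments.get(sp.get("compartment"), 1.0)
        species_comp_size[sid] = size
        if sp.get("initialConcentration") is not None:
            value = float(sp.get("initialConcentration"))
        elif sp.get("initialAmount") is not None:
            value = float(sp.get("initialAmount")) / size
        else:
            value = 0.0
        species_ids.append(sid)
        initial.append(value)
        constant.append(
            sp.get("constant") == "true" or sp.get("boundaryCondition") == "true"
        )
    if not species_ids:
        raise SBMLError("SBML model declares no species")

    parameters = {
        p.get("id"): float(p.get("value", "0"))
        for p in model_el.findall("{*}listOfParameters/{*}parameter")
    }

    rate_rules: Dict[str, tuple] = {}
    for rule in model_el.findall("{*}listOfRules/{*}rateRule"):
        math_el = rule.find(f"{{{MATHML_NS}}}math")
        if math_el is None:
            raise SBMLError("rateRule without <math>")
        rate_rules[rule.get("variable")] = _parse_mathml(math_el)

    reactions: List[_Reaction] = []
    for rxn in model_el.findall("{*}listOfReactions/{*}reaction"):
        kl = rxn.find("{*}kineticLaw")
        if kl is None:
            raise UnsupportedSBMLError("reaction without kineticLaw")
        math_el = kl.find(f"{{{MATHML_NS}}}math")
        if math_el is None:
            raise SBMLError("kineticLaw without <math>")
        local = {
            p.get("id"): float(p.get("value", "0"))
            for lst in ("listOfLocalParameters", "listOfParameters")
            for p in kl.findall("{*}" + lst + "/{*}localParameter")
            + kl.findall("{*}" + lst + "/{*}parameter")
        }
        changes: List[Tuple[str, float]] = []
        for lst, sign in (("listOfReactants", -1.0), ("listOfProducts", 1.0)):
            for ref in rxn.findall("{*}" + lst + "/{*}speciesReference"):
                sid = ref.get("species")
                if sid not in species_ids:
                    raise SBMLError(f"reaction references unknown species {sid!r}")
                stoich = float(ref.get("stoichiometry", "1"))
                changes.append((sid, sign * stoich / species_comp_size[sid]))
        reactions.append(_Reaction(_parse_mathml(math_el), changes, local))

    events: List[SBMLEvent] = []
    for ev in model_el.findall("{*}listOfEvents/{*}event"):
        if ev.find("{*}delay") is not None:
            raise UnsupportedSBMLError("event delay")
        trig = ev.find("{*}trigger")
        if trig is None:
            raise UnsupportedSBMLError("event without trigger")
        math_el = trig.find(f"{{{MATHML_NS}}}math")
        t0 = _trigger_time(_parse_mathml(math_el))
        assignments: List[Tuple[str, tuple]] = []
        for ea in ev.findall("{*}listOfEventAssignments/{*}eventAssignment"):
            am = ea.find(f"{{{MATHML_NS}}}math")
            assignments.append((ea.get("variable"), _parse_mathml(am)))
        events.append(SBMLEvent(time=t0, assignments=assignments))
    times = sorted(e.time for e in events)
    if any(b - a <= 0 for a, b in zip(times, times[1:])):
        raise SBMLError("event trigger times must be distinct")

    if CIRCULATION_SPECIES in species_ids:
        circ = species_ids.index(CIRCULATION_SPECIES)
    else:
        circ = 0  # fall back to the first listed state variable
    return SBMLPKModel(
        species_ids=species_ids,
        initial=initial,
        parameters=parameters,
        rate_rules=rate_rules,
        reactions=reactions,
        events=events,
        circulation_index=circ,
        constant_species=constant,
        time_scale=_resolve_time_scale(model_el),
    )


# --------------------------------------------------------------------- writer

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"


def _math(*children) -> etree._Element:
    m = etree.Element(f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
    for c in children:
        m.append(c)
    return m


def _cn(value: float) -> etree._Element:
    el = etree.Element(f"{{{MATHML_NS}}}cn")
    el.text = repr(float(value))
    return el


def _ci(name: str) -> etree._Element:
    el = etree.Element(f"{{{MATHML_NS}}}ci")
    el.text = f" {name} "
    return el


def _apply(op: str, *args) -> etree._Element:
    el = etree.Element(f"{{{MATHML_NS}}}apply")
    el.append(etree.Element(f"{{{MATHML_NS}}}{op}"))
    for a in args:
        el.append(a)
    return el


def _time_symbol() -> etree._Element:
    el = etree.Element(f"{{{MATHML_NS}}}csymbol")
    el.set("encoding", "text")
    el.set("definitionURL", TIME_URL)
    el.text = " t "
    return el


def write_linear_pk_sbml(
    path: str,
    kind: str,
    elimination_rate: float,
    k12: float = 0.0,
    k21: float = 0.0,
    volume_ratio: float = 1.0,
    initial_circulation: float = 0.0,
    doses: Sequence[Tuple[float, float]] = (),
) -> str:
    """Write a minimal SBML file encoding a linear 1C/2C PK model.

    ``kind`` is "1C" or "2C"; ``doses`` is a sequence of (time_min, amount)
    bolus events that increment ``circulation_concentration``.  Returns the
    path.  Time units are minutes (undeclared, the reader's default).
    """
    if kind not in ("1C", "2C"):
        raise ValueError(f"kind must be '1C' or '2C', got {kind!r}")
    nsmap = {None: SBML_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "1")
    model = etree.SubElement(root, f"{{{SBML_NS}}}model")
    model.set("id", f"linear_pk_{kind}")

    comps = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    comp = etree.SubElement(comps, f"{{{SBML_NS}}}compartment")
    comp.set("id", "central")
    comp.set("size", "1")
    comp.set("constant", "true")

    species_list = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    names = [CIRCULATION_SPECIES] + (["periphery_concentration"] if kind == "2C" else [])
    for i, name in enumerate(names):
        sp = etree.SubElement(species_list, f"{{{SBML_NS}}}species")
        sp.set("id", name)
        sp.set("compartment", "central")
        sp.set(
            "initialConcentration",
            repr(float(initial_circulation)) if i == 0 else "0.0",
        )
        sp.set("hasOnlySubstanceUnits", "false")
        sp.set("boundaryCondition", "false")
        sp.set("constant", "false")

    params_list = etree.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    param_values = {"lam": elimination_rate}
    if kind == "2C":
        param_values.update({"k12": k12, "k21": k21, "R": volume_ratio})
    for pid, value in param_values.items():
        p = etree.SubElement(params_list, f"{{{SBML_NS}}}parameter")
        p.set("id", pid)
        p.set("value", repr(float(value)))
        p.set("constant", "true")

    rules = etree.SubElement(model, f"{{{SBML_NS}}}listOfRules")
    rule_c = etree.SubElement(rules, f"{{{SBML_NS}}}rateRule")
    rule_c.set("variable", CIRCULATION_SPECIES)
    if kind == "1C":
        # dC/dt = -lam * C
        expr = _apply(
            "times", _apply("minus", _ci("lam")), _ci(CIRCULATION_SPECIES)
        )
    else:
        # dC/dt = (k21/R)*P - (k12 + lam)*C
        expr = _apply(
            "minus",
            _apply(
                "times",
                _apply("divide", _ci("k21"), _ci("R")),
                _ci("periphery_concentration"),
            ),
            _apply(
                "times",
                _apply("plus", _ci("k12"), _ci("lam")),
                _ci(CIRCULATION_SPECIES),
            ),
        )
    rule_c.append(_math(expr))
    if kind == "2C":
        rule_p = etree.SubElement(rules, f"{{{SBML_NS}}}rateRule")
        rule_p.set("variable", "periphery_concentration")
        # dP/dt = k12*R*C - k21*P
        rule_p.append(
            _math(
                _apply(
                    "minus",
                    _apply(
                        "times",
                        _ci("k12"),
                        _ci("R"),
                        _ci(CIRCULATION_SPECIES),
                    ),
                    _apply("times", _ci("k21"), _ci("periphery_concentration")),
                )
            )
        )

    if doses:
        events = etree.SubElement(model, f"{{{SBML_NS}}}listOfEvents")
        for i, (t0, amount) in enumerate(doses):
            ev = etree.SubElement(events, f"{{{SBML_NS}}}event")
            ev.set("id", f"dose_{i}")
            ev.set("useValuesFromTriggerTime", "true")
            trig = etree.SubElement(ev, f"{{{SBML_NS}}}trigger")
            trig.set("initialValue", "false")
            trig.set("persistent", "true")
            trig.append(_math(_apply("geq", _time_symbol(), _cn(t0))))
            eas = etree.SubElement(ev, f"{{{SBML_NS}}}listOfEventAssignments")
            ea = etree.SubElement(eas, f"{{{SBML_NS}}}eventAssignment")
            ea.set("variable", CIRCULATION_SPECIES)
            ea.append(
                _math(_apply("plus", _ci(CIRCULATION_SPECIES), _cn(amount)))
            )

    tree = etree.ElementTree(root)
    tree.write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    return str(path)
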