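"""Data model and XML I/O for the AGILE policy definition language (PDL).

A policy suite is a self-contained XML document holding expert screening
logic: variable declarations, threshold templates, comparison rules,
dead-zone tolerance checks, utility functions, actions and policies.
This module defines the in-memory model, the canonical XML dialect and
its reader/writer/validator.  Evaluation lives in
:mod:`spinescreen.agile_engine`.

The dialect (tag names are fixed)::

    <PolicySuite name="...">
      <EnvironmentVariables><Variable name kind default?/>...</EnvironmentVariables>
      <InternalVariables><Variable name kind default?/>...</InternalVariables>
      <ReturnValues><ReturnValue name/>...</ReturnValues>
      <Template name><Assign var value/>...</Template>
      <Rule name left op right onTrue onFalse?/>
      <ToleranceRangeCheck name monitored reference tolerance
                           onInZone? onBelow? onAbove?/>
      <UtilityFunction name>
        <Term var weight/>...
        <Bands breakpoints="b1,b2,..."/>
        <BandActions actions="a0,a1,..."/>
      </UtilityFunction>
      <Action name><Assign var value/>|<Evaluate ref/>|<Yield policy/>
                   |<Return value payload?/></Action>
      <Policy name entry><LoadTemplate ref/>...</Policy>
    </PolicySuite>

Operand attributes (``left``, ``right``, ``reference``, ``value``,
``payload``) hold either a literal -- a number, ``true``/``false`` or a
single-quoted string -- or a bare variable name resolved at evaluation
time (environment, then internal, then local scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

from lxml import etree

__all__ = [
    "PdlError",
    "PolicyParseError",
    "PolicySchemaError",
    "PolicyLinkError",
    "ScalarValue",
    "VarRef",
    "Operand",
    "VariableDecl",
    "Template",
    "RuleSpec",
    "TRCSpec",
    "UFSpec",
    "AssignStep",
    "EvaluateStep",
    "YieldStep",
    "ReturnStep",
    "ActionSpec",
    "PolicySpec",
    "PolicySuite",
    "Diagnostic",
    "parse_policy_suite",
    "serialize_policy_suite",
    "validate_suite",
]


class PdlError(Exception):
    """Base error for policy handling."""


class PolicyParseError(PdlError):
    """Malformed XML (carries parser line information in the message)."""


class PolicySchemaError(PdlError):
    """Well-formed XML that is not valid canonical-dialect policy markup."""


class PolicyLinkError(PdlError):
    """A cross-reference in the document does not resolve."""


SCALAR_KINDS = ("number", "string", "boolean")

RULE_OPERATORS = ("EQ", "NE", "LT", "LE", "GT", "GE")


@dataclass(frozen=True)
class ScalarValue:
    """A typed literal: real number, string or boolean.

    ``kind`` and the payload type always agree; numbers are finite.
    """

    kind: str
    value: Union[float, str, bool]

    def __post_init__(self) -> None:
        if self.kind not in SCALAR_KINDS:
            raise ValueError(f"unknown scalar kind {self.kind!r}")
        if self.kind == "number":
            v = float(self.value)
            if not math.isfinite(v):
                raise ValueError("number payload must be finite")
            object.__setattr__(self, "value", v)
        elif self.kind == "boolean":
            if not isinstance(self.value, bool):
                raise ValueError("boolean payload must be a bool")
        else:
            if not isinstance(self.value, str):
                raise ValueError("string payload must be a str")

    @classmethod
    def number(cls, x: float) -> "ScalarValue":
        return cls("number", float(x))

    @classmethod
    def string(cls, s: str) -> "ScalarValue":
        return cls("string", s)

    @classmethod
    def boolean(cls, b: bool) -> "ScalarValue":
        return cls("boolean", bool(b))

    @classmethod
    def coerce(cls, raw: object) -> "ScalarValue":
        """Wrap a raw Python value (bool checked before number)."""
        if isinstance(raw, ScalarValue):
            return raw
        if isinstance(raw, bool):
            return cls.boolean(raw)
        if isinstance(raw, (int, float)):
            return cls.number(raw)
        if isinstance(raw, str):
            return cls.string(raw)
        raise TypeError(f"cannot coerce {type(raw).__name__} to ScalarValue")


@dataclass(frozen=True)
class VarRef:
    """Reference to a variable by bare name (scope resolved at evaluation)."""

    name: str


Operand = Union[ScalarValue, VarRef]


def parse_operand(text: str) -> Operand:
    """Parse an operand attribute: literal number / boolean /
    single-quoted string, otherwise a variable reference."""
    text = text.strip()
    if not text:
        raise PolicySchemaError("empty operand")
    if len(text) >= 2 and text[0] == "'" and text[-1] == "'":
        return ScalarValue.string(text[1:-1])
    if text == "true":
        return ScalarValue.boolean(True)
    if text == "false":
        return ScalarValue.boolean(False)
    try:
        return ScalarValue.number(float(text))
    except (ValueError, OverflowError):
        pass
    return VarRef(text)


def format_number(v: float) -> str:
    """Shortest decimal form that round-trips through float()."""
    if float(v).is_integer() and abs(v) < 1e16:
        return str(int(v))
    return repr(float(v))


def format_operand(op: Operand) -> str:
    if isinstance(op, VarRef):
        return op.name
    if op.kind == "number":
        return format_number(op.value)
    if op.kind == "boolean":
        return "true" if op.value else "false"
    if "'" in op.value:
        raise PolicySchemaError("string literals may not contain single quotes")
    return f"'{op.value}'"


@dataclass(frozen=True)
class VariableDecl:
    name: str
    scope: str  # environment | internal | local
    kind: str
    default: Optional[ScalarValue] = None


@dataclass(frozen=True)
class Template:
    """Named block of internal-variable assignments (threshold presets)."""

    name: str
    assignments: tuple = ()  # of (internal name, ScalarValue)


@dataclass(frozen=True)
class RuleSpec:
    """Binary comparison dispatching to an action per branch."""

    name: str
    left: Operand
    op: str
    right: Operand
    on_true: str
    on_false: Optional[str] = None


@dataclass(frozen=True)
class TRCSpec:
    """Tolerance range check: a dead-zone of half-width ``tolerance``
    around ``reference``; dispatches on in-zone / below / above."""

    name: str
    monitored: VarRef
    reference: Operand
    tolerance: float
    on_in_zone: Optional[str] = None
    on_below: Optional[str] = None
    on_above: Optional[str] = None


@dataclass(frozen=True)
class UFSpec:
    """Utility function: weighted sum of variables, dispatched through
    ordered bands (half-open; a breakpoint belongs to the upper band)."""

    name: str
    terms: tuple = ()  # of (VarRef, weight)
    breakpoints: tuple = ()
    band_actions: tuple = ()


@dataclass(frozen=True)
class AssignStep:
    var: str
    value: Operand


@dataclass(frozen=True)
class EvaluateStep:
    ref: str  # a Rule, TRC or UF name


@dataclass(frozen=True)
class YieldStep:
    policy: str


@dataclass(frozen=True)
class ReturnStep:
    value: str  # declared return-value name
    payload: Optional[Operand] = None


Step = Union[AssignStep, EvaluateStep, YieldStep, ReturnStep]


@dataclass(frozen=True)
class ActionSpec:
    name: str
    steps: tuple = ()


@dataclass(frozen=True)
class PolicySpec:
    name: str
    templates: tuple = ()  # template names loaded in order
    entry: str = ""  # entry action name


@dataclass
class PolicySuite:
    """A full policy document; the first policy is the entry policy."""

    name: str
    env_vars: list = field(default_factory=list)
    internal_vars: list = field(default_factory=list)
    return_values: list = field(default_factory=list)
    templates: list = field(default_factory=list)
    rules: list = field(default_factory=list)
    trcs: list = field(default_factory=list)
    ufs: list = field(default_factory=list)
    actions: list = field(default_factory=list)
    policies: list = field(default_factory=list)

    # -- lookup helpers ------------------------------------------------
    def _by_name(self, items):
        return {x.name: x for x in items}

    @property
    def template_map(self):
        return self._by_name(self.templates)

    @property
    def rule_map(self):
        return self._by_name(self.rules)

    @property
    def trc_map(self):
        return self._by_name(self.trcs)

    @property
    def uf_map(self):
        return self._by_name(self.ufs)

    @property
    def action_map(self):
        return self._by_name(self.actions)

    @property
    def policy_map(self):
        return self._by_name(self.policies)

    @property
    def entry_policy(self) -> PolicySpec:
        if not self.policies:
            raise PolicyLinkError("no entry policy")
        return self.policies[0]

    def declared(self, scope: str):
        src = self.env_vars if scope == "environment" else self.internal_vars
        return {d.name: d for d in src}

    def local_assign_targets(self):
        """Names assigned by Assign steps inside actions (implicit locals)."""
        out = set()
        for a in self.actions:
            for s in a.steps:
                if isinstance(s, AssignStep):
                    out.add(s.var)
        return out


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "error" | "warning"
    obj: str
    message: str


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_ALLOWED_ATTRS = {
    "PolicySuite": {"name"},
    "Variable": {"name", "kind", "default"},
    "ReturnValue": {"name"},
    "Template": {"name"},
    "Assign": {"var", "value"},
    "Rule": {"name", "left", "op", "right", "onTrue", "onFalse"},
    "ToleranceRangeCheck": {
        "name", "monitored", "reference", "tolerance",
        "onInZone", "onBelow", "onAbove",
    },
    "UtilityFunction": {"name"},
    "Term": {"var", "weight"},
    "Bands": {"breakpoints"},
    "BandActions": {"actions"},
    "Action": {"name"},
    "Evaluate": {"ref"},
    "Yield": {"policy"},
    "Return": {"value", "payload"},
    "Policy": {"name", "entry"},
    "LoadTemplate": {"ref"},
    "EnvironmentVariables": set(),
    "InternalVariables": set(),
    "ReturnValues": set(),
}


def _check_attrs(el) -> None:
    allowed = _ALLOWED_ATTRS.get(el.tag)
    if allowed is None:
        raise PolicySchemaError(
            f"unknown tag <{el.tag}> (line {el.sourceline})")
    extra = set(el.attrib) - allowed
    if extra:
        raise PolicySchemaError(
            f"unknown attribute(s) {sorted(extra)} on <{el.tag}> "
            f"(line {el.sourceline})")


def _req(el, attr: str) -> str:
    _check_attrs(el)
    try:
        return el.attrib[attr]
    except KeyError:
        raise PolicySchemaError(
            f"<{el.tag}> missing required attribute {attr!r} "
            f"(line {el.sourceline})") from None


def _parse_variable(el, scope: str) -> VariableDecl:
    name = _req(el, "name")
    kind = _req(el, "kind")
    if kind not in SCALAR_KINDS:
        raise PolicySchemaError(
            f"variable {name!r}: unknown kind {kind!r} (line {el.sourceline})")
    default = None
    if "default" in el.attrib:
        raw = el.attrib["default"]
        if kind == "number":
            try:
                default = ScalarValue.number(float(raw))
            except (ValueError, OverflowError):
                raise PolicySchemaError(
                    f"variable {name!r}: default {raw!r} is not a number") from None
        elif kind == "boolean":
            if raw not in ("true", "false"):
                raise PolicySchemaError(
                    f"variable {name!r}: default {raw!r} is not a boolean")
            default = ScalarValue.boolean(raw == "true")
        else:
            default = ScalarValue.string(raw)
    return VariableDecl(name=name, scope=scope, kind=kind, default=default)


def _parse_assign_value(raw: str) -> ScalarValue:
    op = parse_operand(raw)
    if isinstance(op, VarRef):
        raise PolicySchemaError(
            f"template assignment value {raw!r} must be a literal")
    return op


def _parse_template(el) -> Template:
    _check_attrs(el)
    assignments = []
    for child in el:
        if child.tag != "Assign":
            raise PolicySchemaError(
                f"unexpected <{child.tag}> inside <Template> "
                f"(line {child.sourceline})")
        assignments.append((_req(child, "var"),
                            _parse_assign_value(_req(child, "value"))))
    return Template(name=_req(el, "name"), assignments=tuple(assignments))


def _parse_rule(el) -> RuleSpec:
    op = _req(el, "op")
    if op not in RULE_OPERATORS:
        raise PolicySchemaError(
            f"rule {el.get('name')!r}: unknown operator {op!r}")
    return RuleSpec(
        name=_req(el, "name"),
        left=parse_operand(_req(el, "left")),
        op=op,
        right=parse_operand(_req(el, "right")),
        on_true=_req(el, "onTrue"),
        on_false=el.get("onFalse"),
    )


def _parse_trc(el) -> TRCSpec:
    name = _req(el, "name")
    try:
        tol = float(_req(el, "tolerance"))
    except ValueError:
        raise PolicySchemaError(
            f"TRC {name!r}: tolerance is not a number") from None
    spec = TRCSpec(
        name=name,
        monitored=VarRef(_req(el, "monitored")),
        reference=parse_operand(_req(el, "reference")),
        tolerance=tol,
        on_in_zone=el.get("onInZone"),
        on_below=el.get("onBelow"),
        on_above=el.get("onAbove"),
    )
    if spec.on_in_zone is None and spec.on_below is None and spec.on_above is None:
        raise PolicySchemaError(f"TRC {name!r}: no zone action given")
    return spec


def _parse_uf(el) -> UFSpec:
    name = _req(el, "name")
    terms, breakpoints, band_actions = [], None, None
    for child in el:
        if child.tag == "Term":
            terms.append((VarRef(_req(child, "var")),
                          float(_req(child, "weight"))))
        elif child.tag == "Bands":
            breakpoints = tuple(
                float(t) for t in _req(child, "breakpoints").split(",") if t.strip())
        elif child.tag == "BandActions":
            band_actions = tuple(
                t.strip() for t in _req(child, "actions").split(",") if t.strip())
        else:
            raise PolicySchemaError(
                f"unexpected <{child.tag}> inside <UtilityFunction> "
                f"(line {child.sourceline})")
    if breakpoints is None or band_actions is None:
        raise PolicySchemaError(
            f"utility function {name!r}: Bands and BandActions are required")
    return UFSpec(name=name, terms=tuple(terms),
                  breakpoints=breakpoints, band_actions=band_actions)


def _parse_action(el) -> ActionSpec:
    steps = []
    for child in el:
        if child.tag == "Assign":
            steps.append(AssignStep(_req(child, "var"),
                                    parse_operand(_req(child, "value"))))
        elif child.tag == "Evaluate":
            steps.append(EvaluateStep(_req(child, "ref")))
        elif child.tag == "Yield":
            steps.append(YieldStep(_req(child, "policy")))
        elif child.tag == "Return":
            payload = child.get("payload")
            steps.append(ReturnStep(
                _req(child, "value"),
                parse_operand(payload) if payload is not None else None))
        else:
            raise PolicySchemaError(
                f"unexpected <{child.tag}> inside <Action> "
                f"(line {child.sourceline})")
    return ActionSpec(name=_req(el, "name"), steps=tuple(steps))


def _parse_policy(el) -> PolicySpec:
    templates = []
    for child in el:
        if child.tag != "LoadTemplate":
            raise PolicySchemaError(
                f"unexpected <{child.tag}> inside <Policy> "
                f"(line {child.sourceline})")
        templates.append(_req(child, "ref"))
    return PolicySpec(name=_req(el, "name"),
                      templates=tuple(templates),
                      entry=_req(el, "entry"))


def parse_policy_suite(xml_text: str) -> PolicySuite:
    """Parse canonical-dialect XML into a fully cross-linked suite.

    Raises :class:`PolicyParseError` on malformed XML,
    :class:`PolicySchemaError` on unknown tags/attributes and
    :class:`PolicyLinkError` on dangling references.
    """
    try:
        root = etree.fromstring(xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise PolicyParseError(f"malformed XML: {exc}") from None
    if root.tag != "PolicySuite":
        raise PolicySchemaError(f"root element must be <PolicySuite>, "
                                f"got <{root.tag}>")
    suite = PolicySuite(name=_req(root, "name"))
    for el in root:
        if el.tag == "EnvironmentVariables":
            _check_attrs(el)
            suite.env_vars.extend(
                _parse_variable(v, "environment") for v in el)
        elif el.tag == "InternalVariables":
            _check_attrs(el)
            suite.internal_vars.extend(
                _parse_variable(v, "internal") for v in el)
        elif el.tag == "ReturnValues":
            _check_attrs(el)
            for v in el:
                if v.tag != "ReturnValue":
                    raise PolicySchemaError(
                        f"unexpected <{v.tag}> inside <ReturnValues>")
                suite.return_values.append(_req(v, "name"))
        elif el.tag == "Template":
            suite.templates.append(_parse_template(el))
        elif el.tag == "Rule":
            suite.rules.append(_parse_rule(el))
        elif el.tag == "ToleranceRangeCheck":
            suite.trcs.append(_parse_trc(el))
        elif el.tag == "UtilityFunction":
            suite.ufs.append(_parse_uf(el))
        elif el.tag == "Action":
            suite.actions.append(_parse_action(el))
        elif el.tag == "Policy":
            suite.policies.append(_parse_policy(el))
        else:
            raise PolicySchemaError(
                f"unknown tag <{el.tag}> (line {el.sourceline})")
    _link(suite)
    return suite


def _link(suite: PolicySuite) -> None:
    """Reject dangling cross-references."""
    if not suite.policies:
        raise PolicyLinkError("no entry policy")
    actions = set(suite.action_map)
    evaluables = set(suite.rule_map) | set(suite.trc_map) | set(suite.uf_map)
    declared = (set(suite.declared("environment"))
                | set(suite.declared("internal"))
                | suite.local_assign_targets())

    def need_action(ref, owner):
        if ref is not None and ref not in actions:
            raise PolicyLinkError(
                f"{owner}: dangling action reference {ref!r}")

    def need_var(op, owner):
        if isinstance(op, VarRef) and op.name not in declared:
            raise PolicyLinkError(
                f"{owner}: dangling variable reference {op.name!r}")

    for r in suite.rules:
        need_action(r.on_true, f"rule {r.name!r}")
        need_action(r.on_false, f"rule {r.name!r}")
        need_var(r.left, f"rule {r.name!r}")
        need_var(r.right, f"rule {r.name!r}")
    for t in suite.trcs:
        for ref in (t.on_in_zone, t.on_below, t.on_above):
            need_action(ref, f"TRC {t.name!r}")
        need_var(t.monitored, f"TRC {t.name!r}")
        need_var(t.reference, f"TRC {t.name!r}")
    for u in suite.ufs:
        for ref in u.band_actions:
            need_action(ref, f"utility function {u.name!r}")
        for var, _w in u.terms:
            need_var(var, f"utility function {u.name!r}")
    internal = set(suite.declared("internal"))
    for tpl in suite.templates:
        for var, _v in tpl.assignments:
            if var not in internal:
                raise PolicyLinkError(
                    f"template {tpl.name!r}: assignment to undeclared "
                    f"internal variable {var!r}")
    for a in suite.actions:
        for s in a.steps:
            if isinstance(s, EvaluateStep) and s.ref not in evaluables:
                raise PolicyLinkError(
                    f"action {a.name!r}: dangling Evaluate reference {s.ref!r}")
            if isinstance(s, YieldStep) and s.policy not in suite.policy_map:
                raise PolicyLinkError(
                    f"action {a.name!r}: dangling Yield policy {s.policy!r}")
            if isinstance(s, ReturnStep) and s.value not in suite.return_values:
                raise PolicyLinkError(
                    f"action {a.name!r}: undeclared return value {s.value!r}")
            if isinstance(s, AssignStep):
                need_var(s.value, f"action {a.name!r}")
            if isinstance(s, ReturnStep) and s.payload is not None:
                need_var(s.payload, f"action {a.name!r}")
    for p in suite.policies:
        for ref in p.templates:
            if ref not in suite.template_map:
                raise PolicyLinkError(
                    f"policy {p.name!r}: dangling template reference {ref!r}")
        need_action(p.entry, f"policy {p.name!r}")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _scalar_attr(sv: ScalarValue) -> str:
    """Attribute text for a declared-kind value (strings unquoted)."""
    if sv.kind == "number":
        return format_number(sv.value)
    if sv.kind == "boolean":
        return "true" if sv.value else "false"
    return sv.value


def serialize_policy_suite(suite: PolicySuite) -> str:
    """Emit canonical XML; ``parse_policy_suite`` inverts this exactly
    (structural equality, numeric drift-free)."""
    root = etree.Element("PolicySuite", name=suite.name)

    def var_section(tag, decls):
        if not decls:
            return
        sec = etree.SubElement(root, tag)
        for d in decls:
            attrs = {"name": d.name, "kind": d.kind}
            if d.default is not None:
                attrs["default"] = _scalar_attr(d.default)
            etree.SubElement(sec, "Variable", **attrs)

    var_section("EnvironmentVariables", suite.env_vars)
    var_section("InternalVariables", suite.internal_vars)
    if suite.return_values:
        sec = etree.SubElement(root, "ReturnValues")
        for name in suite.return_values:
            etree.SubElement(sec, "ReturnValue", name=name)
    for tpl in suite.templates:
        el = etree.SubElement(root, "Template", name=tpl.name)
        for var, value in tpl.assignments:
            etree.SubElement(el, "Assign", var=var,
                             value=format_operand(value))
    for r in suite.rules:
        attrs = {"name": r.name, "left": format_operand(r.left),
                 "op": r.op, "right": format_operand(r.right),
                 "onTrue": r.on_true}
        if r.on_false is not None:
            attrs["onFalse"] = r.on_false
        etree.SubElement(root, "Rule", **attrs)
    for t in suite.trcs:
        attrs = {"name": t.name, "monitored": t.monitored.name,
                 "reference": format_operand(t.reference),
                 "tolerance": format_number(t.tolerance)}
        for key, ref in (("onInZone", t.on_in_zone),
                         ("onBelow", t.on_below),
                         ("onAbove", t.on_above)):
            if ref is not None:
                attrs[key] = ref
        etree.SubElement(root, "ToleranceRangeCheck", **attrs)
    for u in suite.ufs:
        el = etree.SubElement(root, "UtilityFunction", name=u.name)
        for var, weight in u.terms:
            etree.SubElement(el, "Term", var=var.name,
                             weight=format_number(weight))
        etree.SubElement(el, "Bands", breakpoints=",".join(
            format_number(b) for b in u.breakpoints))
        etree.SubElement(el, "BandActions", actions=",".join(u.band_actions))
    for a in suite.actions:
        el = etree.SubElement(root, "Action", name=a.name)
        for s in a.steps:
            if isinstance(s, AssignStep):
                etree.SubElement(el, "Assign", var=s.var,
                                 value=format_operand(s.value))
            elif isinstance(s, EvaluateStep):
                etree.SubElement(el, "Evaluate", ref=s.ref)
            elif isinstance(s, YieldStep):
                etree.SubElement(el, "Yield", policy=s.policy)
            else:
                attrs = {"value": s.value}
                if s.payload is not None:
                    attrs["payload"] = format_operand(s.payload)
                etree.SubElement(el, "Return", **attrs)
    for p in suite.policies:
        el = etree.SubElement(root, "Policy", name=p.name, entry=p.entry)
        for ref in p.templates:
            etree.SubElement(el, "LoadTemplate", ref=ref)
    text = etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8")
    return text.decode("utf-8").replace("\r\n", "\n")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_suite(suite: PolicySuite) -> list:
    """Check suite invariants; returns diagnostics instead of raising.

    An empty list means the suite is evaluable.  Errors cover duplicate
    names, negative tolerances, inconsistent utility-function bands,
    kind mismatches, dead steps after a Return and dangling references;
    cross-scope name shadowing is reported as a warning.
    """
    diags: list = []

    def err(obj, msg):
        diags.append(Diagnostic("error", obj, msg))

    def warn(obj, msg):
        diags.append(Diagnostic("warning", obj, msg))

    def check_unique(category, names):
        seen = set()
        for n in names:
            if n in seen:
                err(n, f"duplicate {category} name {n!r}")
            seen.add(n)

    check_unique("environment variable", [d.name for d in suite.env_vars])
    check_unique("internal variable", [d.name for d in suite.internal_vars])
    check_unique("return value", suite.return_values)
    check_unique("template", [t.name for t in suite.templates])
    check_unique("rule", [r.name for r in suite.rules])
    check_unique("TRC", [t.name for t in suite.trcs])
    check_unique("utility function", [u.name for u in suite.ufs])
    check_unique("action", [a.name for a in suite.actions])
    check_unique("policy", [p.name for p in suite.policies])

    env = set(suite.declared("environment"))
    internal_map = suite.declared("internal")
    shadowed = env & set(internal_map)
    for n in sorted(shadowed):
        warn(n, f"internal variable {n!r} shadows an environment variable")

    for d in suite.env_vars + suite.internal_vars:
        if not d.name:
            err(d.name, "variable name must be nonempty")
        if d.default is not None and d.default.kind != d.kind:
            err(d.name, f"default kind {d.default.kind!r} does not match "
                        f"declared kind {d.kind!r}")

    for tpl in suite.templates:
        for var, value in tpl.assignments:
            decl = internal_map.get(var)
            if decl is None:
                err(tpl.name, f"assignment to undeclared internal "
                              f"variable {var!r}")
            elif decl.kind != value.kind:
                err(tpl.name, f"assignment to {var!r}: value kind "
                              f"{value.kind!r} does not match declared "
                              f"kind {decl.kind!r}")

    for t in suite.trcs:
        if t.tolerance < 0:
            err(t.name, "tolerance must be ≥ 0")

    for u in suite.ufs:
        if any(b2 <= b1 for b1, b2 in zip(u.breakpoints, u.breakpoints[1:])):
            err(u.name, "breakpoints must be strictly increasing")
        if len(u.band_actions) != len(u.breakpoints) + 1:
            err(u.name, f"band action count {len(u.band_actions)} does not "
                        f"match breakpoint count {len(u.breakpoints)} + 1")

    for a in suite.actions:
        for i, s in enumerate(a.steps):
            if isinstance(s, ReturnStep) and i != len(a.steps) - 1:
                err(a.name, "unreachable steps after Return")
                break

    if not suite.policies:
        err(suite.name, "no entry policy")

    try:
        _link(suite)
    except PolicyLinkError as exc:
        err(suite.name, str(exc))

    return diags
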