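"""Mamdani fuzzy policy engine producing a disease-severity scalar.

A fuzzy policy describes each quantity (signal ``Amplitude``, impulse
``Width``, and the output ``Condition``) as a linguistic variable: a
numeric universe carrying named fuzzy terms (Small / Medium / High),
each a trapezoid or Gaussian membership function.  Inference is the
classic Mamdani pipeline:

1. *fuzzify* — each crisp input is graded against every term of its
   linguistic variable (inputs outside the universe are clamped);
2. *fire* — each rule's strength is the minimum of its antecedent
   grades (min-conjunction);
3. *aggregate* — every consequent term is clipped at the maximum
   strength of the rules that assert it, and the clipped terms are
   combined by pointwise maximum over the output universe grid;
4. *defuzzify* — the centroid ∫x·μ(x)dx / ∫μ(x)dx of the aggregate,
   by trapezoidal quadrature on a uniform grid (default 1001 points).

The severity output lives on [0, 1]: 0 means no spine issue detected,
1 a severe condition.  The rule base is the monotone 3×3 table pairing
amplitude and width terms: tall narrow impulses (confident, quick
sit-to-stand movement) map to low severity, shallow wide impulses
(careful, stiffened movement) to high severity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from lxml import etree

from .pdl_model import PolicyParseError, PolicySchemaError, PolicyLinkError

__all__ = [
    "FuzzyError",
    "NoRuleFiredError",
    "Universe",
    "Trapezoid",
    "Gaussian",
    "MembershipFunction",
    "LinguisticVariable",
    "LVarBinding",
    "FuzzyRule",
    "FuzzyPolicy",
    "RuleBase3x3",
    "SPINE_RULE_BASE",
    "gaussian_membership",
    "trapezoid_membership",
    "fuzzify",
    "rule_firing_strength",
    "aggregate_and_defuzzify",
    "expand_rule_base",
    "evaluate_fuzzy_policy",
    "parse_fuzzy_policy",
    "serialize_fuzzy_policy",
]


class FuzzyError(Exception):
    """Base error for fuzzy policy handling."""


class NoRuleFiredError(FuzzyError):
    """All rule strengths are zero — screening must not silently emit a
    default severity."""


# ---------------------------------------------------------------------------
# membership functions
# ---------------------------------------------------------------------------

def gaussian_membership(x, center: float, sigma: float):
    """Gaussian fuzzy-set membership μ(x) = exp(−(c − x)² / (2σ²)).

    Symmetric about ``center``; equals 1 at the center and lies in
    (0, 1] everywhere.  Accepts scalars or arrays.
    """
    if sigma <= 0:
        raise FuzzyError(f"Gaussian sigma must be > 0, got {sigma}")
    x = np.asarray(x, dtype=float)
    out = np.exp(-((center - x) ** 2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def trapezoid_membership(x, a: float, b: float, c: float, d: float):
    """Trapezoid membership: 0 outside [a, d], linear ramps on [a, b]
    and [c, d], plateau 1 on [b, c].

    Degenerate edges (a == b or c == d) give a crisp step; membership
    at the shared point is 1.  Accepts scalars or arrays.
    """
    if not (a <= b <= c <= d):
        raise FuzzyError(
            f"trapezoid parameters must satisfy a ≤ b ≤ c ≤ d, "
            f"got ({a}, {b}, {c}, {d})")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    # plateau first so degenerate edges (a==b, c==d) land on 1
    left = (x >= a) & (x < b)
    right = (x > c) & (x <= d)
    if b > a:
        out[left] = (x[left] - a) / (b - a)
    if d > c:
        out[right] = (d - x[right]) / (d - c)
    out[(x >= b) & (x <= c)] = 1.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Trapezoid:
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if not (self.a <= self.b <= self.c <= self.d):
            raise FuzzyError(
                f"trapezoid parameters must satisfy a ≤ b ≤ c ≤ d, "
                f"got ({self.a}, {self.b}, {self.c}, {self.d})")

    def __call__(self, x):
        return trapezoid_membership(x, self.a, self.b, self.c, self.d)

    @property
    def params(self) -> Tuple[float, ...]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class Gaussian:
    center: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise FuzzyError(
                f"Gaussian sigma must be > 0, got {self.sigma}")

    def __call__(self, x):
        return gaussian_membership(x, self.center, self.sigma)

    @property
    def params(self) -> Tuple[float, ...]:
        return (self.center, self.sigma)


Shape = Union[Trapezoid, Gaussian]


@dataclass(frozen=True)
class MembershipFunction:
    """A named fuzzy term (e.g. ``Small``) over a linguistic variable."""

    name: str
    shape: Shape

    def __call__(self, x):
        return self.shape(x)


@dataclass(frozen=True)
class Universe:
    """Numeric domain of a linguistic variable plus the uniform grid
    resolution used for centroid defuzzification."""

    lo: float
    hi: float
    resolution: int = 1001

    def __post_init__(self):
        if not self.lo < self.hi:
            raise FuzzyError(f"universe requires lo < hi, "
                             f"got [{self.lo}, {self.hi}]")
        if self.resolution < 3:
            raise FuzzyError("universe resolution must be ≥ 3")

    def grid(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.resolution)

    def clamp(self, x: float) -> float:
        return min(max(x, self.lo), self.hi)


@dataclass(frozen=True)
class LinguisticVariable:
    name: str
    role: str  # "input" | "output"
    universe: Universe
    terms: Tuple[MembershipFunction, ...]

    def __post_init__(self):
        if self.role not in ("input", "output"):
            raise FuzzyError(f"role must be input or output, got {self.role!r}")
        if not self.terms:
            raise FuzzyError(f"linguistic variable {self.name!r} has no terms")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise FuzzyError(
                f"linguistic variable {self.name!r} has duplicate terms")

    def term(self, name: str) -> MembershipFunction:
        for t in self.terms:
            if t.name == name:
                return t
        raise FuzzyError(f"variable {self.name!r} has no term {name!r}")


@dataclass(frozen=True)
class LVarBinding:
    """Tie between a context variable (a physical quantity such as
    ``Amplitude``) and a linguistic variable, for fuzzification (input)
    or defuzzification (output)."""

    context: str
    linguistic: str
    direction: str  # "fuzzify" | "defuzzify"

    def __post_init__(self):
        if self.direction not in ("fuzzify", "defuzzify"):
            raise FuzzyError(
                f"direction must be fuzzify or defuzzify, "
                f"got {self.direction!r}")


@dataclass(frozen=True)
class FuzzyRule:
    """IF (lvar₁ is term₁) AND ... THEN (output lvar is term)."""

    antecedents: Tuple[Tuple[str, str], ...]  # (lvar name, term name)
    consequent: Tuple[str, str]

    def __post_init__(self):
        if not self.antecedents:
            raise FuzzyError("fuzzy rule must have at least one antecedent")


@dataclass
class FuzzyPolicy:
    """Linguistic variables, context bindings and a rule set evaluating
    to a crisp severity."""

    name: str
    variables: List[LinguisticVariable] = field(default_factory=list)
    bindings: List[LVarBinding] = field(default_factory=list)
    rules: List[FuzzyRule] = field(default_factory=list)
    output_context: str = "Condition"

    @property
    def variable_map(self) -> Dict[str, LinguisticVariable]:
        return {v.name: v for v in self.variables}

    @property
    def input_bindings(self) -> List[LVarBinding]:
        return [b for b in self.bindings if b.direction == "fuzzify"]

    @property
    def output_binding(self) -> LVarBinding:
        outs = [b for b in self.bindings if b.direction == "defuzzify"]
        if len(outs) != 1:
            raise FuzzyError(
                f"policy {self.name!r} must have exactly one output "
                f"binding, found {len(outs)}")
        return outs[0]

    def validate(self) -> None:
        vmap = self.variable_map
        if len(vmap) != len(self.variables):
            raise FuzzyError("duplicate linguistic variable names")
        seen = set()
        for b in self.bindings:
            if b.context in seen:
                raise FuzzyError(
                    f"context variable {b.context!r} bound more than once")
            seen.add(b.context)
            if b.linguistic not in vmap:
                raise FuzzyError(
                    f"binding {b.context!r}: unknown linguistic "
                    f"variable {b.linguistic!r}")
            want = "input" if b.direction == "fuzzify" else "output"
            if vmap[b.linguistic].role != want:
                raise FuzzyError(
                    f"binding {b.context!r}: {b.linguistic!r} has role "
                    f"{vmap[b.linguistic].role!r}, expected {want!r}")
        out = self.output_binding
        if out.context != self.output_context:
            raise FuzzyError(
                f"output binding is for {out.context!r} but the policy "
                f"declares output {self.output_context!r}")
        for i, rule in enumerate(self.rules):
            for lvar, term in rule.antecedents:
                if lvar not in vmap:
                    raise FuzzyError(f"rule {i}: unknown variable {lvar!r}")
                vmap[lvar].term(term)  # raises on unknown term
            clvar, cterm = rule.consequent
            if clvar != out.linguistic:
                raise FuzzyError(
                    f"rule {i}: consequent uses {clvar!r}, not the output "
                    f"variable {out.linguistic!r}")
            vmap[clvar].term(cterm)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def fuzzify(value: float, lvar: LinguisticVariable) -> Dict[str, float]:
    """Grade a crisp value against every term of an input variable.

    Values outside the universe are clamped to its bounds first, so
    extreme movements degrade gracefully instead of erroring.
    """
    if lvar.role != "input":
        raise FuzzyError(f"cannot fuzzify over output variable {lvar.name!r}")
    x = lvar.universe.clamp(float(value))
    return {t.name: float(t(x)) for t in lvar.terms}


def rule_firing_strength(rule: FuzzyRule,
                         grades: Dict[str, Dict[str, float]]) -> float:
    """Mamdani conjunction: the minimum antecedent grade."""
    strengths = []
    for lvar, term in rule.antecedents:
        try:
            strengths.append(grades[lvar][term])
        except KeyError:
            raise FuzzyError(
                f"missing grade for {lvar!r} is {term!r}") from None
    return min(strengths)


def aggregate_and_defuzzify(rules, strengths,
                            out_lvar: LinguisticVariable) -> float:
    """Clip each consequent term at its best rule strength, combine by
    pointwise max, and return the centroid of the aggregate.

    Raises :class:`NoRuleFiredError` when every strength is zero.
    """
    if len(rules) != len(strengths):
        raise FuzzyError("strengths are not aligned with rules")
    if out_lvar.role != "output":
        raise FuzzyError(
            f"defuzzification requires an output variable, "
            f"got {out_lvar.name!r}")
    term_strength: Dict[str, float] = {}
    for rule, s in zip(rules, strengths):
        term = rule.consequent[1]
        term_strength[term] = max(term_strength.get(term, 0.0), float(s))
    if not term_strength or max(term_strength.values()) <= 0.0:
        raise NoRuleFiredError("no rule fired")
    grid = out_lvar.universe.grid()
    agg = np.zeros_like(grid)
    for term, s in term_strength.items():
        if s <= 0.0:
            continue
        mu = np.minimum(out_lvar.term(term)(grid), s)
        np.maximum(agg, mu, out=agg)
    denom = np.trapezoid(agg, grid)
    if denom <= 0.0:
        raise NoRuleFiredError("aggregate has zero area")
    centroid = float(np.trapezoid(grid * agg, grid) / denom)
    return min(max(centroid, out_lvar.universe.lo), out_lvar.universe.hi)


def evaluate_fuzzy_policy(policy: FuzzyPolicy,
                          bindings: Dict[str, float]) -> float:
    """Full pipeline: fuzzify every bound input, fire all rules,
    aggregate and defuzzify.  Deterministic."""
    policy.validate()
    vmap = policy.variable_map
    grades: Dict[str, Dict[str, float]] = {}
    for b in policy.input_bindings:
        if b.context not in bindings:
            raise FuzzyError(f"unbound input {b.context!r}")
        grades[b.linguistic] = fuzzify(bindings[b.context], vmap[b.linguistic])
    strengths = [rule_firing_strength(r, grades) for r in policy.rules]
    out_lvar = vmap[policy.output_binding.linguistic]
    return aggregate_and_defuzzify(policy.rules, strengths, out_lvar)


# ---------------------------------------------------------------------------
# the 3×3 rule base
# ---------------------------------------------------------------------------

TERM_ORDER = ("Small", "Medium", "High")


@dataclass(frozen=True)
class RuleBase3x3:
    """Severity term per (width term, amplitude term) cell.

    Rows are indexed by the width term, columns by the amplitude term —
    the orientation under which a tall narrow impulse (healthy, brisk
    movement) maps to low severity and a shallow wide one to high.
    """

    # cells[w][a]: w indexes widths, a amplitudes, both in TERM_ORDER
    cells: Tuple[Tuple[str, str, str], ...]

    def severity(self, width_term: str, amplitude_term: str) -> str:
        w = TERM_ORDER.index(width_term)
        a = TERM_ORDER.index(amplitude_term)
        return self.cells[w][a]

    def validate(self) -> None:
        if len(self.cells) != 3 or any(len(r) != 3 for r in self.cells):
            raise FuzzyError("rule base must be a complete 3×3 grid")
        for row in self.cells:
            for term in row:
                if term not in TERM_ORDER:
                    raise FuzzyError(f"unknown severity term {term!r}")
        rank = {t: i for i, t in enumerate(TERM_ORDER)}
        # severity nondecreasing with width, nonincreasing with amplitude
        for a in range(3):
            col = [rank[self.cells[w][a]] for w in range(3)]
            if any(c2 < c1 for c1, c2 in zip(col, col[1:])):
                raise FuzzyError("severity must be nondecreasing in width")
        for w in range(3):
            row = [rank[self.cells[w][a]] for a in range(3)]
            if any(r2 > r1 for r1, r2 in zip(row, row[1:])):
                raise FuzzyError("severity must be nonincreasing in amplitude")


# cells[width][amplitude], both indexed Small, Medium, High:
#   narrow impulse: only a *small* amplitude raises concern (Medium);
#   medium width: severity tracks how weak the impulse is;
#   wide impulse: anything but a strong amplitude is High severity.
SPINE_RULE_BASE = RuleBase3x3(cells=(
    ("Medium", "Small", "Small"),   # Width Small × Amp (Small, Medium, High)
    ("High", "Medium", "Small"),    # Width Medium
    ("High", "High", "Medium"),     # Width High
))


def expand_rule_base(base: RuleBase3x3,
                     amplitude_lvar: str = "LAmpl",
                     width_lvar: str = "LWdth",
                     output_lvar: str = "LCond") -> List[FuzzyRule]:
    """One two-antecedent rule per cell — exactly 9 rules."""
    base.validate()
    rules = []
    for w_term in TERM_ORDER:
        for a_term in TERM_ORDER:
            rules.append(FuzzyRule(
                antecedents=((amplitude_lvar, a_term), (width_lvar, w_term)),
                consequent=(output_lvar, base.severity(w_term, a_term)),
            ))
    return rules


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------

def _parse_shape(mf_type: str, value: str):
    parts = [p.strip() for p in value.split(",") if p.strip()]
    try:
        nums = [float(p) for p in parts]
    except ValueError:
        raise PolicySchemaError(
            f"membership Value {value!r} is not numeric") from None
    if mf_type == "Trapezoid":
        if len(nums) != 4:
            raise PolicySchemaError(
                f"Trapezoid Value needs 4 parameters, got {len(nums)}")
        try:
            return Trapezoid(*nums)
        except FuzzyError as exc:
            raise PolicySchemaError(str(exc)) from None
    if mf_type == "Gaussian":
        if len(nums) != 2:
            raise PolicySchemaError(
                f"Gaussian Value needs 2 parameters (center, sigma), "
                f"got {len(nums)}")
        try:
            return Gaussian(*nums)
        except FuzzyError as exc:
            raise PolicySchemaError(str(exc)) from None
    raise PolicySchemaError(f"unknown membership Type {mf_type!r}")


def parse_fuzzy_policy(xml_text: str) -> FuzzyPolicy:
    """Parse the fuzzy XML dialect into a validated policy."""
    try:
        root = etree.fromstring(xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise PolicyParseError(f"malformed XML: {exc}") from None
    if root.tag != "FuzzyPolicy":
        raise PolicySchemaError(
            f"root element must be <FuzzyPolicy>, got <{root.tag}>")
    policy = FuzzyPolicy(name=root.get("name", ""),
                         output_context=root.get("output", "Condition"))
    for el in root:
        if el.tag == "LinguisticVariables":
            for lv in el:
                if lv.tag != "LinguisticVariable":
                    raise PolicySchemaError(
                        f"unexpected <{lv.tag}> in <LinguisticVariables>")
                uni = lv.find("Universe")
                if uni is None:
                    raise PolicySchemaError(
                        f"variable {lv.get('name')!r}: missing <Universe>")
                resolution = int(uni.get("resolution", "1001"))
                universe = Universe(float(uni.get("lo")),
                                    float(uni.get("hi")), resolution)
                mfs = []
                mfsec = lv.find("MembershipFunctions")
                for mf in (mfsec if mfsec is not None else []):
                    if mf.tag != "MF":
                        raise PolicySchemaError(
                            f"unexpected <{mf.tag}> in <MembershipFunctions>")
                    mfs.append(MembershipFunction(
                        name=mf.get("Name"),
                        shape=_parse_shape(mf.get("Type"), mf.get("Value"))))
                policy.variables.append(LinguisticVariable(
                    name=lv.get("name"), role=lv.get("role"),
                    universe=universe, terms=tuple(mfs)))
        elif el.tag == "LVar":
            policy.bindings.append(LVarBinding(
                context=el.get("context"),
                linguistic=el.get("linguistic"),
                direction=el.get("direction")))
        elif el.tag == "FuzzyRules":
            for fr in el:
                if fr.tag != "FuzzyRule":
                    raise PolicySchemaError(
                        f"unexpected <{fr.tag}> in <FuzzyRules>")
                ants, cons = [], None
                for part in fr:
                    if part.tag == "If":
                        ants.append((part.get("lvar"), part.get("term")))
                    elif part.tag == "Then":
                        cons = (part.get("lvar"), part.get("term"))
                    else:
                        raise PolicySchemaError(
                            f"unexpected <{part.tag}> in <FuzzyRule>")
                if cons is None:
                    raise PolicySchemaError("fuzzy rule missing <Then>")
                policy.rules.append(FuzzyRule(tuple(ants), cons))
        else:
            raise PolicySchemaError(f"unknown tag <{el.tag}>")
    try:
        policy.validate()
    except FuzzyError as exc:
        raise PolicyLinkError(str(exc)) from None
    return policy


def serialize_fuzzy_policy(policy: FuzzyPolicy) -> str:
    """Emit the fuzzy dialect; inverse of :func:`parse_fuzzy_policy`."""
    from .pdl_model import format_number

    root = etree.Element("FuzzyPolicy", name=policy.name,
                         output=policy.output_context)
    lvs = etree.SubElement(root, "LinguisticVariables")
    for v in policy.variables:
        lv = etree.SubElement(lvs, "LinguisticVariable",
                              name=v.name, role=v.role)
        uni_attrs = {"lo": format_number(v.universe.lo),
                     "hi": format_number(v.universe.hi)}
        if v.universe.resolution != 1001:
            uni_attrs["resolution"] = str(v.universe.resolution)
        etree.SubElement(lv, "Universe", **uni_attrs)
        mfs = etree.SubElement(lv, "MembershipFunctions")
        for t in v.terms:
            mf_type = ("Trapezoid" if isinstance(t.shape, Trapezoid)
                       else "Gaussian")
            etree.SubElement(
                mfs, "MF", Name=t.name, Type=mf_type,
                Value=",".join(format_number(p) for p in t.shape.params))
    for b in policy.bindings:
        etree.SubElement(root, "LVar", context=b.context,
                         linguistic=b.linguistic, direction=b.direction)
    frs = etree.SubElement(root, "FuzzyRules")
    for r in policy.rules:
        fr = etree.SubElement(frs, "FuzzyRule")
        for lvar, term in r.antecedents:
            etree.SubElement(fr, "If", lvar=lvar, term=term)
        etree.SubElement(fr, "Then", lvar=r.consequent[0],
                         term=r.consequent[1])
    text = etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8")
    return text.decode("utf-8").replace("\r\n", "\n")
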