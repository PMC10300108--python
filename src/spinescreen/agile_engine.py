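"""Deterministic evaluation of AGILE policy suites.

The engine binds environment variables (e.g. the extracted ``Amplitude``
and ``Width`` features), applies the entry policy's templates to the
internal store, and walks the entry action step by step.  Rules compare
operands, tolerance range checks classify a monitored value into
in-zone / below / above a dead-zone (boundary inclusive: |value −
reference| ≤ tolerance is in-zone), and utility functions dispatch a
weighted sum through ordered bands.  Evaluation ends at the first
``Return``, yielding a :class:`Decision` with a complete ordered trace
of every object visited — the trace is the screening audit trail.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Optional

from .pdl_model import (
    ActionSpec,
    AssignStep,
    EvaluateStep,
    PolicySpec,
    PolicySuite,
    ReturnStep,
    RuleSpec,
    ScalarValue,
    Template,
    TRCSpec,
    UFSpec,
    VarRef,
    YieldStep,
    validate_suite,
)

__all__ = [
    "EvaluationError",
    "EvaluationContext",
    "TraceEntry",
    "Decision",
    "apply_template",
    "evaluate_rule",
    "evaluate_trc",
    "evaluate_utility_function",
    "evaluate_policy_suite",
    "render_trace",
    "MAX_DEPTH",
]

MAX_DEPTH = 32  # guard against cyclic Yield / action chains


class EvaluationError(Exception):
    """Raised when a suite cannot be evaluated (missing binding, kind
    mismatch, recursion limit, no decision...)."""


@dataclass
class EvaluationContext:
    """Three-scope variable store; names resolve environment → internal
    → local."""

    environment: Dict[str, ScalarValue] = field(default_factory=dict)
    internal: Dict[str, ScalarValue] = field(default_factory=dict)
    local: Dict[str, ScalarValue] = field(default_factory=dict)

    def resolve(self, name: str) -> ScalarValue:
        for store in (self.environment, self.internal, self.local):
            if name in store:
                return store[name]
        raise EvaluationError(f"unresolved variable {name!r}")


@dataclass(frozen=True)
class TraceEntry:
    ordinal: int
    category: str  # policy|template|action|rule|trc|uf|return
    name: str
    outcome: str


@dataclass(frozen=True)
class Decision:
    name: str
    payload: Optional[ScalarValue]
    trace: tuple  # of TraceEntry


def render_trace(trace) -> str:
    """One line per entry: ``ordinal. category name → outcome``."""
    return "\n".join(f"{e.ordinal}. {e.category} {e.name} → {e.outcome}"
                     for e in trace)


def _resolve_operand(op, ctx: EvaluationContext) -> ScalarValue:
    if isinstance(op, VarRef):
        return ctx.resolve(op.name)
    return op


def _number(sv: ScalarValue, what: str) -> float:
    if sv.kind != "number":
        raise EvaluationError(f"{what} must be a number, got {sv.kind}")
    return sv.value


def apply_template(template: Template, ctx: EvaluationContext) -> EvaluationContext:
    """Apply assignments to the internal store in document order;
    later templates (and later assignments) win."""
    for var, value in template.assignments:
        if var not in ctx.internal:
            raise EvaluationError(
                f"template {template.name!r}: assignment to undeclared "
                f"internal variable {var!r}")
        ctx.internal[var] = value
    return ctx


def evaluate_rule(rule: RuleSpec, ctx: EvaluationContext):
    """Compare the two operands; returns (branch, action ref or None)."""
    left = _resolve_operand(rule.left, ctx)
    right = _resolve_operand(rule.right, ctx)
    if left.kind != right.kind:
        raise EvaluationError(
            f"rule {rule.name!r}: kind mismatch {left.kind} vs {right.kind}")
    if left.kind != "number" and rule.op not in ("EQ", "NE"):
        raise EvaluationError(
            f"rule {rule.name!r}: operator {rule.op} is only defined "
            f"for numbers")
    a, b = left.value, right.value
    branch = {
        "EQ": a == b, "NE": a != b,
        "LT": a < b, "LE": a <= b,
        "GT": a > b, "GE": a >= b,
    }[rule.op]
    return branch, (rule.on_true if branch else rule.on_false)


def evaluate_trc(trc: TRCSpec, ctx: EvaluationContext):
    """Dead-zone classification; returns (zone, action ref or None).

    Exactly one of ``in`` / ``below`` / ``above`` holds; the boundary
    |d| == tolerance is in-zone.
    """
    if trc.tolerance < 0:
        raise EvaluationError(f"TRC {trc.name!r}: tolerance must be ≥ 0")
    value = _number(ctx.resolve(trc.monitored.name),
                    f"TRC {trc.name!r} monitored variable")
    reference = _number(_resolve_operand(trc.reference, ctx),
                        f"TRC {trc.name!r} reference")
    d = value - reference
    if abs(d) <= trc.tolerance:
        return "in", trc.on_in_zone
    if d < 0:
        return "below", trc.on_below
    return "above", trc.on_above


def evaluate_utility_function(uf: UFSpec, ctx: EvaluationContext):
    """Weighted-sum utility dispatched through half-open bands
    [bᵢ, bᵢ₊₁); a utility exactly at a breakpoint belongs to the upper
    band.  Returns (utility, action ref)."""
    utility = 0.0
    for var, weight in uf.terms:
        utility += weight * _number(ctx.resolve(var.name),
                                    f"utility term {var.name!r}")
    band = bisect.bisect_right(list(uf.breakpoints), utility)
    return utility, uf.band_actions[band]


class _Evaluator:
    def __init__(self, suite: PolicySuite, max_depth: int = MAX_DEPTH):
        self.suite = suite
        self.max_depth = max_depth
        self.trace: list = []
        self._ordinal = 0

    def log(self, category: str, name: str, outcome: str) -> None:
        self._ordinal += 1
        self.trace.append(TraceEntry(self._ordinal, category, name, outcome))

    def run_policy(self, policy: PolicySpec, ctx: EvaluationContext,
                   depth: int) -> Optional[Decision]:
        if depth > self.max_depth:
            raise EvaluationError("policy recursion limit")
        self.log("policy", policy.name, "enter")
        for ref in policy.templates:
            template = self.suite.template_map[ref]
            apply_template(template, ctx)
            self.log("template", template.name, "applied")
        action = self.suite.action_map[policy.entry]
        return self.run_action(action, ctx, depth + 1)

    def run_action(self, action: ActionSpec, ctx: EvaluationContext,
                   depth: int) -> Optional[Decision]:
        if depth > self.max_depth:
            raise EvaluationError("policy recursion limit")
        self.log("action", action.name, "enter")
        for step in action.steps:
            if isinstance(step, AssignStep):
                value = _resolve_operand(step.value, ctx)
                ctx.local[step.var] = value
                self.log("action", action.name,
                         f"assign {step.var}={value.value}")
            elif isinstance(step, EvaluateStep):
                decision = self.run_evaluate(step.ref, ctx, depth)
                if decision is not None:
                    return decision
            elif isinstance(step, YieldStep):
                decision = self.run_policy(
                    self.suite.policy_map[step.policy], ctx, depth + 1)
                if decision is not None:
                    return decision
            elif isinstance(step, ReturnStep):
                payload = (_resolve_operand(step.payload, ctx)
                           if step.payload is not None else None)
                self.log("return", step.value, step.value)
                return Decision(name=step.value, payload=payload,
                                trace=tuple(self.trace))
        return None

    def run_evaluate(self, ref: str, ctx: EvaluationContext,
                     depth: int) -> Optional[Decision]:
        suite = self.suite
        if ref in suite.rule_map:
            rule = suite.rule_map[ref]
            branch, action_ref = evaluate_rule(rule, ctx)
            self.log("rule", ref, "true" if branch else "false")
        elif ref in suite.trc_map:
            zone, action_ref = evaluate_trc(suite.trc_map[ref], ctx)
            self.log("trc", ref, zone)
        elif ref in suite.uf_map:
            utility, action_ref = evaluate_utility_function(
                suite.uf_map[ref], ctx)
            self.log("uf", ref, f"utility={utility}")
        else:
            raise EvaluationError(f"unknown Evaluate reference {ref!r}")
        if action_ref is None:
            return None
        return self.run_action(suite.action_map[action_ref], ctx, depth + 1)


def build_context(suite: PolicySuite, bindings: Dict[str, object]) -> EvaluationContext:
    """Bind environment variables (raw Python values are coerced) and
    initialise the internal store from declared defaults."""
    ctx = EvaluationContext()
    for decl in suite.env_vars:
        if decl.name not in bindings:
            raise EvaluationError(
                f"unbound environment variable {decl.name}")
        sv = ScalarValue.coerce(bindings[decl.name])
        if sv.kind != decl.kind:
            raise EvaluationError(
                f"environment variable {decl.name!r}: bound {sv.kind}, "
                f"declared {decl.kind}")
        ctx.environment[decl.name] = sv
    unknown = set(bindings) - set(ctx.environment)
    if unknown:
        raise EvaluationError(
            f"bindings for undeclared environment variable(s): "
            f"{sorted(unknown)}")
    for decl in suite.internal_vars:
        if decl.default is not None:
            ctx.internal[decl.name] = decl.default
        else:
            # placeholder of the declared kind; templates normally overwrite
            zero = {"number": ScalarValue.number(0.0),
                    "string": ScalarValue.string(""),
                    "boolean": ScalarValue.boolean(False)}[decl.kind]
            ctx.internal[decl.name] = zero
    return ctx


def evaluate_policy_suite(suite: PolicySuite, bindings: Dict[str, object],
                          max_depth: int = MAX_DEPTH,
                          skip_validation: bool = False) -> Decision:
    """Evaluate the suite's entry policy against environment bindings.

    Deterministic: identical suite and bindings give an identical
    decision and trace.  Refuses to evaluate a suite with validation
    errors.  ``skip_validation`` is for hot loops over an
    already-validated suite (e.g. parameter sweeps).
    """
    if not skip_validation:
        errors = [d for d in validate_suite(suite) if d.level == "error"]
        if errors:
            raise EvaluationError(
                "suite has validation errors: "
                + "; ".join(f"{d.obj}: {d.message}" for d in errors))
    ctx = build_context(suite, bindings)
    evaluator = _Evaluator(suite, max_depth=max_depth)
    decision = evaluator.run_policy(suite.entry_policy, ctx, depth=0)
    if decision is None:
        raise EvaluationError("policy returned no decision")
    return decision
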