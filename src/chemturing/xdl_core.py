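"""A conditional dialect of XDL: parse, validate and execute procedures.

The dialect extends a small vocabulary of liquid-handling unit operations
(Add, Transfer, EmptyToWaste, Wait) with the machinery that makes chemical
programs Turing complete:

* **Measure** steps read a virtual sensor, apply a comparison and store the
  boolean outcome under a mandatory, document-unique ``step_id``.
* Any step may carry a ``condition`` attribute — a boolean expression over
  stored step_ids (precedence ``not`` > ``and`` > ``or``, parentheses
  override).  A step whose condition evaluates false is skipped and leaves
  the platform untouched.
* **Repeat** loops re-evaluate a continue-while condition before every
  iteration and are bounded by a mandatory iteration cap.
* **Blueprints** are named, parameterized step sequences (the dialect's
  functions), invoked by their id; the call graph must be acyclic, so
  looping is provided solely by Repeat.

There are no arithmetic or string variables: the only mutable program state
is the boolean store written by Measure steps.  That austere expressive
budget is exactly what forces the Turing-machine compiler downstream to
unroll all position logic over the tape cells.

Execution produces an :class:`ExecutionTrace` — an ordered record of every
step executed, skipped, measured and looped, serializable to JSON lines.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Callable, Iterable, Mapping, Optional

from lxml import etree

from . import virtual_platform as vp
from .virtual_platform import PlatformState, PlatformError

# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class XDLError(Exception):
    """Base class for dialect-level failures."""


class XDLValidationError(XDLError):
    """The document violates a structural invariant of the dialect."""


class ConditionSyntaxError(XDLValidationError):
    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnsetVariableError(XDLError):
    """A condition referenced a step_id no Measure has written yet.

    Reading an unset variable is always an error, never a silent default:
    defaults would mask a mis-wired look-up table.
    """


class IterationCapError(XDLError):
    """A Repeat loop reached its iteration cap before its condition fell."""


# ---------------------------------------------------------------------------
# boolean condition expressions
# ---------------------------------------------------------------------------


class ConditionExpr:
    """Base class for condition expression nodes."""

    __slots__ = ()


@dataclass(frozen=True)
class Atom(ConditionExpr):
    name: str


@dataclass(frozen=True)
class Literal(ConditionExpr):
    value: bool


@dataclass(frozen=True)
class Not(ConditionExpr):
    operand: ConditionExpr


@dataclass(frozen=True)
class And(ConditionExpr):
    operands: tuple[ConditionExpr, ...]


@dataclass(frozen=True)
class Or(ConditionExpr):
    operands: tuple[ConditionExpr, ...]


_TOKEN_RE = re.compile(r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_]*)|(?P<lp>\()|(?P<rp>\)))")
_KEYWORDS = {"not", "and", "or", "true", "false"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ConditionSyntaxError(
                f"unexpected character {stripped[0]!r}", len(text) - len(stripped)
            )
        if m.lastgroup == "ident":
            word = m.group("ident")
            kind = word.lower() if word.lower() in _KEYWORDS else "ident"
            tokens.append((kind, word, m.start("ident")))
        elif m.lastgroup == "lp":
            tokens.append(("(", "(", m.start("lp")))
        else:
            tokens.append((")", ")", m.start("rp")))
        pos = m.end()
    return tokens


def parse_condition(text: str) -> ConditionExpr:
    """Parse a boolean expression over step_ids.

    Grammar (precedence ``not`` > ``and`` > ``or``)::

        or_expr  := and_expr ("or" and_expr)*
        and_expr := not_expr ("and" not_expr)*
        not_expr := "not" not_expr | atom
        atom     := IDENT | "true" | "false" | "(" or_expr ")"

    Keywords are case-insensitive; identifiers are case-sensitive.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ConditionSyntaxError("empty condition expression", 0)
    idx = 0

    def peek() -> Optional[tuple[str, str, int]]:
        return tokens[idx] if idx < len(tokens) else None

    def take(kind: str) -> tuple[str, str, int]:
        nonlocal idx
        tok = peek()
        if tok is None or tok[0] != kind:
            at = tok[2] if tok else len(text)
            raise ConditionSyntaxError(f"expected {kind!r}", at)
        idx += 1
        return tok

    def parse_or() -> ConditionExpr:
        operands = [parse_and()]
        while (tok := peek()) is not None and tok[0] == "or":
            take("or")
            operands.append(parse_and())
        return operands[0] if len(operands) == 1 else Or(tuple(operands))

    def parse_and() -> ConditionExpr:
        operands = [parse_not()]
        while (tok := peek()) is not None and tok[0] == "and":
            take("and")
            operands.append(parse_not())
        return operands[0] if len(operands) == 1 else And(tuple(operands))

    def parse_not() -> ConditionExpr:
        tok = peek()
        if tok is not None and tok[0] == "not":
            take("not")
            return Not(parse_not())
        return parse_atom()

    def parse_atom() -> ConditionExpr:
        tok = peek()
        if tok is None:
            raise ConditionSyntaxError("unexpected end of expression", len(text))
        kind, word, at = tok
        if kind == "ident":
            take("ident")
            return Atom(word)
        if kind == "true":
            take("true")
            return Literal(True)
        if kind == "false":
            take("false")
            return Literal(False)
        if kind == "(":
            take("(")
            inner = parse_or()
            take(")")
            return inner
        raise ConditionSyntaxError(f"unexpected token {word!r}", at)

    expr = parse_or()
    if (tok := peek()) is not None:
        raise ConditionSyntaxError(f"trailing input {tok[1]!r}", tok[2])
    return expr


def condition_atoms(expr: ConditionExpr) -> set[str]:
    """All step_id names an expression references."""
    if isinstance(expr, Atom):
        return {expr.name}
    if isinstance(expr, Literal):
        return set()
    if isinstance(expr, Not):
        return condition_atoms(expr.operand)
    out: set[str] = set()
    for op in expr.operands:  # type: ignore[union-attr]
        out |= condition_atoms(op)
    return out


class VariableStore:
    """Boolean store written by Measure steps: step_id -> (value, event)."""

    def __init__(self) -> None:
        self._entries: dict[str, tuple[bool, int]] = {}

    def set(self, step_id: str, value: bool, event_index: int) -> None:
        self._entries[step_id] = (bool(value), event_index)

    def get(self, step_id: str) -> bool:
        try:
            return self._entries[step_id][0]
        except KeyError:
            raise UnsetVariableError(
                f"condition references step_id {step_id!r} with no stored value"
            ) from None

    def last_write(self, step_id: str) -> int:
        return self._entries[step_id][1]

    def __contains__(self, step_id: str) -> bool:
        return step_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def as_dict(self) -> dict[str, bool]:
        return {k: v for k, (v, _) in self._entries.items()}


def evaluate_condition(expr: ConditionExpr, store: VariableStore) -> bool:
    """Standard boolean semantics; total evaluation, no short-circuiting, so
    an unset variable anywhere in the expression is always detected."""
    if isinstance(expr, Atom):
        return store.get(expr.name)
    if isinstance(expr, Literal):
        return expr.value
    if isinstance(expr, Not):
        return not evaluate_condition(expr.operand, store)
    if isinstance(expr, And):
        results = [evaluate_condition(op, store) for op in expr.operands]
        return all(results)
    if isinstance(expr, Or):
        results = [evaluate_condition(op, store) for op in expr.operands]
        return any(results)
    raise TypeError(f"not a condition expression: {expr!r}")


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

COMPARISONS = ("equal", "not_equal", "less_than", "greater_than", "between")


@dataclass(frozen=True)
class MeasureSpec:
    """What a Measure step checks: one sensor quantity against reference(s)."""

    step_id: str
    vessel: str
    quantity: str  # color | temperature | pH | volume
    comparison: str
    value: str
    value2: Optional[str] = None

    def validate(self) -> None:
        if not self.step_id:
            raise XDLValidationError("Measure requires a step_id")
        if self.quantity not in vp.QUANTITIES:
            raise XDLValidationError(f"unknown quantity {self.quantity!r}")
        if self.comparison not in COMPARISONS:
            raise XDLValidationError(f"unknown comparison {self.comparison!r}")
        if self.quantity == "color" and self.comparison not in ("equal", "not_equal"):
            raise XDLValidationError(
                f"comparison {self.comparison!r} is not defined on colors"
            )
        if self.comparison == "between":
            if self.value2 is None:
                raise XDLValidationError("between requires two reference values")
            if float(self.value) > float(self.value2):
                raise XDLValidationError("between bounds must satisfy low <= high")
        elif self.value2 is not None:
            raise XDLValidationError("value2 only allowed with comparison=between")


def execute_measure(
    spec: MeasureSpec,
    platform: PlatformState,
    store: VariableStore,
    event_index: int = 0,
) -> bool:
    """Read the sensor, apply the comparison, store and return the boolean.

    Numeric comparisons: ``less_than``/``greater_than`` are strict,
    ``between`` is inclusive on both ends.  Re-executing a Measure overwrites
    its previous entry.
    """
    spec.validate()
    reading = vp.sense(platform, spec.vessel, spec.quantity)
    if spec.quantity == "color":
        if spec.comparison == "equal":
            result = reading.value == spec.value
        else:
            result = reading.value != spec.value
    else:
        measured = float(reading.value)
        if spec.comparison == "equal":
            result = measured == float(spec.value)
        elif spec.comparison == "not_equal":
            result = measured != float(spec.value)
        elif spec.comparison == "less_than":
            result = measured < float(spec.value)
        elif spec.comparison == "greater_than":
            result = measured > float(spec.value)
        else:  # between, inclusive
            result = float(spec.value) <= measured <= float(spec.value2)
    store.set(spec.step_id, result, event_index)
    return result


# ---------------------------------------------------------------------------
# document model
# ---------------------------------------------------------------------------

UNIT_STEPS = ("Add", "Transfer", "EmptyToWaste", "Wait", "Measure", "Repeat")

# which params of each unit step name a vessel / a reagent
_VESSEL_PARAMS = {
    "Add": ("vessel",),
    "Transfer": ("from_vessel", "to_vessel"),
    "EmptyToWaste": ("vessel",),
    "Measure": ("vessel",),
}
_REAGENT_PARAMS = {"Add": ("reagent",)}
_REQUIRED_PARAMS = {
    "Add": ("vessel", "reagent", "volume"),
    "Transfer": ("from_vessel", "to_vessel", "volume"),
    "EmptyToWaste": ("vessel",),
    "Wait": ("time",),
    "Measure": ("vessel", "quantity", "comparison", "value"),
    "Repeat": ("condition",),
}


@dataclass
class Step:
    """One step of a procedure.

    ``params`` holds the step's attributes as strings (volumes in mL,
    durations in s); ``condition`` is the raw guard expression, if any;
    ``children`` is non-empty only for Repeat bodies.
    """

    name: str
    params: dict[str, str] = field(default_factory=dict)
    condition: Optional[str] = None
    step_id: Optional[str] = None
    children: list["Step"] = field(default_factory=list)

    def condition_expr(self) -> Optional[ConditionExpr]:
        return None if self.condition is None else parse_condition(self.condition)

    def measure_spec(self) -> MeasureSpec:
        assert self.name == "Measure"
        return MeasureSpec(
            step_id=self.step_id or "",
            vessel=self.params.get("vessel", ""),
            quantity=self.params.get("quantity", ""),
            comparison=self.params.get("comparison", ""),
            value=self.params.get("value", ""),
            value2=self.params.get("value2"),
        )


@dataclass
class Blueprint:
    """A named, parameterized, reusable block of steps (the dialect's
    function)."""

    id: str
    params: tuple[str, ...]
    steps: list[Step]


@dataclass
class XDLDocument:
    """A parsed procedure: declarations, blueprints and the main sequence."""

    reagents: dict[str, str]  # reagent id -> color label
    vessels: list[str]
    blueprints: dict[str, Blueprint]
    main: list[Step]

    def all_steps(self) -> Iterable[tuple[Step, Optional[Blueprint]]]:
        """Every step in the document with its enclosing blueprint (None for
        main), depth-first through Repeat children."""

        def walk(steps, bp):
            for s in steps:
                yield s, bp
                yield from walk(s.children, bp)

        yield from walk(self.main, None)
        for bp in self.blueprints.values():
            yield from walk(bp.steps, bp)

    def measure_step_ids(self) -> set[str]:
        return {
            s.step_id for s, _ in self.all_steps() if s.name == "Measure" and s.step_id
        }

    def validate(self) -> None:
        validate_document(self)


def validate_document(doc: XDLDocument) -> None:
    """Check every structural invariant of the dialect; raise
    :class:`XDLValidationError` on the first violation."""
    # step names and required params
    for step, bp in doc.all_steps():
        if step.name not in UNIT_STEPS and step.name not in doc.blueprints:
            raise XDLValidationError(f"unknown step name {step.name!r}")
        if step.name in _REQUIRED_PARAMS:
            for p in _REQUIRED_PARAMS[step.name]:
                if p not in step.params and not (p == "condition" and step.condition):
                    if step.name == "Repeat" and p == "condition":
                        if step.condition is None:
                            raise XDLValidationError("Repeat requires a condition")
                        continue
                    raise XDLValidationError(
                        f"step {step.name} missing required param {p!r}"
                    )
        if step.children and step.name != "Repeat":
            raise XDLValidationError(
                f"step {step.name} cannot carry child steps"
            )
        if step.name == "Measure":
            if not step.step_id:
                raise XDLValidationError("Measure without step_id")
            formals = set(bp.params) if bp else set()
            spec = step.measure_spec()
            if not {spec.value, spec.value2} & formals:
                spec.validate()

    # step_id uniqueness across the whole document
    seen: set[str] = set()
    for step, _ in doc.all_steps():
        if step.step_id is not None:
            if step.step_id in seen:
                raise XDLValidationError(f"duplicate step_id {step.step_id!r}")
            seen.add(step.step_id)

    # vessel / reagent declarations (blueprint formals count as declared)
    declared_vessels = set(doc.vessels)
    declared_reagents = set(doc.reagents)
    for step, bp in doc.all_steps():
        formals = set(bp.params) if bp else set()
        for p in _VESSEL_PARAMS.get(step.name, ()):
            ref = step.params.get(p)
            if ref is not None and ref not in declared_vessels | formals:
                raise XDLValidationError(f"undeclared vessel {ref!r} in {step.name}")
        for p in _REAGENT_PARAMS.get(step.name, ()):
            ref = step.params.get(p)
            if ref is not None and ref not in declared_reagents | formals:
                raise XDLValidationError(f"undeclared reagent {ref!r} in {step.name}")

    # conditions parse and reference only Measure-defined step_ids
    defined = doc.measure_step_ids()
    for step, _ in doc.all_steps():
        if step.condition is not None:
            expr = parse_condition(step.condition)
            for atom in sorted(condition_atoms(expr)):
                if atom not in defined:
                    raise XDLValidationError(f"undefined condition variable {atom}")

    # blueprint invocations: defined, fully bound, acyclic call graph
    def invocations(steps):
        for s in steps:
            if s.name in doc.blueprints:
                yield s
            yield from invocations(s.children)

    for step, _ in doc.all_steps():
        if step.name in doc.blueprints:
            bp = doc.blueprints[step.name]
            for formal in bp.params:
                if formal not in step.params:
                    raise XDLValidationError(
                        f"invocation of {bp.id!r} leaves param {formal!r} unbound"
                    )

    calls = {
        bp.id: {s.name for s in invocations(bp.steps)} for bp in doc.blueprints.values()
    }
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(node: str, stack: tuple[str, ...]) -> None:
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            cycle = " -> ".join(stack + (node,))
            raise XDLValidationError(f"recursive blueprint invocation: {cycle}")
        state[node] = 0
        for callee in sorted(calls.get(node, ())):
            visit(callee, stack + (node,))
        state[node] = 1

    for bp_id in doc.blueprints:
        visit(bp_id, ())


# ---------------------------------------------------------------------------
# XML parse / serialize
# ---------------------------------------------------------------------------


def _parse_step(elem: etree._Element, blueprint_ids: set[str]) -> Step:
    name = elem.tag
    if name not in UNIT_STEPS and name not in blueprint_ids:
        raise XDLValidationError(f"unknown step name {name!r}")
    params = dict(elem.attrib)
    condition = params.pop("condition", None)
    step_id = params.pop("step_id", None)
    children = [_parse_step(c, blueprint_ids) for c in elem]
    if children and name != "Repeat":
        raise XDLValidationError(f"step {name} cannot carry child steps")
    return Step(name=name, params=params, condition=condition, step_id=step_id,
                children=children)


def parse_xdl(text: str | bytes) -> XDLDocument:
    """Parse and validate an XDL document.  See the module docstring for the
    dialect; raises :class:`XDLValidationError` on any invariant violation."""
    if isinstance(text, str):
        text = text.encode()
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise XDLValidationError(f"malformed XML: {exc}") from exc
    if root.tag != "XDL":
        raise XDLValidationError(f"root element must be XDL, got {root.tag!r}")

    reagents: dict[str, str] = {}
    vessels: list[str] = []
    blueprint_elems: list[etree._Element] = []
    procedure_elem = None
    for child in root:
        if child.tag == "Reagents":
            for r in child:
                reagents[r.get("id")] = r.get("color", "")
        elif child.tag == "Vessels":
            vessels.extend(v.get("id") for v in child)
        elif child.tag == "Blueprint":
            blueprint_elems.append(child)
        elif child.tag == "Procedure":
            procedure_elem = child
        else:
            raise XDLValidationError(f"unexpected element {child.tag!r}")
    if procedure_elem is None:
        raise XDLValidationError("document has no Procedure")

    blueprint_ids = {b.get("id") for b in blueprint_elems}
    blueprints: dict[str, Blueprint] = {}
    for b in blueprint_elems:
        bid = b.get("id")
        if bid in blueprints:
            raise XDLValidationError(f"duplicate blueprint id {bid!r}")
        raw = b.get("params", "")
        params = tuple(p.strip() for p in raw.split(",") if p.strip())
        steps = [_parse_step(s, blueprint_ids) for s in b]
        blueprints[bid] = Blueprint(bid, params, steps)

    main = [_parse_step(s, blueprint_ids) for s in procedure_elem]
    doc = XDLDocument(reagents=reagents, vessels=vessels, blueprints=blueprints,
                      main=main)
    validate_document(doc)
    return doc


_MEASURE_ATTR_ORDER = ("vessel", "quantity", "comparison", "value", "value2")


def _step_to_elem(step: Step, parent: etree._Element) -> None:
    elem = etree.SubElement(parent, step.name)
    if step.step_id is not None:
        elem.set("step_id", step.step_id)
    order = _MEASURE_ATTR_ORDER if step.name == "Measure" else sorted(step.params)
    for key in order:
        if key in step.params:
            elem.set(key, step.params[key])
    for key in sorted(set(step.params) - set(order)):
        elem.set(key, step.params[key])
    if step.condition is not None:
        elem.set("condition", step.condition)
    for child in step.children:
        _step_to_elem(child, elem)


def serialize_xdl(doc: XDLDocument) -> str:
    """Render a document back to XML; ``parse_xdl(serialize_xdl(doc))`` is
    equal to ``doc``."""
    root = etree.Element("XDL")
    reagents = etree.SubElement(root, "Reagents")
    for rid, color in doc.reagents.items():
        etree.SubElement(reagents, "Reagent", id=rid, color=color)
    vessels = etree.SubElement(root, "Vessels")
    for vid in doc.vessels:
        etree.SubElement(vessels, "Vessel", id=vid)
    for bp in doc.blueprints.values():
        elem = etree.SubElement(root, "Blueprint", id=bp.id)
        if bp.params:
            elem.set("params", ",".join(bp.params))
        for s in bp.steps:
            _step_to_elem(s, elem)
    proc = etree.SubElement(root, "Procedure")
    for s in doc.main:
        _step_to_elem(s, proc)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# execution traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceEvent:
    """One event of an execution trace.

    Kinds: ``step_executed``, ``step_skipped``, ``measurement``,
    ``loop_iteration``, ``halt``.  Unused fields are None and omitted from
    the serialized form.
    """

    kind: str
    name: Optional[str] = None
    step_id: Optional[str] = None
    params: Optional[tuple[tuple[str, str], ...]] = None
    condition: Optional[str] = None
    reading: Optional[object] = None
    result: Optional[bool] = None
    index: Optional[int] = None
    reason: Optional[str] = None
    detail: Optional[str] = None

    def to_dict(self) -> dict:
        out: dict = {"kind": self.kind}
        for key in ("name", "step_id", "condition", "reading", "result", "index",
                    "reason", "detail"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        if self.params is not None:
            out["params"] = dict(self.params)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "TraceEvent":
        params = data.get("params")
        return cls(
            kind=data["kind"],
            name=data.get("name"),
            step_id=data.get("step_id"),
            params=None if params is None else tuple(sorted(params.items())),
            condition=data.get("condition"),
            reading=data.get("reading"),
            result=data.get("result"),
            index=data.get("index"),
            reason=data.get("reason"),
            detail=data.get("detail"),
        )


HALT_COMPLETED = "completed"
HALT_CAP = "iteration_cap"
HALT_PLATFORM_ERROR = "platform_error"
HALT_RUNTIME_ERROR = "runtime_error"


@dataclass
class ExecutionTrace:
    """Ordered events of one procedure execution.

    The final event is always a ``halt`` whose reason is one of
    ``completed``, ``iteration_cap``, ``platform_error`` or
    ``runtime_error``; :attr:`status` exposes it.
    """

    events: list[TraceEvent] = field(default_factory=list)

    def append(self, event: TraceEvent) -> None:
        self.events.append(event)

    @property
    def status(self) -> str:
        for ev in reversed(self.events):
            if ev.kind == "halt":
                return ev.reason or HALT_COMPLETED
        return "incomplete"

    @property
    def error_detail(self) -> Optional[str]:
        for ev in reversed(self.events):
            if ev.kind == "halt":
                return ev.detail
        return None

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(ev.to_dict(), sort_keys=True) for ev in self.events)

    @classmethod
    def from_jsonl(cls, text: str) -> "ExecutionTrace":
        events = [
            TraceEvent.from_dict(json.loads(line))
            for line in text.splitlines()
            if line.strip()
        ]
        return cls(events=events)

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# executor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExecutionLimits:
    """Bounds on a run.  ``max_iterations`` is the default cap for any Repeat
    that does not set its own ``max_iterations`` attribute: physical loops
    cannot be allowed to run forever (supervisory time-outs)."""

    max_iterations: int = 10_000


class _Executor:
    def __init__(
        self,
        doc: XDLDocument,
        platform: PlatformState,
        limits: ExecutionLimits,
        iteration_hook: Optional[Callable[[int], None]] = None,
    ) -> None:
        self.doc = doc
        self.platform = platform
        self.limits = limits
        self.iteration_hook = iteration_hook
        self.store = VariableStore()
        self.trace = ExecutionTrace()
        self._cond_cache: dict[str, ConditionExpr] = {}

    def _condition(self, text: str) -> ConditionExpr:
        expr = self._cond_cache.get(text)
        if expr is None:
            expr = self._cond_cache[text] = parse_condition(text)
        return expr

    @staticmethod
    def _bind(value: str, bindings: Mapping[str, str]) -> str:
        return bindings.get(value, value)

    def run(self) -> ExecutionTrace:
        try:
            self._run_steps(self.doc.main, {})
        except IterationCapError as exc:
            self.trace.append(TraceEvent("halt", reason=HALT_CAP, detail=str(exc)))
        except PlatformError as exc:
            self.trace.append(
                TraceEvent("halt", reason=HALT_PLATFORM_ERROR, detail=str(exc))
            )
        except UnsetVariableError as exc:
            self.trace.append(
                TraceEvent("halt", reason=HALT_RUNTIME_ERROR, detail=str(exc))
            )
        else:
            self.trace.append(TraceEvent("halt", reason=HALT_COMPLETED))
        return self.trace

    def _run_steps(self, steps: list[Step], bindings: Mapping[str, str]) -> None:
        for step in steps:
            if step.condition is not None and step.name != "Repeat":
                if not evaluate_condition(self._condition(step.condition), self.store):
                    self.trace.append(
                        TraceEvent(
                            "step_skipped",
                            name=step.name,
                            step_id=step.step_id,
                            condition=step.condition,
                        )
                    )
                    continue
            self._dispatch(step, bindings)

    def _dispatch(self, step: Step, bindings: Mapping[str, str]) -> None:
        bound = {k: self._bind(v, bindings) for k, v in step.params.items()}
        name = step.name
        if name == "Add":
            color = self.doc.reagents[bound["reagent"]]
            vp.add_from_stock(
                self.platform, color, bound["vessel"], Decimal(bound["volume"])
            )
            self._record_step(step, bound)
        elif name == "Transfer":
            vp.transfer(
                self.platform,
                bound["from_vessel"],
                bound["to_vessel"],
                Decimal(bound["volume"]),
            )
            self._record_step(step, bound)
        elif name == "EmptyToWaste":
            vp.empty_to_waste(self.platform, bound["vessel"])
            self._record_step(step, bound)
        elif name == "Wait":
            self.platform.event_counter += 1
            self._record_step(step, bound)
        elif name == "Measure":
            spec = MeasureSpec(
                step_id=step.step_id or "",
                vessel=bound["vessel"],
                quantity=bound["quantity"],
                comparison=bound["comparison"],
                value=bound["value"],
                value2=bound.get("value2"),
            )
            reading = vp.sense(self.platform, spec.vessel, spec.quantity)
            result = execute_measure(
                spec, self.platform, self.store, event_index=len(self.trace.events)
            )
            self.trace.append(
                TraceEvent(
                    "measurement",
                    step_id=spec.step_id,
                    name="Measure",
                    reading=reading.value,
                    result=result,
                )
            )
        elif name == "Repeat":
            self._run_repeat(step, bindings)
        else:  # blueprint invocation
            bp = self.doc.blueprints[name]
            inner = {formal: bound[formal] for formal in bp.params}
            self._record_step(step, bound)
            self._run_steps(bp.steps, inner)

    def _run_repeat(self, step: Step, bindings: Mapping[str, str]) -> None:
        cond = self._condition(step.condition) if step.condition else Literal(True)
        cap = int(step.params.get("max_iterations", self.limits.max_iterations))
        iteration = 0
        while True:
            if not evaluate_condition(cond, self.store):
                break
            if iteration >= cap:
                raise IterationCapError(
                    f"Repeat reached its iteration cap of {cap} with condition "
                    f"{step.condition!r} still true"
                )
            self.trace.append(TraceEvent("loop_iteration", index=iteration))
            self._run_steps(step.children, bindings)
            if self.iteration_hook is not None:
                self.iteration_hook(iteration)
            iteration += 1

    def _record_step(self, step: Step, bound: Mapping[str, str]) -> None:
        self.trace.append(
            TraceEvent(
                "step_executed",
                name=step.name,
                step_id=step.step_id,
                params=tuple(sorted(bound.items())),
            )
        )


def execute_procedure(
    doc: XDLDocument,
    platform: PlatformState,
    limits: Optional[ExecutionLimits] = None,
    iteration_hook: Optional[Callable[[int], None]] = None,
) -> ExecutionTrace:
    """Execute a validated document on a platform, depth-first.

    A step whose condition is false is skipped and recorded; Repeat
    re-evaluates its continue-while condition before every iteration; a
    blueprint invocation binds formal parameters to actual vessel/reagent
    ids and executes its body.  Any platform error aborts the run; the trace
    up to the failure is returned with a terminal ``halt`` event whose
    reason distinguishes normal completion, the iteration cap, platform
    errors and runtime errors.

    ``iteration_hook`` (if given) is called with the iteration index after
    each completed Repeat iteration — observers such as the compiled-program
    decoder use it to snapshot the platform between loop passes.
    """
    validate_document(doc)
    return _Executor(doc, platform, limits or ExecutionLimits(), iteration_hook).run()
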