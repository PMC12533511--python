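"""Human-readable intermediate representation: rendering and parsing.

Statements are sentences built only from concept display names, the
connectors AND/OR/NOT, numerical quantifiers, and count/period prefixes.
The grammar is strict and unambiguous: mixed AND/OR requires parentheses,
counted combinations are written ``AT LEAST n OF (a; b; c)``, frequency
actions carry a ``n×/period:`` prefix, continuous goals a ``(continuous)``
suffix, and rates a ``per 1000 patient-days`` suffix.  Everything the
renderer emits parses back to a structurally identical model.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .model import (
    ActionSpec,
    Atom,
    Catalog,
    CmpOp,
    CombinationMethod,
    Comparator,
    Combo,
    Concept,
    CriterionAtom,
    DEFAULT_SHIFTS,
    Expr,
    GoalSpec,
    IndicatorType,
    Intervention,
    Not,
    QualityIndicator,
    RateSpec,
    RecommendationPlanDef,
    TimingKind,
    TimingSpec,
)

_CMP_SYMBOLS = {
    CmpOp.EQ: "=",
    CmpOp.NE: "≠",
    CmpOp.LT: "<",
    CmpOp.LE: "≤",
    CmpOp.GT: ">",
    CmpOp.GE: "≥",
}
_SYMBOL_CMPS = {v: k for k, v in _CMP_SYMBOLS.items()}
_SYMBOL_CMPS.update({"<=": CmpOp.LE, ">=": CmpOp.GE, "!=": CmpOp.NE})

_PERIOD_TOKENS = {
    TimingKind.PER_DAY: "day",
    TimingKind.PER_SHIFT: "shift",
    TimingKind.PER_WEEK: "week",
    TimingKind.ONCE_PER_STAY: "stay",
}
_TOKEN_PERIODS = {v: k for k, v in _PERIOD_TOKENS.items()}

RATE_SUFFIX = "per 1000 patient-days"
GOAL_SUFFIX = "(continuous)"
HISTORY_SUFFIX = "before admission"

#: words that terminate a free-text unit while scanning
_UNIT_STOPWORDS = {"AND", "OR", "NOT", "OF", "and", "to", "before", "per"}


class BackTranslationError(ValueError):
    pass


class ParseError(ValueError):
    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class IntermediateStatement:
    sub_id: str
    plan_id: str
    population_text: str
    intervention_text: str
    notes: Optional[str] = None


# ---------------------------------------------------------------------------
# rendering


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def _render_comparator(cmp: Comparator) -> str:
    unit = f" {cmp.unit}" if cmp.unit else ""
    if cmp.op is CmpOp.RANGE:
        return f"between {_fmt_num(cmp.value)} and {_fmt_num(cmp.value_high)}{unit}"
    return f"{_CMP_SYMBOLS[cmp.op]} {_fmt_num(cmp.value)}{unit}"


def _render_atom(atom: CriterionAtom) -> str:
    if not atom.concept.display:
        raise BackTranslationError(
            f"concept {atom.concept.codings[0].code!r} has no display name"
        )
    parts = [atom.concept.display]
    if atom.comparator is not None:
        parts.append(_render_comparator(atom.comparator))
    if atom.history:
        parts.append(HISTORY_SUFFIX)
    return " ".join(parts)


def render_expr(expr: Expr, parent: Optional[CombinationMethod] = None) -> str:
    """Deterministic rendering; parentheses whenever a combination nests
    under NOT or under a different combination."""
    if isinstance(expr, Atom):
        return _render_atom(expr.atom)
    if isinstance(expr, Not):
        inner = render_expr(expr.child, parent=None)
        if isinstance(expr.child, Combo):
            inner = f"({inner})"
        return f"NOT {inner}"
    assert isinstance(expr, Combo)
    if expr.method in (CombinationMethod.ALL, CombinationMethod.ANY):
        sep = " AND " if expr.method is CombinationMethod.ALL else " OR "
        text = sep.join(render_expr(c, parent=expr.method) for c in expr.children)
        if parent is not None and parent is not expr.method:
            return f"({text})"
        if parent is expr.method:
            # same-method nesting still needs parentheses to round-trip
            return f"({text})"
        return text
    body = "; ".join(render_expr(c, parent=None) for c in expr.children)
    if expr.method is CombinationMethod.ONE_OR_MORE:
        return f"ONE OR MORE OF ({body})"
    return f"{expr.method.value.replace('_', ' ')} {expr.n} OF ({body})"


def _timing_prefix(action: ActionSpec) -> str:
    timing = action.timing
    if timing.kind is TimingKind.WITHIN_HOURS_OF_ADMISSION:
        return f"within {_fmt_num(timing.hours)}h of admission:"
    n = 0 if action.negated else timing.n
    return f"{n}×/{_PERIOD_TOKENS[timing.kind]}:"


def _render_item(item: Union[ActionSpec, GoalSpec, RateSpec]) -> str:
    if isinstance(item, ActionSpec):
        return f"{_timing_prefix(item)} {item.concept.display}"
    if isinstance(item, GoalSpec):
        return f"{item.concept.display} {_render_comparator(item.comparator)} {GOAL_SUFFIX}"
    assert isinstance(item, RateSpec)
    if item.threshold is None:
        return f"{item.numerator_concept.display} {RATE_SUFFIX}"
    return (
        f"{item.numerator_concept.display} "
        f"{_render_comparator(item.threshold)} {RATE_SUFFIX}"
    )


def render_intervention(intervention: Intervention) -> str:
    items = intervention.items
    method = intervention.method
    all_actions = all(isinstance(i, ActionSpec) for i in items)
    if len(items) == 1:
        return _render_item(items[0])
    if all_actions:
        timings = {(i.timing, i.negated) for i in items}  # type: ignore[union-attr]
        if len(timings) != 1:
            raise BackTranslationError(
                "multi-action interventions with differing timings are not renderable"
            )
        prefix = _timing_prefix(items[0])  # type: ignore[arg-type]
        names = [i.concept.display for i in items]  # type: ignore[union-attr]
        if method in (CombinationMethod.ALL, CombinationMethod.ANY):
            sep = " AND " if method is CombinationMethod.ALL else " OR "
            return f"{prefix} ({sep.join(names)})"
        body = "; ".join(names)
        if method is CombinationMethod.ONE_OR_MORE:
            return f"{prefix} ONE OR MORE OF ({body})"
        return f"{prefix} {method.value.replace('_', ' ')} {intervention.n} OF ({body})"
    rendered = [_render_item(i) for i in items]
    if method in (CombinationMethod.ALL, CombinationMethod.ANY):
        sep = " AND " if method is CombinationMethod.ALL else " OR "
        return sep.join(rendered)
    body = "; ".join(rendered)
    if method is CombinationMethod.ONE_OR_MORE:
        return f"ONE OR MORE OF ({body})"
    return f"{method.value.replace('_', ' ')} {intervention.n} OF ({body})"


def backtranslate_plan(qi: QualityIndicator, plan: RecommendationPlanDef) -> IntermediateStatement:
    return IntermediateStatement(
        sub_id=qi.sub_id,
        plan_id=plan.id,
        population_text=render_expr(plan.population),
        intervention_text=render_intervention(plan.intervention),
    )


def backtranslate(source) -> list[IntermediateStatement]:
    """Render an indicator (or an encoded bundle) into intermediate statements,
    one per population-intervention pair."""
    from .fhir import ResourceBundle, decode_bundle

    if isinstance(source, ResourceBundle):
        source = decode_bundle(source)
    if not isinstance(source, QualityIndicator):
        raise BackTranslationError(f"cannot back-translate {type(source).__name__}")
    if source.type is IndicatorType.STRUCTURE:
        raise BackTranslationError(
            f"indicator {source.sub_id} is a structure indicator (narrative only)"
        )
    return [backtranslate_plan(source, plan) for plan in source.plans]


def render_statement(stmt: IntermediateStatement) -> str:
    lines = [
        f"[{stmt.plan_id}]",
        f"population: {stmt.population_text}",
        f"intervention: {stmt.intervention_text}",
    ]
    if stmt.notes:
        lines.append(f"notes: {stmt.notes}")
    return "\n".join(lines)


def write_qitxt(statements: Iterable[IntermediateStatement]) -> str:
    return "\n\n".join(render_statement(s) for s in statements) + "\n"


# ---------------------------------------------------------------------------
# parsing


def _display_map(registry) -> dict[str, Concept]:
    if isinstance(registry, Catalog):
        concepts: Iterable[Concept] = registry.concepts
    else:
        concepts = registry
    return {c.display: c for c in concepts}


class _Parser:
    """Recursive-descent parser over the rendered grammar.

    Concept names are recognized by longest match against the registry's
    display names; there is no implicit AND/OR precedence.
    """

    def __init__(self, text: str, displays: dict[str, Concept]) -> None:
        self.text = text
        self.pos = 0
        self.displays = displays
        # longest-first so multiword names win over their prefixes
        self.names = sorted(displays, key=len, reverse=True)

    def error(self, message: str) -> ParseError:
        return ParseError(message, self.pos)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] in " \t":
            self.pos += 1

    def eof(self) -> bool:
        self.skip_ws()
        return self.pos >= len(self.text)

    def peek_literal(self, literal: str) -> bool:
        self.skip_ws()
        if not self.text.startswith(literal, self.pos):
            return False
        end = self.pos + len(literal)
        if literal[-1].isalnum() and end < len(self.text) and self.text[end].isalnum():
            return False  # require word boundary
        return True

    def take_literal(self, literal: str) -> bool:
        if self.peek_literal(literal):
            self.pos += len(literal)
            return True
        return False

    def expect(self, literal: str) -> None:
        if not self.take_literal(literal):
            raise self.error(f"expected {literal!r}")

    def take_number(self) -> Optional[float]:
        self.skip_ws()
        m = re.match(r"[-+]?\d+(\.\d+)?", self.text[self.pos :])
        if not m:
            return None
        self.pos += m.end()
        return float(m.group())

    def expect_number(self) -> float:
        value = self.take_number()
        if value is None:
            raise self.error("expected a number")
        return value

    def take_concept(self) -> Optional[Concept]:
        self.skip_ws()
        for name in self.names:
            if self.peek_literal(name):
                self.pos += len(name)
                return self.displays[name]
        return None

    def take_unit(self) -> str:
        words: list[str] = []
        while True:
            self.skip_ws()
            m = re.match(r"[A-Za-z%][\w%/.\-]*", self.text[self.pos :])
            if not m or m.group() in _UNIT_STOPWORDS:
                break
            # stop if this word begins a known suffix/connector context
            if self.peek_literal(GOAL_SUFFIX):
                break
            words.append(m.group())
            self.pos += m.end()
        return " ".join(words)

    def take_comparator(self) -> Optional[Comparator]:
        self.skip_ws()
        if self.take_literal("between"):
            low = self.expect_number()
            self.expect("and")
            high = self.expect_number()
            unit = self.take_unit()
            return Comparator(CmpOp.RANGE, low, high, unit)
        for sym in ("<=", ">=", "!=", "≤", "≥", "≠", "<", ">", "="):
            if self.take_literal(sym):
                value = self.expect_number()
                unit = self.take_unit()
                return Comparator(_SYMBOL_CMPS[sym], value, unit=unit)
        return None

    # -- population ------------------------------------------------------

    def parse_population(self) -> Expr:
        expr = self.parse_expr()
        if not self.eof():
            raise self.error("trailing input after population expression")
        return expr

    def parse_expr(self) -> Expr:
        children = [self.parse_term()]
        connector: Optional[str] = None
        while True:
            if self.peek_literal("AND"):
                word = "AND"
            elif self.peek_literal("ONE OR MORE"):
                break
            elif self.peek_literal("OR"):
                word = "OR"
            else:
                break
            if connector is not None and word != connector:
                raise self.error(
                    "ambiguous mix of AND and OR without parentheses"
                )
            self.take_literal(word)
            connector = word
            children.append(self.parse_term())
        if len(children) == 1:
            return children[0]
        method = CombinationMethod.ALL if connector == "AND" else CombinationMethod.ANY
        return Combo(method, tuple(children))

    def parse_term(self) -> Expr:
        if self.take_literal("NOT"):
            return Not(self.parse_term())
        for label, method in (
            ("AT LEAST", CombinationMethod.AT_LEAST),
            ("EXACTLY", CombinationMethod.EXACTLY),
        ):
            if self.take_literal(label):
                n = int(self.expect_number())
                self.expect("OF")
                return Combo(method, self._parse_semicolon_list(), n=n)
        if self.take_literal("ONE OR MORE"):
            self.expect("OF")
            return Combo(CombinationMethod.ONE_OR_MORE, self._parse_semicolon_list())
        if self.take_literal("("):
            expr = self.parse_expr()
            self.expect(")")
            return expr
        return Atom(self._parse_atom())

    def _parse_semicolon_list(self) -> tuple[Expr, ...]:
        self.expect("(")
        children = [self.parse_expr()]
        while self.take_literal(";"):
            children.append(self.parse_expr())
        self.expect(")")
        return tuple(children)

    def _parse_atom(self) -> CriterionAtom:
        concept = self.take_concept()
        if concept is None:
            raise self.error("expected a concept name")
        comparator = self.take_comparator()
        history = self.take_literal(HISTORY_SUFFIX)
        return CriterionAtom(concept, comparator, history)

    # -- intervention ----------------------------------------------------

    def take_timing_prefix(self) -> Optional[tuple[TimingSpec, bool]]:
        """Returns (timing, negated) when a prefix is present."""
        self.skip_ws()
        start = self.pos
        if self.take_literal("within"):
            hours = self.expect_number()
            self.expect("h")
            self.expect("of admission:")
            return TimingSpec(TimingKind.WITHIN_HOURS_OF_ADMISSION, hours=hours), False
        m = re.match(r"(\d+)[×x]/(day|shift|week|stay):", self.text[self.pos :])
        if not m:
            self.pos = start
            return None
        self.pos += m.end()
        count = int(m.group(1))
        kind = _TOKEN_PERIODS[m.group(2)]
        negated = count == 0
        n = 1 if negated else count
        shifts = DEFAULT_SHIFTS if kind is TimingKind.PER_SHIFT else None
        return TimingSpec(kind, n=n, shifts=shifts), negated

    def parse_intervention(self) -> Intervention:
        prefix = self.take_timing_prefix()
        if prefix is not None:
            timing, negated = prefix
            if self.take_literal("("):
                names, method, n = self._parse_action_group()
                self.expect(")")
            elif self.peek_literal("ONE OR MORE") or self.peek_literal("AT LEAST") or self.peek_literal("EXACTLY"):
                names, method, n = self._parse_counted_action_group()
            else:
                concept = self.take_concept()
                if concept is None:
                    raise self.error("expected a concept name after timing prefix")
                names, method, n = [concept], CombinationMethod.ALL, None
            if not self.eof():
                raise self.error("trailing input after intervention")
            items = tuple(ActionSpec(c, timing, negated) for c in names)
            return Intervention(method, items, n=n)

        items = [self._parse_item()]
        connector: Optional[str] = None
        while True:
            if self.peek_literal("AND"):
                word = "AND"
            elif self.peek_literal("OR"):
                word = "OR"
            else:
                break
            if connector is not None and word != connector:
                raise self.error("ambiguous mix of AND and OR without parentheses")
            self.take_literal(word)
            connector = word
            items.append(self._parse_item())
        if not self.eof():
            raise self.error("trailing input after intervention")
        method = CombinationMethod.ANY if connector == "OR" else CombinationMethod.ALL
        return _normalize_intervention(Intervention(method, tuple(items)))

    def _parse_action_group(self):
        names = [self._expect_concept()]
        connector: Optional[str] = None
        while True:
            if self.peek_literal("AND"):
                word = "AND"
            elif self.peek_literal("OR"):
                word = "OR"
            else:
                break
            if connector is not None and word != connector:
                raise self.error("ambiguous mix of AND and OR without parentheses")
            self.take_literal(word)
            connector = word
            names.append(self._expect_concept())
        method = CombinationMethod.ANY if connector == "OR" else CombinationMethod.ALL
        return names, method, None

    def _parse_counted_action_group(self):
        for label, method in (
            ("AT LEAST", CombinationMethod.AT_LEAST),
            ("EXACTLY", CombinationMethod.EXACTLY),
        ):
            if self.take_literal(label):
                n = int(self.expect_number())
                self.expect("OF")
                self.expect("(")
                names = [self._expect_concept()]
                while self.take_literal(";"):
                    names.append(self._expect_concept())
                self.expect(")")
                return names, method, n
        self.expect("ONE OR MORE")
        self.expect("OF")
        self.expect("(")
        names = [self._expect_concept()]
        while self.take_literal(";"):
            names.append(self._expect_concept())
        self.expect(")")
        return names, CombinationMethod.ONE_OR_MORE, None

    def _expect_concept(self) -> Concept:
        concept = self.take_concept()
        if concept is None:
            raise self.error("expected a concept name")
        return concept

    def _parse_item(self) -> Union[ActionSpec, GoalSpec, RateSpec]:
        prefix = self.take_timing_prefix()
        if prefix is not None:
            timing, negated = prefix
            return ActionSpec(self._expect_concept(), timing, negated)
        concept = self._expect_concept()
        comparator = self.take_comparator()
        if self.take_literal(RATE_SUFFIX):
            return RateSpec(concept, comparator)
        if self.take_literal(GOAL_SUFFIX):
            if comparator is None:
                raise self.error("continuous goal requires a comparator")
            return GoalSpec(concept, comparator)
        raise self.error(
            "intervention item needs a timing prefix, '(continuous)' suffix, "
            "or rate suffix"
        )


def _normalize_intervention(intervention: Intervention) -> Intervention:
    """Merge a paired lower/upper bound on one concept into a RANGE goal."""
    if intervention.method is not CombinationMethod.ALL or len(intervention.items) != 2:
        return intervention
    a, b = intervention.items
    if not (isinstance(a, GoalSpec) and isinstance(b, GoalSpec)):
        return intervention
    if a.concept != b.concept:
        return intervention
    bounds = {a.comparator.op: a.comparator, b.comparator.op: b.comparator}
    if set(bounds) == {CmpOp.GE, CmpOp.LE} and a.comparator.unit == b.comparator.unit:
        merged = Comparator(
            CmpOp.RANGE,
            bounds[CmpOp.GE].value,
            bounds[CmpOp.LE].value,
            a.comparator.unit,
        )
        return Intervention(CombinationMethod.ALL, (GoalSpec(a.concept, merged),))
    return intervention


def parse_population(text: str, registry) -> Expr:
    return _Parser(text, _display_map(registry)).parse_population()


def parse_intervention(text: str, registry) -> Intervention:
    return _Parser(text, _display_map(registry)).parse_intervention()


def parse_intermediate(text: str, registry) -> tuple[Expr, Intervention]:
    """Parse one statement block (``population: ...`` / ``intervention: ...``)."""
    pop_text = intv_text = None
    for line in text.strip().splitlines():
        line = line.strip()
        if line.startswith("population:"):
            pop_text = line[len("population:") :].strip()
        elif line.startswith("intervention:"):
            intv_text = line[len("intervention:") :].strip()
    if pop_text is None or intv_text is None:
        raise ParseError("statement needs population: and intervention: lines", 0)
    return parse_population(pop_text, registry), parse_intervention(intv_text, registry)


def parse_qitxt(text: str, registry) -> list[tuple[str, Expr, Intervention]]:
    """Parse a .qitxt document into (plan_id, population, intervention) triples."""
    out = []
    for block in re.split(r"\n\s*\n", text.strip()):
        header = re.match(r"\[([^\]]+)\]", block.strip())
        plan_id = header.group(1) if header else ""
        population, intervention = parse_intermediate(block, registry)
        out.append((plan_id, population, intervention))
    return out
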