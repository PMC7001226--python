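"""Scoring Scheme Definition Language: parse, validate, evaluate.

A scheme is a JSON document: ordered categories, each holding one or more
entries.  An entry is a rule with an artifact weight and/or a polymorphism
weight and a condition tree whose internal nodes are AND/OR combinators and
whose leaves are sandboxed boolean expressions.  When an entry's condition
holds for a variant row, its weights are added to the row's artifact and
polymorphism scores; the scores classify the row as artifact, polymorphism,
both, or pass.

The leaf expression language is deliberately tiny and side-effect free:

    literal     number | 'string' | "string" | true | false
    access      x("column")            -- variant-table column, as string
    threshold   th("name")             -- user-adjustable numeric threshold
    functions   isEmpty(e), stringContains(haystack, needle)
    comparison  < <= > >= == !=
    boolean     and, or, not, parentheses

``x()`` returns the raw cell string; a missing column is the empty string,
so ``isEmpty`` is the designated missingness test.  Comparing a missing or
unparseable value numerically yields false and records a diagnostic —
missing data never silently fires a rule.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

from .variants import VariantRow, row_field

__all__ = [
    "SchemeError",
    "ExpressionError",
    "Scheme",
    "Category",
    "Entry",
    "ThresholdSpec",
    "Cutoffs",
    "ScoreResult",
    "compile_expression",
    "parse_scheme",
    "load_scheme",
    "scheme_to_json",
    "eval_expr",
    "score_variant",
    "classify",
    "list_controls",
    "score_table",
]


class SchemeError(ValueError):
    """Structurally invalid scheme document; message carries a JSON path."""


class ExpressionError(ValueError):
    """Syntax or reference error in a leaf expression."""


# ---------------------------------------------------------------------------
# expression tokenizer / recursive-descent parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<number>\d+\.\d*|\.\d+|\d+)
      | (?P<string>'[^']*'|"[^"]*")
      | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
      | (?P<op><=|>=|==|!=|<|>|\(|\)|,|-)
    )""",
    re.VERBOSE,
)

_CMP_OPS = {"<", "<=", ">", ">=", "==", "!="}
_FUNCTIONS = {"x": 1, "th": 1, "isEmpty": 1, "stringContains": 2, "state": 1}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens, i = [], 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if not m or m.end() == i:
            if text[i:].strip():
                raise ExpressionError(f"bad character at position {i}: {text[i:i+10]!r}")
            break
        i = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
    return tokens


@dataclass
class Node:
    kind: str  # and/or/not/cmp/call/num/str/bool
    value: Any = None
    children: list["Node"] = field(default_factory=list)


class _Parser:
    """expr := or ; or := and ('or' and)* ; and := unary ('and' unary)* ;
    unary := 'not' unary | cmp ; cmp := atom (OP atom)? ;
    atom := literal | call | '(' expr ')'"""

    def __init__(self, text: str, allow_state: bool = False):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0
        self.allow_state = allow_state

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise ExpressionError(f"unexpected end of expression: {self.text!r}")
        self.i += 1
        return tok

    def _expect(self, value: str):
        tok = self._next()
        if tok[1] != value:
            raise ExpressionError(
                f"expected {value!r} at position {tok[2]} in {self.text!r}, got {tok[1]!r}"
            )

    def parse(self) -> Node:
        node = self._or()
        if self._peek() is not None:
            tok = self._peek()
            raise ExpressionError(
                f"trailing input at position {tok[2]} in {self.text!r}: {tok[1]!r}"
            )
        return node

    def _or(self) -> Node:
        node = self._and()
        while self._peek() and self._peek()[:2] == ("name", "or"):
            self._next()
            node = Node("or", children=[node, self._and()])
        return node

    def _and(self) -> Node:
        node = self._unary()
        while self._peek() and self._peek()[:2] == ("name", "and"):
            self._next()
            node = Node("and", children=[node, self._unary()])
        return node

    def _unary(self) -> Node:
        if self._peek() and self._peek()[:2] == ("name", "not"):
            self._next()
            return Node("not", children=[self._unary()])
        return self._cmp()

    def _cmp(self) -> Node:
        left = self._atom()
        tok = self._peek()
        if tok and tok[0] == "op" and tok[1] in _CMP_OPS:
            op = self._next()[1]
            right = self._atom()
            return Node("cmp", op, [left, right])
        return left

    def _atom(self) -> Node:
        tok = self._next()
        kind, value, pos = tok
        if kind == "number":
            return Node("num", float(value))
        if kind == "string":
            return Node("str", value[1:-1])
        if kind == "op" and value == "-":  # negative number literal
            tok2 = self._next()
            if tok2[0] != "number":
                raise ExpressionError(
                    f"'-' must precede a number (position {tok2[2]})"
                )
            return Node("num", -float(tok2[1]))
        if kind == "op" and value == "(":
            node = self._or()
            self._expect(")")
            return node
        if kind == "name":
            if value in ("true", "false"):
                return Node("bool", value == "true")
            if value in _FUNCTIONS:
                if value == "state" and not self.allow_state:
                    raise ExpressionError(
                        f"state() is only available in diagnostic rules (position {pos})"
                    )
                self._expect("(")
                args = [self._or()]
                for _ in range(_FUNCTIONS[value] - 1):
                    self._expect(",")
                    args.append(self._or())
                self._expect(")")
                if value in ("x", "th", "state") and args[0].kind != "str":
                    raise ExpressionError(
                        f"{value}() takes a quoted name (position {pos})"
                    )
                return Node("call", value, args)
            raise ExpressionError(f"unknown identifier {value!r} at position {pos}")
        raise ExpressionError(f"unexpected token {value!r} at position {pos}")


@dataclass
class CompiledExpression:
    """A parsed leaf expression plus the column/threshold/site names it uses."""

    source: str
    root: Node
    columns: frozenset[str]
    thresholds: frozenset[str]
    sites: frozenset[str]

    def evaluate(
        self,
        get_column: Callable[[str], str],
        thresholds: Mapping[str, float] | None = None,
        get_state: Callable[[str], str] | None = None,
        diagnostics: list[str] | None = None,
    ) -> bool:
        return bool(
            _eval_node(self.root, get_column, thresholds or {}, get_state, diagnostics)
        )


def compile_expression(text: str, allow_state: bool = False) -> CompiledExpression:
    if not isinstance(text, str) or not text.strip():
        raise ExpressionError("empty expression")
    root = _Parser(text, allow_state=allow_state).parse()
    cols, ths, sites = set(), set(), set()

    def walk(n: Node) -> None:
        if n.kind == "call":
            name = n.value
            target = n.children[0].value if n.children[0].kind == "str" else None
            if name == "x" and target is not None:
                cols.add(target)
            elif name == "th" and target is not None:
                ths.add(target)
            elif name == "state" and target is not None:
                sites.add(target)
        for c in n.children:
            walk(c)

    walk(root)
    return CompiledExpression(text, root, frozenset(cols), frozenset(ths), frozenset(sites))


def _as_number(value: Any) -> float | None:
    if isinstance(value, bool):
        return float(value)
    if isinstance(value, float):
        return value
    try:
        return float(str(value).strip())
    except (ValueError, TypeError):
        return None


def _eval_node(node, get_column, thresholds, get_state, diagnostics):
    k = node.kind
    if k == "num":
        return node.value
    if k == "str":
        return node.value
    if k == "bool":
        return node.value
    if k == "and":
        return all(bool(_eval_node(c, get_column, thresholds, get_state, diagnostics)) for c in node.children)
    if k == "or":
        return any(bool(_eval_node(c, get_column, thresholds, get_state, diagnostics)) for c in node.children)
    if k == "not":
        return not bool(_eval_node(node.children[0], get_column, thresholds, get_state, diagnostics))
    if k == "call":
        args = [
            _eval_node(c, get_column, thresholds, get_state, diagnostics)
            for c in node.children
        ]
        if node.value == "x":
            return get_column(str(args[0]))
        if node.value == "th":
            name = str(args[0])
            if name not in thresholds:
                raise ExpressionError(f"undeclared threshold {name!r}")
            return float(thresholds[name])
        if node.value == "isEmpty":
            return str(args[0]) == ""
        if node.value == "stringContains":
            return str(args[1]) in str(args[0])
        if node.value == "state":
            if get_state is None:
                raise ExpressionError("state() not available in this context")
            return get_state(str(args[0]))
    if k == "cmp":
        left = _eval_node(node.children[0], get_column, thresholds, get_state, diagnostics)
        right = _eval_node(node.children[1], get_column, thresholds, get_state, diagnostics)
        op = node.value
        ln, rn = _as_number(left), _as_number(right)
        if op in ("==", "!="):
            # numeric equality when both sides parse, string equality otherwise
            equal = ln == rn if (ln is not None and rn is not None) else str(left) == str(right)
            return equal if op == "==" else not equal
        if ln is None or rn is None:
            # ordering against a missing/unparseable value is false, recorded
            if diagnostics is not None:
                bad = left if ln is None else right
                diagnostics.append(f"non-numeric value {bad!r} in comparison {op}")
            return False
        ops = {
            "<": lambda a, b: a < b,
            "<=": lambda a, b: a <= b,
            ">": lambda a, b: a > b,
            ">=": lambda a, b: a >= b,
        }
        return ops[op](ln, rn)
    raise AssertionError(f"unhandled node kind {k}")


# ---------------------------------------------------------------------------
# scheme document model
# ---------------------------------------------------------------------------


@dataclass
class ThresholdSpec:
    name: str
    default: float
    min: float
    max: float
    description: str = ""

    def __post_init__(self) -> None:
        if not (self.min <= self.default <= self.max):
            raise SchemeError(
                f"threshold {self.name!r}: require min <= default <= max "
                f"({self.min} <= {self.default} <= {self.max})"
            )


@dataclass
class ConditionTree:
    """AND/OR combinator over compiled leaf expressions."""

    op: str | None  # "AND", "OR" or None for a leaf
    children: list["ConditionTree"] = field(default_factory=list)
    leaf: CompiledExpression | None = None

    def fires(self, get_column, thresholds, diagnostics=None) -> bool:
        if self.leaf is not None:
            return self.leaf.evaluate(get_column, thresholds, None, diagnostics)
        results = (c.fires(get_column, thresholds, diagnostics) for c in self.children)
        return all(results) if self.op == "AND" else any(results)

    def expressions(self) -> list[CompiledExpression]:
        if self.leaf is not None:
            return [self.leaf]
        return [e for c in self.children for e in c.expressions()]


@dataclass
class Entry:
    id: str
    label: str
    condition: ConditionTree
    artifact_weight: float = 0.0
    polymorphism_weight: float = 0.0
    active: bool = True

    def __post_init__(self) -> None:
        if self.artifact_weight < 0 or self.polymorphism_weight < 0:
            raise SchemeError(f"entry {self.id!r}: weights must be >= 0")
        if self.artifact_weight + self.polymorphism_weight <= 0:
            raise SchemeError(
                f"entry {self.id!r}: must contribute to at least one score"
            )


@dataclass
class Category:
    name: str
    entries: list[Entry]


@dataclass
class Cutoffs:
    artifact_cutoff: float = 1.0
    polymorphism_cutoff: float = 1.0


@dataclass
class Scheme:
    name: str
    version: str
    categories: list[Category]
    thresholds: dict[str, ThresholdSpec] = field(default_factory=dict)
    cutoffs: Cutoffs = field(default_factory=Cutoffs)

    @property
    def entries(self) -> list[Entry]:
        return [e for c in self.categories for e in c.entries]

    def entry(self, entry_id: str) -> Entry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise SchemeError(f"unknown entry id {entry_id!r}")

    def referenced_columns(self) -> frozenset[str]:
        cols: set[str] = set()
        for e in self.entries:
            for expr in e.condition.expressions():
                cols |= expr.columns
        return frozenset(cols)


# ---------------------------------------------------------------------------
# parsing & serialization
# ---------------------------------------------------------------------------


def _parse_condition(obj: Any, path: str) -> ConditionTree:
    if not isinstance(obj, dict):
        raise SchemeError(f"{path}: condition must be an object")
    if "expr" in obj:
        try:
            return ConditionTree(None, leaf=compile_expression(obj["expr"]))
        except ExpressionError as exc:
            raise SchemeError(f"{path}.expr: {exc}") from exc
    op = obj.get("op")
    if op not in ("AND", "OR"):
        raise SchemeError(f"{path}.op: must be 'AND' or 'OR', got {op!r}")
    children = obj.get("children")
    if not isinstance(children, list) or len(children) < 2:
        raise SchemeError(f"{path}.children: an {op} node needs >= 2 children")
    return ConditionTree(
        op,
        [_parse_condition(c, f"{path}.children[{i}]") for i, c in enumerate(children)],
    )


def parse_scheme(document: str | Mapping[str, Any]) -> Scheme:
    """Parse and fully validate an SSDL JSON document.

    Violations raise :class:`SchemeError` with a JSON-path location.  All
    leaf expressions are compiled here; evaluation never parses text.
    """
    if isinstance(document, str):
        data = json.loads(document)
    else:
        data = dict(document)
    if not isinstance(data, dict):
        raise SchemeError("$: scheme document must be a JSON object")

    thresholds: dict[str, ThresholdSpec] = {}
    for name, spec in (data.get("thresholds") or {}).items():
        path = f"$.thresholds.{name}"
        if not isinstance(spec, dict) or "default" not in spec:
            raise SchemeError(f"{path}: needs at least a 'default' value")
        try:
            thresholds[name] = ThresholdSpec(
                name=name,
                default=float(spec["default"]),
                min=float(spec.get("min", spec["default"])),
                max=float(spec.get("max", spec["default"])),
                description=str(spec.get("description", "")),
            )
        except SchemeError as exc:
            raise SchemeError(f"{path}: {exc}") from exc

    raw_categories = data.get("categories")
    if not isinstance(raw_categories, list) or not raw_categories:
        raise SchemeError("$.categories: a scheme needs at least one category")

    categories: list[Category] = []
    seen_ids: set[str] = set()
    for ci, cat in enumerate(raw_categories):
        cpath = f"$.categories[{ci}]"
        if not isinstance(cat, dict) or not cat.get("name"):
            raise SchemeError(f"{cpath}: category needs a name")
        raw_entries = cat.get("entries")
        if not isinstance(raw_entries, list) or not raw_entries:
            raise SchemeError(f"{cpath}.entries: a category needs at least one entry")
        entries = []
        for ei, ent in enumerate(raw_entries):
            epath = f"{cpath}.entries[{ei}]"
            if not isinstance(ent, dict) or not ent.get("id"):
                raise SchemeError(f"{epath}: entry needs an id")
            if ent["id"] in seen_ids:
                raise SchemeError(f"{epath}.id: duplicate entry id {ent['id']!r}")
            seen_ids.add(ent["id"])
            if "condition" not in ent:
                raise SchemeError(f"{epath}: entry needs a condition")
            condition = _parse_condition(ent["condition"], f"{epath}.condition")
            try:
                entry = Entry(
                    id=str(ent["id"]),
                    label=str(ent.get("label", ent["id"])),
                    condition=condition,
                    artifact_weight=float(ent.get("artifact_weight", 0.0)),
                    polymorphism_weight=float(ent.get("polymorphism_weight", 0.0)),
                    active=bool(ent.get("active", True)),
                )
            except SchemeError as exc:
                raise SchemeError(f"{epath}: {exc}") from exc
            entries.append(entry)
        categories.append(Category(str(cat["name"]), entries))

    raw_cutoffs = data.get("cutoffs") or {}
    cutoffs = Cutoffs(
        artifact_cutoff=float(raw_cutoffs.get("artifact_cutoff", 1.0)),
        polymorphism_cutoff=float(raw_cutoffs.get("polymorphism_cutoff", 1.0)),
    )

    scheme = Scheme(
        name=str(data.get("name", "unnamed")),
        version=str(data.get("version", "0")),
        categories=categories,
        thresholds=thresholds,
        cutoffs=cutoffs,
    )

    # every referenced threshold must be declared
    for e in scheme.entries:
        for expr in e.condition.expressions():
            missing = expr.thresholds - set(thresholds)
            if missing:
                raise SchemeError(
                    f"entry {e.id!r}: undeclared threshold(s) {sorted(missing)} "
                    f"in expression {expr.source!r}"
                )
    return scheme


def load_scheme(path: str) -> Scheme:
    with open(path, encoding="utf-8") as fh:
        return parse_scheme(fh.read())


def _condition_to_json(tree: ConditionTree) -> dict:
    if tree.leaf is not None:
        return {"expr": tree.leaf.source}
    return {"op": tree.op, "children": [_condition_to_json(c) for c in tree.children]}


def scheme_to_json(scheme: Scheme) -> str:
    """Serialize a scheme; parse(serialize(s)) equals s."""
    doc = {
        "name": scheme.name,
        "version": scheme.version,
        "categories": [
            {
                "name": c.name,
                "entries": [
                    {
                        "id": e.id,
                        "label": e.label,
                        "active": e.active,
                        "artifact_weight": e.artifact_weight,
                        "polymorphism_weight": e.polymorphism_weight,
                        "condition": _condition_to_json(e.condition),
                    }
                    for e in c.entries
                ],
            }
            for c in scheme.categories
        ],
        "thresholds": {
            t.name: {
                "default": t.default,
                "min": t.min,
                "max": t.max,
                "description": t.description,
            }
            for t in scheme.thresholds.values()
        },
        "cutoffs": {
            "artifact_cutoff": scheme.cutoffs.artifact_cutoff,
            "polymorphism_cutoff": scheme.cutoffs.polymorphism_cutoff,
        },
    }
    return json.dumps(doc, indent=2, sort_keys=False)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def eval_expr(
    expr: str | CompiledExpression,
    row: VariantRow,
    thresholds: Mapping[str, float] | None = None,
    diagnostics: list[str] | None = None,
) -> bool:
    """Evaluate one leaf expression against a variant row."""
    compiled = expr if isinstance(expr, CompiledExpression) else compile_expression(expr)
    return compiled.evaluate(lambda c: row_field(row, c), thresholds, None, diagnostics)


@dataclass
class ScoreResult:
    a_score: float
    p_score: float
    fired_artifact: list[str] = field(default_factory=list)
    fired_polymorphism: list[str] = field(default_factory=list)


def _resolve_overrides(
    scheme: Scheme, overrides: Mapping[str, Any] | None
) -> tuple[dict[str, bool], dict[str, float]]:
    active = {e.id: e.active for e in scheme.entries}
    values = {t.name: t.default for t in scheme.thresholds.values()}
    if not overrides:
        return active, values
    for eid, flag in (overrides.get("entries") or {}).items():
        if eid not in active:
            raise SchemeError(f"override references unknown entry {eid!r}")
        active[eid] = bool(flag)
    for name, value in (overrides.get("thresholds") or {}).items():
        if name not in values:
            raise SchemeError(f"override references unknown threshold {name!r}")
        spec = scheme.thresholds[name]
        if not (spec.min <= float(value) <= spec.max):
            raise SchemeError(
                f"threshold {name!r} override {value} outside [{spec.min}, {spec.max}]"
            )
        values[name] = float(value)
    return active, values


def score_variant(
    scheme: Scheme,
    row: VariantRow,
    overrides: Mapping[str, Any] | None = None,
    diagnostics: list[str] | None = None,
) -> ScoreResult:
    """Sum the weights of all fired, active entries into A/P scores.

    An entry fires at most once regardless of its condition-tree size; an
    inactive entry contributes nothing.  ``overrides`` is
    ``{"entries": {id: bool}, "thresholds": {name: value}}``.
    """
    active, th_values = _resolve_overrides(scheme, overrides)
    result = ScoreResult(0.0, 0.0)
    get = lambda c: row_field(row, c)
    for entry in scheme.entries:
        if not active[entry.id]:
            continue
        if entry.condition.fires(get, th_values, diagnostics):
            if entry.artifact_weight > 0:
                result.a_score += entry.artifact_weight
                result.fired_artifact.append(entry.id)
            if entry.polymorphism_weight > 0:
                result.p_score += entry.polymorphism_weight
                result.fired_polymorphism.append(entry.id)
    return result


def classify(score: ScoreResult, cutoffs: Cutoffs) -> str:
    """Inclusive cutoffs: a score exactly at the cutoff triggers the label."""
    is_artifact = score.a_score >= cutoffs.artifact_cutoff
    is_poly = score.p_score >= cutoffs.polymorphism_cutoff
    if is_artifact and is_poly:
        return "artifact_and_polymorphism"
    if is_artifact:
        return "artifact"
    if is_poly:
        return "polymorphism"
    return "pass"


def list_controls(scheme: Scheme) -> list[dict[str, Any]]:
    """Descriptors from which a settings panel can be reconstructed.

    One descriptor per entry (checkbox) and one per threshold (slider), in
    deterministic scheme order.
    """
    controls: list[dict[str, Any]] = []
    for cat in scheme.categories:
        for e in cat.entries:
            controls.append(
                {
                    "kind": "entry",
                    "id": e.id,
                    "label": e.label,
                    "category": cat.name,
                    "active": e.active,
                    "artifact_weight": e.artifact_weight,
                    "polymorphism_weight": e.polymorphism_weight,
                }
            )
    for name in sorted(scheme.thresholds):
        t = scheme.thresholds[name]
        controls.append(
            {
                "kind": "threshold",
                "name": t.name,
                "default": t.default,
                "min": t.min,
                "max": t.max,
                "description": t.description,
            }
        )
    return controls


def score_table(scheme, table, overrides=None):
    """Score every row of a variant table and set classifications.

    Column references are checked against the table's registry (plus the
    built-in quality columns) before any row is evaluated, so a typo in a
    scheme fails fast rather than silently reading empty strings.
    Returns a new table; the input is unmodified.
    """
    from .variants import BUILTIN_COLUMNS, VariantTable

    known = set(BUILTIN_COLUMNS) | set(table.column_registry)
    unknown = scheme.referenced_columns() - known
    if unknown:
        raise SchemeError(
            f"scheme references unregistered column(s) {sorted(unknown)}; "
            f"known columns: {sorted(known)}"
        )
    out = table.copy()
    for r in out.rows:
        s = score_variant(scheme, r, overrides)
        r.a_score = s.a_score
        r.p_score = s.p_score
        r.classification = classify(s, scheme.cutoffs)
    return out
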