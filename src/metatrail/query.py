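"""Search, reporting and export over materialized entity state.

Queries are small boolean trees: leaves apply one operator — ``equal``
(exact match on normalized text), ``like`` (case-insensitive substring) or
``in`` (membership in a list) — to one field or globally to any attribute;
inner nodes combine children with AND / OR / NOT.  Evaluation is a plain
entity-by-entity scan over current state, which *is* the contract: the
property tests compare it against nothing cleverer than itself re-derived.

Search runs over materialized current state only; time travel lives in
:meth:`MetadataStore.event_history`.
"""
from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

from .errors import QueryError, UsageError
from .model import PROJECT_NAME_FIELD, SAMPLE_NAME_FIELD

#: leaf field sentinel: match if any attribute satisfies the predicate
GLOBAL = "*"

OPS = ("equal", "like", "in")
CONNECTIVES = ("AND", "OR", "NOT")


@dataclass(frozen=True)
class Leaf:
    field: str                      # field name or GLOBAL
    op: str                         # equal | like | in
    operand: Union[str, tuple[str, ...]]

    def __post_init__(self):
        if self.op not in OPS:
            raise QueryError(f"unknown operator {self.op!r}")
        if self.op == "in":
            if not isinstance(self.operand, (tuple, list)) or not self.operand:
                raise QueryError("'in' requires a non-empty operand list")
            object.__setattr__(self, "operand", tuple(self.operand))
        elif not isinstance(self.operand, str):
            raise QueryError(f"{self.op!r} requires a text operand")


@dataclass(frozen=True)
class Node:
    connective: str                 # AND | OR | NOT
    children: tuple["QueryExpr", ...]

    def __post_init__(self):
        if self.connective not in CONNECTIVES:
            raise QueryError(f"unknown connective {self.connective!r}")
        object.__setattr__(self, "children", tuple(self.children))
        if self.connective == "NOT" and len(self.children) != 1:
            raise QueryError("NOT takes exactly one child")
        if self.connective != "NOT" and not self.children:
            raise QueryError(f"{self.connective} needs at least one child")


QueryExpr = Union[Leaf, Node]


def _leaf_matches(leaf: Leaf, value: Optional[str]) -> bool:
    if value is None:
        return False
    if leaf.op == "equal":
        return value == leaf.operand
    if leaf.op == "like":
        return leaf.operand.lower() in value.lower()
    return value in leaf.operand   # in


def evaluate(query: QueryExpr, attributes: dict[str, str]) -> bool:
    """Evaluate a query tree against one entity's field→value mapping."""
    if isinstance(query, Leaf):
        if query.field == GLOBAL:
            return any(_leaf_matches(query, v) for v in attributes.values())
        return _leaf_matches(query, attributes.get(query.field))
    if query.connective == "NOT":
        return not evaluate(query.children[0], attributes)
    if query.connective == "AND":
        return all(evaluate(c, attributes) for c in query.children)
    return any(evaluate(c, attributes) for c in query.children)


def _known_fields(store, project_names) -> set[str]:
    known = {PROJECT_NAME_FIELD, SAMPLE_NAME_FIELD}
    for t in store.list_templates():
        known.update(f.name for f in t.fields)
    return known


def _check_fields(query: QueryExpr, known: set[str]) -> None:
    if isinstance(query, Leaf):
        if query.field != GLOBAL and query.field not in known:
            raise QueryError(f"unknown field {query.field!r} in query")
    else:
        for c in query.children:
            _check_fields(c, known)


def _entity_attributes(store, project: str, sample: str) -> dict[str, str]:
    """Current state plus the virtual identity columns."""
    attrs = dict(store.current_state(project, sample))
    attrs[PROJECT_NAME_FIELD] = project
    attrs[SAMPLE_NAME_FIELD] = sample
    return attrs


def _visible_projects(store, project, caller) -> list[str]:
    from .errors import NotFoundError
    if project is not None:
        if store.get_project(project) is None:
            raise NotFoundError(f"unknown project {project!r}")
        store._require_role(caller, project, "view")
        return [project]
    if store.is_admin(caller):
        return store.list_projects()
    return [p for p in store.list_projects()
            if store.role_on(caller, p) is not None]


def search(store, query: QueryExpr, caller: str,
           project: Optional[str] = None) -> list[tuple[str, str, dict[str, str]]]:
    """Run a query over the samples of one project (or every project the
    caller may view).  Returns ``(project, sample, attributes)`` triples
    ordered by entity name."""
    projects = _visible_projects(store, project, caller)
    _check_fields(query, _known_fields(store, projects))
    hits = []
    for p in projects:
        for s in store.list_samples(p):
            attrs = _entity_attributes(store, p, s)
            if evaluate(query, attrs):
                hits.append((p, s, attrs))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def default_export_fields(store, project: Optional[str] = None) -> list[str]:
    """Column order for a full export: identity columns first, then the
    union of active sample-scope fields in (template, position) order."""
    fields = [PROJECT_NAME_FIELD, SAMPLE_NAME_FIELD]
    for t in store.list_templates():
        if t.scope != "sample":
            continue
        for f in t.ordered_fields(active_only=True):
            if f.name not in fields:
                fields.append(f.name)
    return fields


def _export_rows(store, project, fields, caller):
    if store.get_project(project) is None:
        from .errors import NotFoundError
        raise NotFoundError(f"unknown project {project!r}")
    store._require_role(caller, project, "view")
    known = _known_fields(store, [project])
    for f in fields:
        if f not in known:
            raise QueryError(f"unknown field {f!r} in export")
    for s in store.list_samples(project):
        attrs = _entity_attributes(store, project, s)
        yield [attrs.get(f, "") for f in fields]


def export_csv(store, project: str, caller: str,
               fields: Optional[Sequence[str]] = None) -> str:
    """One CSV row per sample in name order, with the requested columns
    (default: all active sample fields)."""
    fields = list(fields) if fields else default_export_fields(store)
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(fields)
    for row in _export_rows(store, project, fields, caller):
        w.writerow(row)
    return buf.getvalue()


def export_json(store, project: str, caller: str,
                fields: Optional[Sequence[str]] = None) -> str:
    """JSON array of flat objects, keys in field (position) order."""
    fields = list(fields) if fields else default_export_fields(store)
    objs = [dict(zip(fields, row))
            for row in _export_rows(store, project, fields, caller)]
    return json.dumps(objs, indent=2, ensure_ascii=False)


@dataclass
class Report:
    """A generated report: a header plus rows of text cells."""

    header: list[str]
    rows: list[list[str]] = dc_field(default_factory=list)

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(self.header)
        for r in self.rows:
            w.writerow(r)
        return buf.getvalue()


def generate_report(store, project: str, caller: str,
                    template: Optional[str] = None,
                    fields: Optional[Sequence[str]] = None) -> Report:
    """Event-selector reports give one row per event record of that
    template (its values plus actor and timestamp); field-selector reports
    are equivalent to an export over those fields."""
    if (template is None) == (fields is None):
        raise UsageError("select either an event template or a field list")
    if fields is not None:
        header = list(fields)
        report = Report(header=header)
        for row in _export_rows(store, project, header, caller):
            report.rows.append(row)
        return report
    t = store.get_template(template)
    cols = [f.name for f in t.ordered_fields(active_only=True)]
    report = Report(header=cols + ["actor", "timestamp"])
    for rec in store.event_history(caller, project=project, template=template):
        values = {v.field: v.raw for v in rec.values}
        report.rows.append([values.get(c, "") for c in cols]
                           + [rec.actor, rec.timestamp])
    return report


# --------------------------------------------------------------------------
# tiny query grammar for the command line:
#   expr   := term (OR term)*
#   term   := factor (AND factor)*
#   factor := NOT factor | '(' expr ')' | leaf
#   leaf   := FIELD op VALUE ;  op := equal | like | in
#   FIELD  := bare word or "quoted string" or * (global)
#   VALUE  := "quoted string", or ("a","b",...) for in
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r'\s*(?:(\()|(\))|(,)|"((?:[^"\\]|\\.)*)"|([^\s(),"]+))')


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            rest = text[pos:].strip()
            if not rest:
                break
            raise QueryError(f"cannot tokenize query near {rest!r}")
        pos = m.end()
        if m.group(1):
            tokens.append(("punct", "("))
        elif m.group(2):
            tokens.append(("punct", ")"))
        elif m.group(3):
            tokens.append(("punct", ","))
        elif m.group(4) is not None:
            tokens.append(("string", m.group(4).replace('\\"', '"')))
        elif m.group(5):
            tokens.append(("word", m.group(5)))
    return tokens


class _Parser:
    def __init__(self, tokens):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect_punct(self, p):
        kind, val = self.next()
        if kind != "punct" or val != p:
            raise QueryError(f"expected {p!r}, got {val!r}")

    def parse(self) -> QueryExpr:
        expr = self.expr()
        if self.i != len(self.tokens):
            raise QueryError(f"trailing tokens after query: "
                             f"{self.tokens[self.i:]!r}")
        return expr

    def expr(self) -> QueryExpr:
        children = [self.term()]
        while self.peek() == ("word", "OR"):
            self.next()
            children.append(self.term())
        return children[0] if len(children) == 1 else Node("OR", tuple(children))

    def term(self) -> QueryExpr:
        children = [self.factor()]
        while self.peek() == ("word", "AND"):
            self.next()
            children.append(self.factor())
        return children[0] if len(children) == 1 else Node("AND", tuple(children))

    def factor(self) -> QueryExpr:
        kind, val = self.peek()
        if (kind, val) == ("word", "NOT"):
            self.next()
            return Node("NOT", (self.factor(),))
        if (kind, val) == ("punct", "("):
            self.next()
            inner = self.expr()
            self.expect_punct(")")
            return inner
        return self.leaf()

    def leaf(self) -> Leaf:
        kind, field = self.next()
        if kind not in ("word", "string"):
            raise QueryError(f"expected a field name, got {field!r}")
        kind, op = self.next()
        if kind != "word" or op not in OPS:
            raise QueryError(f"expected one of {OPS}, got {op!r}")
        if op == "in":
            self.expect_punct("(")
            values = []
            while True:
                k, v = self.next()
                if k not in ("word", "string"):
                    raise QueryError(f"expected a value, got {v!r}")
                values.append(v)
                k, v = self.next()
                if (k, v) == ("punct", ")"):
                    break
                if (k, v) != ("punct", ","):
                    raise QueryError(f"expected ',' or ')', got {v!r}")
            return Leaf(field=field, op="in", operand=tuple(values))
        k, v = self.next()
        if k not in ("word", "string"):
            raise QueryError(f"expected a value, got {v!r}")
        return Leaf(field=field, op=op, operand=v)


def parse_query(text: str) -> QueryExpr:
    """Parse the CLI query grammar into a query tree."""
    tokens = _tokenize(text)
    if not tokens:
        raise QueryError("empty query")
    return _Parser(tokens).parse()


def query_from_json(data) -> QueryExpr:
    """Build a query tree from the JSON form:
    ``{"op": ..., "field": ..., "operand": ...}`` leaves and
    ``{"connective": ..., "children": [...]}`` nodes."""
    if isinstance(data, str):
        data = json.loads(data)
    if not isinstance(data, dict):
        raise QueryError("query JSON must be an object")
    if "connective" in data:
        children = tuple(query_from_json(c) for c in data.get("children", []))
        return Node(data["connective"], children)
    try:
        operand = data["operand"]
        if isinstance(operand, list):
            operand = tuple(operand)
        return Leaf(field=data.get("field", GLOBAL), op=data["op"],
                    operand=operand)
    except KeyError as exc:
        raise QueryError(f"query JSON leaf missing key: {exc}") from exc
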