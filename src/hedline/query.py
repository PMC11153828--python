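"""Abstraction-aware search over annotations and factor-vector extraction.

A :class:`TermQuery` matches any tag that *is a* (descendant of) the query
term, so searching for ``2D-shape`` finds ``Triangle`` as well as user
extensions like ``2D-shape/Star``.  A :class:`GroupQuery` requires its
sub-queries to be satisfied among the direct children of one group —
grouping expresses association, so ``(Red, Triangle)`` (a red triangle) is
distinct from ``Red, (Blue, Triangle)``.

Surface syntax (case-insensitive keywords)::

    Sensory-event AND NOT (Target)        # boolean combinators
    (Red, Triangle)                       # comma list in parens = group query

``Not`` may appear only inside an ``And`` conjunction, which rules out
match-everything queries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .bids_io import AnnotatedFile
from .errors import ErrorCode, QueryError
from .schema import Schema, is_descendant
from .strings import HedGroup, HedString, HedTag
from .timeline import context_at


class Query:
    _is_query = True


@dataclass
class TermQuery(Query):
    term: str
    _resolved: str | None = field(default=None, repr=False, compare=False)

    def resolved(self, schema: Schema) -> str:
        if self._resolved is None:
            try:
                self._resolved = schema.resolve_tag(self.term).long_form
            except Exception as exc:
                raise QueryError(
                    ErrorCode.QUERY_BAD_TERM,
                    f"query term {self.term!r} is not resolvable: {exc}",
                ) from exc
        return self._resolved


@dataclass
class GroupQuery(Query):
    subqueries: list[Query]


@dataclass
class And(Query):
    items: list[Query]


@dataclass
class Or(Query):
    items: list[Query]


@dataclass
class Not(Query):
    item: Query


def validate_query(q: Query, under_and: bool = False) -> None:
    """Enforce the Not-only-under-And invariant."""
    if isinstance(q, Not):
        if not under_and:
            raise QueryError(ErrorCode.QUERY_SYNTAX,
                             "NOT may appear only inside an AND conjunction")
        validate_query(q.item, under_and=False)
    elif isinstance(q, And):
        for item in q.items:
            validate_query(item, under_and=True)
    elif isinstance(q, Or):
        for item in q.items:
            validate_query(item, under_and=False)
    elif isinstance(q, GroupQuery):
        for item in q.subqueries:
            validate_query(item, under_and=False)


# ----------------------------------------------------------------------
# surface-syntax parser

_TOKEN_RE = re.compile(r"\(|\)|,|[^\s(),]+")


def parse_query(text: str) -> Query:
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        raise QueryError(ErrorCode.QUERY_SYNTAX, "empty query")
    q, pos = _parse_or(tokens, 0)
    if pos != len(tokens):
        raise QueryError(ErrorCode.QUERY_SYNTAX,
                         f"unexpected token {tokens[pos]!r}")
    validate_query(q)
    return q


def _parse_or(tokens, pos):
    left, pos = _parse_and(tokens, pos)
    items = [left]
    while pos < len(tokens) and tokens[pos].upper() == "OR":
        nxt, pos = _parse_and(tokens, pos + 1)
        items.append(nxt)
    return (items[0] if len(items) == 1 else Or(items)), pos


def _parse_and(tokens, pos):
    left, pos = _parse_unary(tokens, pos)
    items = [left]
    while pos < len(tokens) and tokens[pos].upper() == "AND":
        nxt, pos = _parse_unary(tokens, pos + 1)
        items.append(nxt)
    return (items[0] if len(items) == 1 else And(items)), pos


def _parse_unary(tokens, pos):
    if pos < len(tokens) and tokens[pos].upper() == "NOT":
        inner, pos = _parse_primary(tokens, pos + 1)
        return Not(inner), pos
    return _parse_primary(tokens, pos)


def _parse_primary(tokens, pos):
    if pos >= len(tokens):
        raise QueryError(ErrorCode.QUERY_SYNTAX, "unexpected end of query")
    tok = tokens[pos]
    if tok == "(":
        items = []
        pos += 1
        q, pos = _parse_or(tokens, pos)
        items.append(q)
        while pos < len(tokens) and tokens[pos] == ",":
            q, pos = _parse_or(tokens, pos + 1)
            items.append(q)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise QueryError(ErrorCode.QUERY_SYNTAX, "unbalanced '(' in query")
        pos += 1
        if len(items) == 1:
            return items[0], pos  # plain precedence parentheses
        return GroupQuery(items), pos
    if tok in (")", ",") or tok.upper() in ("AND", "OR", "NOT"):
        raise QueryError(ErrorCode.QUERY_SYNTAX, f"unexpected token {tok!r}")
    return TermQuery(tok), pos + 1


# ----------------------------------------------------------------------
# matching


def _tag_matches(tag: HedTag, q: TermQuery, schema: Schema) -> bool:
    term_long = q.resolved(schema)
    if tag.path is not None and tag.path.rsplit("/", 1)[-1].lower() == "description":
        # free-text descriptions are filtered out of search unless the
        # query explicitly targets Description
        if term_long.split("/")[0].lower() != "description" and \
                not term_long.lower().endswith("description"):
            return False
    return is_descendant(tag.long_form, term_long)


def _group_satisfies(group: HedGroup, q: Query, schema: Schema) -> bool:
    """Does ``group`` satisfy ``q`` among its *direct* children?"""
    if isinstance(q, TermQuery):
        return any(_tag_matches(c, q, schema)
                   for c in group.children if isinstance(c, HedTag))
    if isinstance(q, GroupQuery):
        return any(
            isinstance(c, HedGroup)
            and all(_group_satisfies(c, sq, schema) for sq in q.subqueries)
            for c in group.children)
    if isinstance(q, And):
        return all(_group_satisfies(group, i, schema) for i in q.items)
    if isinstance(q, Or):
        return any(_group_satisfies(group, i, schema) for i in q.items)
    if isinstance(q, Not):
        return not _group_satisfies(group, q.item, schema)
    raise TypeError(f"unknown query node {q!r}")


def matches(annotation: HedString, q: Query, schema: Schema) -> bool:
    """Evaluate a query against one resolved annotation."""
    validate_query(q)
    return _matches(annotation, q, schema)


def _matches(annotation: HedString, q: Query, schema: Schema) -> bool:
    if isinstance(q, TermQuery):
        return any(_tag_matches(t, q, schema) for t in annotation.tags())
    if isinstance(q, GroupQuery):
        scopes = [annotation.as_group()] + list(annotation.groups())
        return any(
            all(_group_satisfies(g, sq, schema) for sq in q.subqueries)
            for g in scopes)
    if isinstance(q, And):
        return all(_matches(annotation, i, schema) for i in q.items)
    if isinstance(q, Or):
        return any(_matches(annotation, i, schema) for i in q.items)
    if isinstance(q, Not):
        return not _matches(annotation, q.item, schema)
    raise TypeError(f"unknown query node {q!r}")


# ----------------------------------------------------------------------
# dataset search


@dataclass
class Hit:
    file: str
    row: int
    time: float
    annotation: HedString


def _as_query(q) -> Query:
    return parse_query(q) if isinstance(q, str) else q


def enriched_annotation(marker_annotation: HedString, timeline,
                        t: float) -> HedString:
    """Marker annotation augmented with the annotations of all processes
    active at its time (including the Recording process)."""
    top = list(marker_annotation.top)
    for proc in context_at(timeline, t):
        if proc.annotation.children:
            top.append(proc.annotation)
    return HedString(top=top, source_text=marker_annotation.source_text)


def search(dataset: list[AnnotatedFile], q, schema: Schema,
           scope: str = "markers", enrich: bool = False) -> list[Hit]:
    """Search annotated files; hits come back in (file, time) order."""
    q = _as_query(q)
    validate_query(q)
    hits: list[Hit] = []
    for f in dataset:
        if scope == "processes":
            if f.timeline is None:
                raise ValueError(f"{f.name}: no timeline assembled")
            for proc in [f.timeline.recording] + f.timeline.processes:
                hs = HedString(top=[proc.annotation])
                if _matches(hs, q, schema):
                    hits.append(Hit(file=f.name, row=-1, time=proc.onset_t,
                                    annotation=hs))
            continue
        if scope != "markers":
            raise ValueError(f"unknown scope {scope!r}")
        for idx, hs in f.annotations:
            t = float(f.table.df.loc[idx, "onset"])
            if enrich:
                if f.timeline is None:
                    raise ValueError(f"{f.name}: enrich=True needs a timeline")
                hs = enriched_annotation(hs, f.timeline, t)
            if _matches(hs, q, schema):
                hits.append(Hit(file=f.name, row=idx, time=t, annotation=hs))
    hits.sort(key=lambda h: (h.file, h.time, h.row))
    return hits


def factor_matrix(dataset: list[AnnotatedFile],
                  named_queries: dict[str, Query] | list[tuple[str, Query]],
                  schema: Schema, enrich: bool = False) -> pd.DataFrame:
    """0/1 design-matrix: one row per event marker, one column per query."""
    pairs = list(named_queries.items()) if isinstance(named_queries, dict) \
        else list(named_queries)
    if not pairs:
        raise QueryError(ErrorCode.QUERY_SYNTAX, "at least one query required")
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise QueryError(ErrorCode.QUERY_DUPLICATE_NAME,
                         "duplicate factor names")
    pairs = [(n, _as_query(q)) for n, q in pairs]
    for _, q in pairs:
        validate_query(q)
    rows = []
    for f in dataset:
        for idx, hs in f.annotations:
            t = float(f.table.df.loc[idx, "onset"])
            if enrich:
                if f.timeline is None:
                    raise ValueError(f"{f.name}: enrich=True needs a timeline")
                hs = enriched_annotation(hs, f.timeline, t)
            record = {"file": f.name, "row": idx, "onset": t}
            for name, q in pairs:
                record[name] = int(_matches(hs, q, schema))
            rows.append(record)
    return pd.DataFrame(rows, columns=["file", "row", "onset"] + names)
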