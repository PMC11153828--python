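"""Annotation-string grammar: comma-separated tags, parenthesized groups.

A tag string like ``(Red, Triangle)`` denotes an association of its member
tags; groups nest arbitrarily, e.g. ``(Experiment-participant, (Move, (Left,
Hand)))``.  Parsing is schema-free; :func:`resolve` maps every tag to its
long form against a schema and splits off value suffixes (``Duration/0.5 s``
-> numeric value 0.5, unit "s", normalized to seconds).

Group *comparison* is order-insensitive (groups are semantically sets), but
the sibling order of the source text is preserved for serialization.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Union

from .errors import ErrorCode, ParseError, ResolutionError
from .schema import Schema

#: recognized time units and their factor to seconds
TIME_UNITS = {"s": 1.0, "ms": 1e-3, "min": 60.0}

_VALUE_RE = re.compile(r"^([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)(?:\s+(\S+))?$")


@dataclass
class HedTag:
    """A single tag: resolved path plus optional extension and value."""

    source: str
    path: str | None = None  # canonical long form once resolved
    extension: str = ""
    value: str | None = None
    numeric_value: float | None = None
    unit: str | None = None

    @property
    def is_resolved(self) -> bool:
        return self.path is not None

    @property
    def long_form(self) -> str:
        if self.path is None:
            return self.source
        parts = [self.path]
        if self.extension:
            parts.append(self.extension)
        if self.value is not None:
            parts.append(self.value)
        return "/".join(parts)

    @property
    def short_form(self) -> str:
        if self.path is None:
            return self.source
        parts = [self.path.rsplit("/", 1)[-1]]
        if self.extension:
            parts.append(self.extension)
        if self.value is not None:
            parts.append(self.value)
        return "/".join(parts)

    @property
    def schema_term(self) -> str:
        """Final schema component (short name) of the resolved path."""
        base = self.path if self.path is not None else self.source
        return base.rsplit("/", 1)[-1]

    def matches_term(self, term: str) -> bool:
        return self.schema_term.lower() == term.lower()

    def _key(self):
        return ("tag", self.long_form.strip().lower())

    def __eq__(self, other) -> bool:
        return isinstance(other, HedTag) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def __repr__(self) -> str:
        return f"HedTag({self.long_form!r})"


@dataclass
class HedGroup:
    """A parenthesized association of tags and sub-groups."""

    children: list[Union[HedTag, "HedGroup"]] = field(default_factory=list)

    def _key(self):
        return ("group", tuple(sorted(c._key() for c in self.children)))

    def __eq__(self, other) -> bool:
        return isinstance(other, HedGroup) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def tags(self) -> Iterator[HedTag]:
        """All tags in the subtree, depth-first."""
        for child in self.children:
            if isinstance(child, HedTag):
                yield child
            else:
                yield from child.tags()

    def groups(self) -> Iterator["HedGroup"]:
        """This group and all nested sub-groups."""
        yield self
        for child in self.children:
            if isinstance(child, HedGroup):
                yield from child.groups()

    def first_tag(self) -> HedTag | None:
        for child in self.children:
            if isinstance(child, HedTag):
                return child
        return None

    def __repr__(self) -> str:
        return f"HedGroup({self.children!r})"


@dataclass
class HedString:
    """A parsed annotation: ordered top-level tags and groups."""

    top: list[Union[HedTag, HedGroup]] = field(default_factory=list)
    source_text: str = ""

    def _key(self):
        return tuple(sorted(c._key() for c in self.top))

    def __eq__(self, other) -> bool:
        return isinstance(other, HedString) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def tags(self) -> Iterator[HedTag]:
        for item in self.top:
            if isinstance(item, HedTag):
                yield item
            else:
                yield from item.tags()

    def groups(self) -> Iterator[HedGroup]:
        """All groups at any nesting level (top level is not a group)."""
        for item in self.top:
            if isinstance(item, HedGroup):
                yield from item.groups()

    def is_empty(self) -> bool:
        return not self.top

    def as_group(self) -> HedGroup:
        """The whole string viewed as one implicit group."""
        return HedGroup(list(self.top))

    def __repr__(self) -> str:
        return f"HedString({serialize(self)!r})"


# ----------------------------------------------------------------------
# parsing


def parse(text: str) -> HedString:
    """Parse annotation text into a :class:`HedString` (no schema applied)."""
    if text is None or not text.strip():
        raise ParseError(ErrorCode.PARSE_EMPTY_STRING, "empty annotation string")
    items, pos = _parse_items(text, 0, depth=0)
    if pos != len(text):
        raise ParseError(ErrorCode.PARSE_UNBALANCED,
                         f"unmatched ')' at position {pos} in {text!r}")
    return HedString(top=items, source_text=text)


def _parse_items(text: str, pos: int, depth: int):
    items: list[Union[HedTag, HedGroup]] = []
    expecting_item = True
    while pos < len(text):
        ch = text[pos]
        if ch == "(":
            if not expecting_item:
                raise ParseError(ErrorCode.PARSE_EMPTY_TAG,
                                 f"missing ',' before '(' at position {pos}")
            inner, pos = _parse_items(text, pos + 1, depth + 1)
            if pos >= len(text) or text[pos] != ")":
                raise ParseError(ErrorCode.PARSE_UNBALANCED,
                                 f"unbalanced '(' in {text!r}")
            if not inner:
                raise ParseError(ErrorCode.PARSE_EMPTY_GROUP,
                                 f"empty group at position {pos} in {text!r}")
            items.append(HedGroup(inner))
            pos += 1
            expecting_item = False
        elif ch == ")":
            if depth == 0:
                break  # reported as unmatched by caller
            if expecting_item and items:
                raise ParseError(ErrorCode.PARSE_EMPTY_TAG,
                                 f"empty tag before ')' at position {pos}")
            return items, pos
        elif ch == ",":
            if expecting_item:
                raise ParseError(ErrorCode.PARSE_EMPTY_TAG,
                                 f"empty tag at position {pos} in {text!r}")
            pos += 1
            expecting_item = True
        elif ch.isspace():
            pos += 1
        else:
            if not expecting_item:
                raise ParseError(ErrorCode.PARSE_EMPTY_TAG,
                                 f"missing ',' before tag at position {pos}")
            end = pos
            while end < len(text) and text[end] not in "(),":
                end += 1
            token = text[pos:end].strip()
            if not token:
                raise ParseError(ErrorCode.PARSE_EMPTY_TAG,
                                 f"empty tag at position {pos}")
            items.append(HedTag(source=token))
            pos = end
            expecting_item = False
    if depth > 0:
        raise ParseError(ErrorCode.PARSE_UNBALANCED, f"unbalanced '(' in {text!r}")
    if expecting_item and items:
        raise ParseError(ErrorCode.PARSE_EMPTY_TAG, "trailing comma")
    return items, pos


# ----------------------------------------------------------------------
# resolution


def resolve_tag(tag: HedTag, schema: Schema) -> HedTag:
    """Resolve one tag against the schema; returns a new tag."""
    if tag.is_resolved:  # idempotent
        return replace(tag)
    rt = schema.resolve_tag(tag.source)
    out = HedTag(source=tag.source, path=rt.path, extension=rt.extension,
                 value=rt.value)
    if rt.value is not None:
        m = _VALUE_RE.match(rt.value.strip())
        if rt.node.unit_class == "time":
            if m is None:
                raise ResolutionError(
                    ErrorCode.TAG_VALUE_INVALID,
                    f"{rt.node.term}: value {rt.value!r} is not numeric time",
                )
            number, unit = float(m.group(1)), m.group(2)
            if unit is None:
                warnings.warn(
                    f"{rt.node.term}/{rt.value}: no unit given, assuming seconds",
                    stacklevel=2,
                )
                unit = "s"
            if unit not in TIME_UNITS:
                raise ResolutionError(
                    ErrorCode.TAG_VALUE_INVALID,
                    f"{rt.node.term}: unrecognized time unit {unit!r}",
                )
            out.numeric_value = number * TIME_UNITS[unit]
            out.unit = unit
        elif m is not None:
            out.numeric_value = float(m.group(1))
            out.unit = m.group(2)
    return out


def _resolve_group(group: HedGroup, schema: Schema) -> HedGroup:
    return HedGroup([
        resolve_tag(c, schema) if isinstance(c, HedTag) else _resolve_group(c, schema)
        for c in group.children
    ])


def resolve(hs: HedString, schema: Schema) -> HedString:
    """Resolve all tags of a string; returns a new string, input unchanged."""
    top = [
        resolve_tag(c, schema) if isinstance(c, HedTag) else _resolve_group(c, schema)
        for c in hs.top
    ]
    return HedString(top=top, source_text=hs.source_text)


def parse_and_resolve(text: str, schema: Schema) -> HedString:
    return resolve(parse(text), schema)


# ----------------------------------------------------------------------
# serialization


def serialize(hs: HedString | HedGroup, form: str = "short") -> str:
    """Render back to annotation text.

    ``form="short"`` emits the final schema component plus any suffix;
    ``form="long"`` emits full paths.  Unresolved tags emit their source text.
    """
    if form not in ("short", "long"):
        raise ValueError(f"form must be 'short' or 'long', got {form!r}")
    items = hs.top if isinstance(hs, HedString) else [hs]
    return ", ".join(_serialize_item(i, form) for i in items)


def _serialize_item(item: Union[HedTag, HedGroup], form: str) -> str:
    if isinstance(item, HedTag):
        return item.short_form if form == "short" else item.long_form
    inner = ", ".join(_serialize_item(c, form) for c in item.children)
    return f"({inner})"
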