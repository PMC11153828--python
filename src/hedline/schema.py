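"""Hierarchical vocabulary (schema) handling.

A schema is a forest of terms.  Each child term specializes its parent
(*is-a*), so the full path from a root to a node — its *long form* — uniquely
identifies it, and because terms are globally unique the final component — the
*short form* — identifies it too.  Annotations may extend most branches with
terms not in the schema; extensions inherit the is-a relationship of the node
they hang from, which is what makes abstraction search work on them.

Schema documents are UTF-8 JSON::

    {"version": "...",
     "nodes": [{"term": "...", "parent": "<long form or null>",
                "extension_allowed": bool, "takes_value": bool,
                "unit_class": "time" | null}, ...]}

Structural tags (Onset, Offset, Inset, Def, Definition, Duration) never accept
extension children; value-taking nodes are leaves that accept a value suffix
(numeric with optional unit for the "time" unit class, free text otherwise).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from .errors import ErrorCode, ResolutionError, SchemaError

#: tags with assembly semantics; they never take user extensions.
STRUCTURAL_TERMS = frozenset(
    t.lower() for t in ("Onset", "Offset", "Inset", "Def", "Definition", "Duration")
)


@dataclass
class SchemaNode:
    """One term in the vocabulary tree."""

    term: str
    parent_path: str = ""  # long form of parent; "" for roots
    extension_allowed: bool = True
    takes_value: bool = False
    unit_class: str | None = None
    children: dict[str, "SchemaNode"] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.term or "/" in self.term or "," in self.term:
            raise SchemaError(
                ErrorCode.SCHEMA_MALFORMED,
                f"invalid term {self.term!r}: must be non-empty with no '/' or ','",
            )
        if self.takes_value and self.children:
            raise SchemaError(
                ErrorCode.SCHEMA_MALFORMED,
                f"value-taking node {self.term!r} must be a leaf",
            )
        if self.term.lower() in STRUCTURAL_TERMS:
            self.extension_allowed = False

    @property
    def long_path(self) -> str:
        return f"{self.parent_path}/{self.term}" if self.parent_path else self.term


@dataclass
class ResolvedTag:
    """Outcome of resolving a tag path against a schema.

    ``path`` is the canonical long form of the deepest schema node matched;
    ``extension`` holds any trailing user-extension components (joined by
    "/"); ``value`` the value suffix of a value-taking node.
    """

    path: str
    node: SchemaNode
    extension: str = ""
    value: str | None = None

    @property
    def long_form(self) -> str:
        parts = [self.path]
        if self.extension:
            parts.append(self.extension)
        if self.value is not None:
            parts.append(self.value)
        return "/".join(parts)

    @property
    def short_form(self) -> str:
        parts = [self.path.rsplit("/", 1)[-1]]
        if self.extension:
            parts.append(self.extension)
        if self.value is not None:
            parts.append(self.value)
        return "/".join(parts)


class Schema:
    """An indexed vocabulary forest with case-insensitive unique terms."""

    def __init__(self, version: str = "0.0.0"):
        self.version = version
        self.roots: list[SchemaNode] = []
        # lowercased term -> node (terms are globally unique)
        self._by_term: dict[str, SchemaNode] = {}

    # -- construction -----------------------------------------------------

    def add_node(self, node: SchemaNode) -> SchemaNode:
        key = node.term.lower()
        if key in self._by_term:
            raise SchemaError(
                ErrorCode.SCHEMA_DUPLICATE_TERM,
                f"term {node.term!r} appears more than once "
                f"(existing: {self._by_term[key].long_path!r})",
            )
        if node.parent_path:
            parent = self.node_for_path(node.parent_path)
            if parent is None:
                raise SchemaError(
                    ErrorCode.SCHEMA_MALFORMED,
                    f"parent {node.parent_path!r} of {node.term!r} not in schema",
                )
            if parent.takes_value:
                raise SchemaError(
                    ErrorCode.SCHEMA_MALFORMED,
                    f"value-taking node {parent.term!r} cannot have children",
                )
            node.parent_path = parent.long_path  # canonical case
            parent.children[key] = node
        else:
            self.roots.append(node)
        self._by_term[key] = node
        return node

    # -- lookups ----------------------------------------------------------

    @property
    def index(self) -> dict[str, str]:
        """Lowercased term -> canonical long form."""
        return {k: n.long_path for k, n in self._by_term.items()}

    def __len__(self) -> int:
        return len(self._by_term)

    def __contains__(self, term: str) -> bool:
        return term.lower() in self._by_term

    def node_for_term(self, term: str) -> SchemaNode | None:
        return self._by_term.get(term.lower())

    def node_for_path(self, long_path: str) -> SchemaNode | None:
        """Node whose canonical long form matches ``long_path`` (case-insensitive)."""
        last = long_path.rsplit("/", 1)[-1]
        node = self._by_term.get(last.lower())
        if node is not None and node.long_path.lower() == long_path.lower():
            return node
        return None

    def iter_nodes(self) -> Iterable[SchemaNode]:
        return self._by_term.values()

    # -- resolution -------------------------------------------------------

    def resolve_tag(self, tag_path: str) -> ResolvedTag:
        """Resolve a (possibly short-form) tag path to its schema node.

        Components beyond the deepest schema node become the value (for
        value-taking nodes) or extension components (where allowed).
        """
        text = tag_path.strip().strip("/")
        if not text:
            raise ResolutionError(ErrorCode.TAG_UNKNOWN, "empty tag")
        components = text.split("/")
        node = self._by_term.get(components[0].strip().lower())
        if node is None:
            raise ResolutionError(
                ErrorCode.TAG_UNKNOWN,
                f"tag {components[0]!r} is not in the schema (in {tag_path!r})",
            )
        i = 1
        while i < len(components):
            comp = components[i].strip()
            child = node.children.get(comp.lower())
            if child is not None:
                node = child
                i += 1
                continue
            rest = "/".join(c.strip() for c in components[i:])
            if node.takes_value:
                return ResolvedTag(path=node.long_path, node=node, value=rest)
            if node.extension_allowed:
                for c in components[i:]:
                    if not c.strip():
                        raise ResolutionError(
                            ErrorCode.TAG_UNKNOWN,
                            f"empty extension component in {tag_path!r}",
                        )
                return ResolvedTag(path=node.long_path, node=node, extension=rest)
            raise ResolutionError(
                ErrorCode.TAG_EXTENSION_FORBIDDEN,
                f"{node.long_path!r} accepts neither extensions nor values "
                f"(while resolving {tag_path!r})",
            )
        return ResolvedTag(path=node.long_path, node=node)


# ----------------------------------------------------------------------
# module-level operations


def load_schema(source: Union[str, Path, dict]) -> Schema:
    """Load a schema document (JSON file path, JSON text, or parsed dict)."""
    if isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text(encoding="utf-8") if _looks_like_path(source) \
            else str(source)
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SchemaError(ErrorCode.SCHEMA_MALFORMED,
                              f"schema document is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "nodes" not in doc:
        raise SchemaError(ErrorCode.SCHEMA_MALFORMED,
                          "schema document must be an object with a 'nodes' list")
    nodes = doc["nodes"]
    if not nodes:
        raise SchemaError(ErrorCode.SCHEMA_EMPTY, "schema document has no nodes")

    schema = Schema(version=str(doc.get("version", "0.0.0")))
    pending = []
    for entry in nodes:
        try:
            term = entry["term"]
        except (TypeError, KeyError):
            raise SchemaError(ErrorCode.SCHEMA_MALFORMED,
                              f"malformed node entry: {entry!r}") from None
        node = SchemaNode(
            term=term,
            parent_path=entry.get("parent") or "",
            extension_allowed=bool(entry.get("extension_allowed", True)),
            takes_value=bool(entry.get("takes_value", False)),
            unit_class=entry.get("unit_class"),
        )
        pending.append(node)

    # attach in dependency order; leftovers mean an unknown parent or a cycle
    while pending:
        progressed = False
        remaining = []
        for node in pending:
            if not node.parent_path or schema.node_for_path(node.parent_path):
                schema.add_node(node)
                progressed = True
            else:
                remaining.append(node)
        if not progressed:
            names = ", ".join(repr(n.term) for n in remaining)
            raise SchemaError(
                ErrorCode.SCHEMA_CYCLE,
                f"nodes {names} cannot be attached (unknown parent or cycle)",
            )
        pending = remaining
    return schema


def _looks_like_path(source: Union[str, Path]) -> bool:
    if isinstance(source, Path):
        return True
    s = source.lstrip()
    return not s.startswith("{")


def merge_library(base: Schema, lib: Schema, attach_at: str) -> Schema:
    """Attach a library schema's roots under an existing node of ``base``.

    Returns a new merged schema; inputs are unchanged.  Any library term
    already present in the base is a collision error.
    """
    merged = copy.deepcopy(base)
    anchor = merged.node_for_path(attach_at)
    if anchor is None:
        # allow short-form attach point
        anchor = merged.node_for_term(attach_at) if "/" not in attach_at else None
    if anchor is None:
        raise SchemaError(ErrorCode.SCHEMA_ATTACH_MISSING,
                          f"attach point {attach_at!r} not in base schema")
    for term in lib.index:
        if term in merged.index:
            raise SchemaError(
                ErrorCode.SCHEMA_MERGE_COLLISION,
                f"library term {term!r} already exists in the base schema",
            )

    def graft(node: SchemaNode, parent_path: str) -> None:
        clone = SchemaNode(
            term=node.term,
            parent_path=parent_path,
            extension_allowed=node.extension_allowed,
            takes_value=node.takes_value,
            unit_class=node.unit_class,
        )
        merged.add_node(clone)
        for child in node.children.values():
            graft(child, clone.long_path)

    for root in lib.roots:
        graft(root, anchor.long_path)
    merged.version = f"{base.version}+{lib.version}"
    return merged


def long_form(tag_path: str, schema: Schema) -> str:
    """Full root-to-leaf path for a tag, keeping extensions/values verbatim."""
    return schema.resolve_tag(tag_path).long_form


def short_form(tag_path: str, schema: Schema) -> str:
    """Canonical short form (final schema component plus any suffix)."""
    return schema.resolve_tag(tag_path).short_form


def is_descendant(candidate: str, ancestor: str) -> bool:
    """True iff ``ancestor`` equals ``candidate`` or is a component-boundary
    prefix of it (case-insensitive).  Reflexive; extensions on the candidate
    participate like ordinary components."""
    cand = [c.strip().lower() for c in candidate.strip().strip("/").split("/")]
    anc = [c.strip().lower() for c in ancestor.strip().strip("/").split("/")]
    if len(anc) > len(cand):
        return False
    return cand[: len(anc)] == anc
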