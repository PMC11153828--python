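"""Named annotation templates (Definition) and their references (Def).

A top-level group whose first tag is ``Definition/Name`` (or
``Definition/Name/#`` for a single-placeholder family) declares a reusable
template; ``Def/Name`` (or ``Def/Name/value``) references it elsewhere.
Definitions anchor temporally extended event processes: Onset/Offset/Inset
markers match each other through the Def anchor they are grouped with.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

from .errors import DefinitionError, ErrorCode
from .strings import HedGroup, HedString, HedTag

_FORBIDDEN_IN_CONTENT = {"def", "definition", "onset", "offset", "inset"}


@dataclass
class Definition:
    name: str                 # display case; keyed case-insensitively
    takes_value: bool         # declared as "Name/#"
    content: HedGroup

    def __post_init__(self) -> None:
        for tag in self.content.tags():
            if tag.schema_term.lower() in _FORBIDDEN_IN_CONTENT:
                raise DefinitionError(
                    ErrorCode.DEF_MALFORMED,
                    f"definition {self.name!r} contains structural tag "
                    f"{tag.schema_term!r}",
                )
        n_placeholders = sum(_placeholder_count(t) for t in self.content.tags())
        expected = 1 if self.takes_value else 0
        if n_placeholders != expected:
            raise DefinitionError(
                ErrorCode.DEF_MALFORMED,
                f"definition {self.name!r} must contain exactly {expected} '#' "
                f"placeholder(s), found {n_placeholders}",
            )


def _placeholder_count(tag: HedTag) -> int:
    n = 0
    if tag.value is not None:
        n += tag.value.count("#")
    n += tag.extension.count("#")
    return n


class DefinitionRegistry:
    """Case-insensitive name -> Definition map."""

    def __init__(self) -> None:
        self._defs: dict[str, Definition] = {}

    def __len__(self) -> int:
        return len(self._defs)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._defs

    def get(self, name: str) -> Definition | None:
        return self._defs.get(name.lower())

    def names(self) -> list[str]:
        return [d.name for d in self._defs.values()]

    def add(self, definition: Definition) -> None:
        key = definition.name.lower()
        existing = self._defs.get(key)
        if existing is not None:
            same = (existing.takes_value == definition.takes_value
                    and existing.content == definition.content)
            if not same:
                raise DefinitionError(
                    ErrorCode.DEF_DUPLICATE,
                    f"conflicting re-definition of {definition.name!r}",
                )
            return  # identical re-declaration is harmless
        self._defs[key] = definition


# ----------------------------------------------------------------------


def _definition_group_entry(group: HedGroup) -> Definition | None:
    """Parse a group as a Definition declaration, or None if it is not one."""
    first = group.first_tag()
    if first is None or not first.matches_term("Definition"):
        return None
    if not first.value:
        raise DefinitionError(ErrorCode.DEF_MALFORMED,
                              "Definition tag without a name")
    parts = first.value.split("/")
    takes_value = parts[-1] == "#"
    name_parts = parts[:-1] if takes_value else parts
    name = "/".join(name_parts)
    if not name:
        raise DefinitionError(ErrorCode.DEF_MALFORMED,
                              f"Definition/{first.value}: empty name")
    rest = [c for c in group.children if c is not first]
    if len(rest) == 1 and isinstance(rest[0], HedGroup):
        content = rest[0]
    else:
        content = HedGroup(rest)
    return Definition(name=name, takes_value=takes_value,
                      content=copy.deepcopy(content))


def collect_definitions(strings: list[HedString],
                        registry: DefinitionRegistry | None = None,
                        ) -> DefinitionRegistry:
    """Register every top-level Definition group found in ``strings``.

    Collection is order-independent over inputs (conflicts raise either way).
    """
    registry = registry if registry is not None else DefinitionRegistry()
    for hs in strings:
        for item in hs.top:
            if isinstance(item, HedGroup):
                entry = _definition_group_entry(item)
                if entry is not None:
                    registry.add(entry)
    return registry


def strip_definitions(hs: HedString) -> HedString:
    """A copy of ``hs`` with top-level Definition groups removed."""
    top = [
        item for item in hs.top
        if not (isinstance(item, HedGroup) and _definition_group_entry(item))
    ]
    return HedString(top=top, source_text=hs.source_text)


def split_def_reference(tag: HedTag) -> tuple[str, str | None]:
    """(name, value) of a ``Def/Name[/value]`` reference tag."""
    if not tag.matches_term("Def") or not tag.value:
        raise DefinitionError(ErrorCode.DEF_MALFORMED,
                              f"{tag.long_form!r} is not a Def reference")
    name, _, value = tag.value.partition("/")
    return name, (value or None)


def expand_def(tag: HedTag, registry: DefinitionRegistry) -> HedGroup:
    """Expanded content for a Def reference (placeholder substituted).

    The caller keeps the Def tag itself alongside the returned group so the
    reference still anchors Onset/Offset matching.
    """
    name, value = split_def_reference(tag)
    definition = registry.get(name)
    if definition is None:
        raise DefinitionError(ErrorCode.DEF_UNKNOWN,
                              f"Def/{name}: no such definition")
    if definition.takes_value and value is None:
        raise DefinitionError(
            ErrorCode.DEF_VALUE_MISMATCH,
            f"Def/{name}: definition takes a value but none was given")
    if not definition.takes_value and value is not None:
        raise DefinitionError(
            ErrorCode.DEF_VALUE_MISMATCH,
            f"Def/{name}/{value}: definition does not take a value")
    content = copy.deepcopy(definition.content)
    if value is not None:
        for t in content.tags():
            if t.value is not None and "#" in t.value:
                t.value = t.value.replace("#", value)
                t.numeric_value, t.unit = None, None
                try:
                    t.numeric_value = float(t.value)
                except ValueError:
                    pass
            if "#" in t.extension:
                t.extension = t.extension.replace("#", value)
    return content


def _is_expanded_def(group: HedGroup, registry: DefinitionRegistry) -> bool:
    """True for a group of the form ``(Def/Name, <expanded content>)`` that
    :func:`expand_all` already produced (expansion is idempotent)."""
    if len(group.children) != 2:
        return False
    first, second = group.children
    if not isinstance(first, HedTag) or not first.matches_term("Def") \
            or not isinstance(second, HedGroup):
        return False
    try:
        return expand_def(first, registry) == second
    except DefinitionError:
        return False


def expand_all(hs: HedString, registry: DefinitionRegistry,
               missing: str = "error") -> HedString:
    """Replace every Def tag with ``(Def/Name, <content>)``.

    ``missing="warn"`` keeps an unknown Def opaque with a warning, so
    partially annotated data stays searchable; ``missing="error"`` raises.
    Definition contents contain no Def tags, so one pass reaches a fixpoint.
    """

    def transform(item):
        if isinstance(item, HedTag):
            if item.matches_term("Def"):
                try:
                    content = expand_def(item, registry)
                except DefinitionError:
                    if missing != "warn":
                        raise
                    warnings.warn(f"unknown definition for {item.long_form}; "
                                  "kept opaque", stacklevel=2)
                    return copy.deepcopy(item)
                children = [copy.deepcopy(item)]
                if content.children:
                    children.append(content)
                return HedGroup(children)
            return copy.deepcopy(item)
        if _is_expanded_def(item, registry):
            return copy.deepcopy(item)
        return HedGroup([transform(c) for c in item.children])

    return HedString(top=[transform(i) for i in hs.top],
                     source_text=hs.source_text)
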