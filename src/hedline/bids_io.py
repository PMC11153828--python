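"""BIDS-style tabular event I/O and per-row annotation assembly.

Event tables are tab-separated ``*_events.tsv`` files whose first columns are
``onset`` and ``duration`` (seconds; ``n/a`` for missing).  A JSON sidecar
(``*_events.json``) maps column values to annotation strings: categorical
entries map each observed value to a string, value templates contain a single
``#`` that is substituted with the cell value.  Definitions may be declared in
any sidecar string or under a dedicated top-level ``"definitions"`` key.

Assembly concatenates the contributions of all annotated columns in header
order (reproducible across platforms), parses and resolves the result, and
expands Def references.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Union

import pandas as pd

from . import strings as hstr
from .definitions import (DefinitionRegistry, collect_definitions,
                          expand_all, strip_definitions)
from .errors import ErrorCode, EventsError
from .schema import Schema

if TYPE_CHECKING:  # pragma: no cover
    from .timeline import Timeline


# ----------------------------------------------------------------------
# event tables


class EventTable:
    """An ordered event table with ``onset``/``duration`` in seconds.

    Rows are stably sorted by onset; the DataFrame index keeps the original
    file row order so diagnostics can point at source rows.
    """

    def __init__(self, df: pd.DataFrame, source_path: str = "<memory>"):
        if "onset" not in df.columns:
            raise EventsError(ErrorCode.EVENTS_NO_ONSET,
                              "event table has no 'onset' column",
                              file=source_path)
        df = df.copy()
        try:
            df["onset"] = df["onset"].astype(float)
        except (TypeError, ValueError) as exc:
            raise EventsError(ErrorCode.EVENTS_BAD_ONSET,
                              f"unparseable onset value: {exc}",
                              file=source_path) from exc
        if not df["onset"].map(math.isfinite).all():
            raise EventsError(ErrorCode.EVENTS_BAD_ONSET,
                              "onset values must be finite", file=source_path)
        if "duration" in df.columns:
            dur = pd.to_numeric(df["duration"].replace("n/a", None),
                                errors="coerce")
            if (dur.dropna() < 0).any():
                raise EventsError(ErrorCode.EVENTS_BAD_ONSET,
                                  "duration values must be >= 0 or n/a",
                                  file=source_path)
            df["duration"] = dur
        self.df = df.sort_values("onset", kind="stable")
        self.source_path = source_path

    def __len__(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def end_time(self) -> float:
        """Latest onset + duration over all rows (recording extent floor)."""
        if not len(self.df):
            return 0.0
        dur = self.df.get("duration")
        extent = self.df["onset"] + (dur.fillna(0.0) if dur is not None else 0.0)
        return float(extent.max())


def read_events(path: Union[str, Path]) -> EventTable:
    """Read a ``*_events.tsv`` file; ``n/a`` cells stay missing."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         engine="python")
    except pd.errors.ParserError as exc:
        raise EventsError(ErrorCode.EVENTS_RAGGED,
                          f"ragged or malformed table: {exc}",
                          file=str(path)) from exc
    return EventTable(df, source_path=str(path))


def _fmt_cell(v) -> str:
    if v is None:
        return "n/a"
    if isinstance(v, float):
        if math.isnan(v):
            return "n/a"
        return repr(v) if v != int(v) else str(int(v)) + ".0"
    return str(v)


def write_events(table: EventTable, path: Union[str, Path]) -> None:
    """Write in canonical form: onset/duration first, NaN as ``n/a``,
    floats in minimal repr (read→write round-trips byte-identically)."""
    cols = table.columns
    ordered = [c for c in ("onset", "duration") if c in cols]
    ordered += [c for c in cols if c not in ordered]
    lines = ["\t".join(ordered)]
    for _, row in table.df.iterrows():
        lines.append("\t".join(_fmt_cell(row[c]) for c in ordered))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ----------------------------------------------------------------------
# sidecars


@dataclass
class SidecarColumn:
    name: str
    categorical: dict[str, str] | None = None  # value -> annotation text
    template: str | None = None                # contains one '#'

    def annotation_for(self, cell: str) -> str | None:
        if self.template is not None:
            return self.template.replace("#", cell)
        assert self.categorical is not None
        if cell not in self.categorical:
            warnings.warn(f"column {self.name!r}: value {cell!r} has no "
                          "sidecar annotation; skipped", stacklevel=3)
            return None
        return self.categorical[cell]


class Sidecar:
    """Per-column annotation rules plus dataset-level definitions."""

    def __init__(self, columns: dict[str, SidecarColumn] | None = None,
                 definitions: list[str] | None = None):
        self.columns = columns or {}
        self.definitions = definitions or []

    @classmethod
    def from_dict(cls, doc: dict) -> "Sidecar":
        columns: dict[str, SidecarColumn] = {}
        definitions: list[str] = []
        for key, entry in doc.items():
            if key == "definitions":
                if not isinstance(entry, list):
                    raise EventsError(ErrorCode.SIDECAR_MALFORMED,
                                      "'definitions' must be a list of strings")
                definitions.extend(entry)
                continue
            if not isinstance(entry, dict) or "HED" not in entry:
                continue  # non-annotation column metadata is fine
            hed = entry["HED"]
            if isinstance(hed, str):
                if hed.count("#") > 1:
                    raise EventsError(
                        ErrorCode.SIDECAR_MALFORMED,
                        f"column {key!r}: template has more than one '#'")
                hstr.parse(hed.replace("#", "0") if "#" in hed else hed)
                columns[key] = SidecarColumn(name=key, template=hed)
            elif isinstance(hed, dict):
                for value, text in hed.items():
                    hstr.parse(text)  # must at least parse
                columns[key] = SidecarColumn(name=key,
                                             categorical=dict(hed))
            else:
                raise EventsError(ErrorCode.SIDECAR_MALFORMED,
                                  f"column {key!r}: HED entry must be a "
                                  "string template or a value map")
        return cls(columns, definitions)

    def all_annotation_strings(self) -> list[str]:
        out = list(self.definitions)
        for col in self.columns.values():
            if col.template is not None:
                out.append(col.template)
            else:
                out.extend(col.categorical.values())
        return out

    def build_registry(self, schema: Schema) -> DefinitionRegistry:
        """Collect every Definition declared anywhere in this sidecar."""
        resolved = []
        for text in self.all_annotation_strings():
            safe = text.replace("#", "0") if "#" in text else text
            # placeholder '#' only blocks value resolution, not collection,
            # except in Definition declarations where it must survive
            if "definition" in text.lower():
                safe = text
            try:
                resolved.append(hstr.resolve(hstr.parse(safe), schema))
            except Exception:
                continue  # non-definition strings may fail for other reasons
        return collect_definitions(resolved)


def read_sidecar(path: Union[str, Path]) -> Sidecar:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise EventsError(ErrorCode.SIDECAR_MALFORMED,
                          f"sidecar is not valid JSON: {exc}",
                          file=str(path)) from exc
    return Sidecar.from_dict(doc)


def write_sidecar(sidecar_doc: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(sidecar_doc, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")


# ----------------------------------------------------------------------
# annotation assembly


def assemble_annotations(table: EventTable, sidecar: Sidecar, schema: Schema,
                         registry: DefinitionRegistry | None = None,
                         expand: bool = True,
                         ) -> list[tuple[int, hstr.HedString]]:
    """One resolved annotation per row, in onset order.

    Columns contribute in header order; an explicit ``HED`` column
    contributes its cell verbatim.  Returns ``(original row index,
    HedString)`` pairs; rows with no annotated column yield an empty
    annotation with a warning.
    """
    if registry is None:
        registry = sidecar.build_registry(schema)
    out: list[tuple[int, hstr.HedString]] = []
    for idx in table.df.index:
        text = row_annotation_text(table, idx, sidecar)
        if text is None:
            warnings.warn(f"{table.source_path}:{idx}: row has no annotated "
                          "columns", stacklevel=2)
            out.append((idx, hstr.HedString()))
            continue
        hs = hstr.resolve(hstr.parse(text), schema)
        hs = strip_definitions(hs)
        if expand:
            hs = expand_all(hs, registry, missing="warn")
        out.append((idx, hs))
    return out


def row_annotation_text(table: EventTable, idx, sidecar: Sidecar) -> str | None:
    """Concatenated annotation text for one row (header column order),
    or None when no column contributes."""
    row = table.df.loc[idx]
    pieces: list[str] = []
    for col in table.columns:
        cell = row[col]
        if cell is None or (isinstance(cell, float) and math.isnan(cell)):
            continue
        cell = str(cell)
        if cell == "n/a" or cell == "":
            continue
        if col == "HED":
            pieces.append(cell)
        elif col in sidecar.columns:
            text = sidecar.columns[col].annotation_for(cell)
            if text is not None:
                pieces.append(text)
    return ", ".join(pieces) if pieces else None


# ----------------------------------------------------------------------
# participants


#: recognized handedness designations (case-insensitive)
_HANDEDNESS = {"left": "Left-handed", "l": "Left-handed",
               "right": "Right-handed", "r": "Right-handed"}


def normalize_handedness(value: str) -> Optional[str]:
    """Map a participants.tsv handedness designation to its tag.

    ``left, l, L, Left, LEFT`` (any case of "left"/"l") resolve to
    ``Left-handed``; the right-hand family analogously.  Unrecognized values
    return None with a warning.
    """
    tag = _HANDEDNESS.get(str(value).strip().lower())
    if tag is None:
        warnings.warn(f"unrecognized handedness value {value!r}", stacklevel=2)
    return tag


@dataclass
class ParticipantRecord:
    id: str
    fields: dict[str, str] = field(default_factory=dict)
    derived_tags: list[str] = field(default_factory=list)


def read_participants(path: Union[str, Path],
                      extra_tag_map: dict[str, str] | None = None,
                      ) -> dict[str, ParticipantRecord]:
    """Read ``participants.tsv``; handedness is normalized to its tag.

    ``extra_tag_map`` is a flat ``column=value -> tag`` map for acquisition
    or environment metadata kept outside the handedness convention.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "participant_id" not in df.columns:
        raise EventsError(ErrorCode.EVENTS_RAGGED,
                          "participants.tsv has no 'participant_id' column",
                          file=str(path))
    records: dict[str, ParticipantRecord] = {}
    for _, row in df.iterrows():
        rec = ParticipantRecord(id=row["participant_id"],
                                fields={c: row[c] for c in df.columns})
        if "handedness" in df.columns and row["handedness"] not in ("", "n/a"):
            tag = normalize_handedness(row["handedness"])
            if tag is not None:
                rec.derived_tags.append(tag)
        if extra_tag_map:
            for key, tag in extra_tag_map.items():
                col, _, val = key.partition("=")
                if col in df.columns and row[col] == val:
                    rec.derived_tags.append(tag)
        records[rec.id] = rec
    return records


# ----------------------------------------------------------------------
# dataset container


@dataclass
class AnnotatedFile:
    """One event file with its assembled annotations and timeline."""

    name: str
    table: EventTable
    annotations: list[tuple[int, hstr.HedString]]
    timeline: "Timeline | None" = None
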