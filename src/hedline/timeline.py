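"""Temporal assembly: from per-row event markers to event processes.

An *event process* is an identifiable happening that extends through time.
Markers in the event table delimit its phases:

* a group ``(Duration/0.5 s, <tags>)`` opens an anonymous process at the
  marker time that ends 0.5 s later (Duration processes may overlap freely);
* ``(Def/X, <modifiers>, Onset)`` opens a process anchored by definition X;
  it ends at the next ``(Def/X, Offset)`` or at the next ``(Def/X, ...,
  Onset)``, which closes it and opens a new contiguous process of the same
  anchor;
* ``(Def/X, Inset)`` records an internal phase transition of the open X
  process (e.g. a camera-shot change inside a movie scene);
* the *Recording* process spans the whole recording and carries participant,
  environment, and acquisition context tags.

At equal marker times Offsets are applied before Onsets, so contiguous
chains touch without overlap; context queries use half-open intervals
``[onset, offset)``, so at a shared boundary only the newly opened process
is active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Union

from .definitions import DefinitionRegistry, expand_def, split_def_reference
from .errors import AssemblyError, ErrorCode, HedError, Issue
from .strings import HedGroup, HedString, HedTag, serialize

#: absolute tolerance for comparing marker times (seconds)
TIME_TOL = 1e-9


@dataclass
class EventMarker:
    """A time point on the recording with its assembled annotation."""

    time: float
    annotation: HedString
    row_ref: tuple[str, int] = ("<memory>", -1)  # (file, original row index)
    roles: set[str] = field(default_factory=set)

    @property
    def file(self) -> str:
        return self.row_ref[0]

    @property
    def row(self) -> int:
        return self.row_ref[1]


@dataclass
class EventProcess:
    """A temporally extended event: ``[onset_t, offset_t)`` with insets."""

    anchor: str                       # "Name", "Name/value", synthetic id,
    onset_t: float                    # or "Recording"
    offset_t: float
    inset_ts: list[float] = field(default_factory=list)
    annotation: HedGroup = field(default_factory=HedGroup)
    provenance: list[tuple[str, int]] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.offset_t - self.onset_t

    def active_at(self, t: float) -> bool:
        return (t - self.onset_t) >= -TIME_TOL and (self.offset_t - t) > TIME_TOL

    def as_dict(self) -> dict:
        return {"anchor": self.anchor, "onset": self.onset_t,
                "offset": self.offset_t, "insets": list(self.inset_ts),
                "tags": serialize(self.annotation, "short")}


@dataclass
class Timeline:
    """A recording-spanning process, its event processes, and the markers."""

    recording: EventProcess
    processes: list[EventProcess]
    markers: list[EventMarker]

    @property
    def recording_end(self) -> float:
        return self.recording.offset_t

    def to_json(self) -> list[dict]:
        return [self.recording.as_dict()] + [p.as_dict() for p in self.processes]


# ----------------------------------------------------------------------
# assembly


def _direct_tag(group: HedGroup, term: str) -> HedTag | None:
    for child in group.children:
        if isinstance(child, HedTag) and child.matches_term(term):
            return child
    return None


def _direct_def(group: HedGroup) -> HedTag | None:
    """Def anchor among direct children, including the expanded form
    ``(Def/X, <content>)`` produced by definition expansion."""
    tag = _direct_tag(group, "Def")
    if tag is not None:
        return tag
    for child in group.children:
        if isinstance(child, HedGroup):
            first = child.first_tag()
            if first is not None and first.matches_term("Def"):
                return first
    return None


def _anchor_key(tag: HedTag) -> str:
    name, value = split_def_reference(tag)
    return f"{name}/{value}" if value is not None else name


class _Assembler:
    def __init__(self, registry: DefinitionRegistry | None, collect: bool):
        self.registry = registry or DefinitionRegistry()
        self.collect = collect
        self.issues: list[Issue] = []
        self.processes: list[EventProcess] = []
        self.open: dict[str, EventProcess] = {}  # lowercased anchor -> process
        self._n_anon = 0

    def error(self, err: AssemblyError) -> None:
        if self.collect:
            self.issues.append(Issue.from_error(err))
        else:
            raise err

    # -- operations on one marker group -----------------------------------

    def duration_group(self, marker: EventMarker, group: HedGroup,
                       dur_tag: HedTag) -> None:
        if dur_tag.numeric_value is None:
            self.error(AssemblyError(
                ErrorCode.TAG_VALUE_INVALID, "Duration tag without a value",
                file=marker.file, row=marker.row))
            return
        rest = [c for c in group.children if c is not dur_tag]
        self._n_anon += 1
        self.processes.append(EventProcess(
            anchor=f"duration-{self._n_anon}",
            onset_t=marker.time,
            offset_t=marker.time + dur_tag.numeric_value,
            annotation=HedGroup(rest),
            provenance=[marker.row_ref]))
        marker.roles.add("duration")

    def onset_group(self, marker: EventMarker, group: HedGroup,
                    onset_tag: HedTag) -> None:
        def_tag = _direct_def(group)
        if def_tag is None:
            self.error(AssemblyError(
                ErrorCode.TIMELINE_ONSET_NO_ANCHOR,
                "Onset group lacks a Def anchor",
                file=marker.file, row=marker.row))
            return
        key = _anchor_key(def_tag)
        prev = self.open.pop(key.lower(), None)
        if prev is not None:  # contiguous re-onset closes the previous one
            prev.offset_t = marker.time
            self.processes.append(prev)
        annotation = HedGroup([c for c in group.children if c is not onset_tag])
        if _direct_tag(annotation, "Def") is not None and def_tag.value:
            # bare Def anchor: fold in the definition content if known
            try:
                content = expand_def(def_tag, self.registry)
                if content.children:
                    annotation.children.append(content)
            except HedError:
                pass  # searchable anyway; validation reports unknown defs
        self.open[key.lower()] = EventProcess(
            anchor=key, onset_t=marker.time, offset_t=marker.time,
            annotation=annotation, provenance=[marker.row_ref])
        marker.roles.add("onset")

    def offset_group(self, marker: EventMarker, group: HedGroup) -> None:
        def_tag = _direct_def(group)
        if def_tag is None:
            self.error(AssemblyError(
                ErrorCode.TIMELINE_UNMATCHED_OFFSET,
                "Offset group lacks a Def anchor",
                file=marker.file, row=marker.row))
            return
        key = _anchor_key(def_tag)
        proc = self.open.pop(key.lower(), None)
        if proc is None:
            self.error(AssemblyError(
                ErrorCode.TIMELINE_UNMATCHED_OFFSET,
                f"Offset for {key!r} with no open process of that anchor",
                file=marker.file, row=marker.row))
            return
        proc.offset_t = marker.time
        proc.provenance.append(marker.row_ref)
        self.processes.append(proc)
        marker.roles.add("offset")

    def inset_group(self, marker: EventMarker, group: HedGroup) -> None:
        def_tag = _direct_def(group)
        if def_tag is None:
            self.error(AssemblyError(
                ErrorCode.TIMELINE_UNMATCHED_INSET,
                "Inset group lacks a Def anchor (insets on anonymous "
                "Duration processes are not supported)",
                file=marker.file, row=marker.row))
            return
        key = _anchor_key(def_tag)
        proc = self.open.get(key.lower())
        if proc is None:
            self.error(AssemblyError(
                ErrorCode.TIMELINE_UNMATCHED_INSET,
                f"Inset for {key!r} with no open process of that anchor",
                file=marker.file, row=marker.row))
            return
        proc.inset_ts.append(marker.time)
        proc.provenance.append(marker.row_ref)
        marker.roles.add("inset")

    # -- marker dispatch ---------------------------------------------------

    def classify_items(self, marker: EventMarker):
        """Split a marker's top-level items into offset-ops and other ops so
        that, within one time bucket, offsets can be applied first."""
        offsets, others = [], []
        for item in marker.annotation.top:
            if isinstance(item, HedGroup) and _direct_tag(item, "Offset"):
                offsets.append((marker, item))
            else:
                others.append((marker, item))
        return offsets, others

    def apply_other(self, marker: EventMarker, item) -> None:
        if isinstance(item, HedTag):
            if item.matches_term("Onset") or item.matches_term("Offset") \
                    or item.matches_term("Inset"):
                self.error(AssemblyError(
                    ErrorCode.TIMELINE_ONSET_NO_ANCHOR,
                    f"bare {item.schema_term} tag outside a Def group",
                    file=marker.file, row=marker.row))
            else:
                marker.roles.add("point")
            return
        dur = _direct_tag(item, "Duration")
        onset = _direct_tag(item, "Onset")
        if dur is not None:
            self.duration_group(marker, item, dur)
        elif onset is not None:
            self.onset_group(marker, item, onset)
        elif _direct_tag(item, "Inset") is not None:
            self.inset_group(marker, item)
        else:
            marker.roles.add("point")


def assemble(markers: Iterable[EventMarker],
             registry: DefinitionRegistry | None = None,
             recording_end: float | None = None,
             recording_tags: HedString | HedGroup | None = None,
             on_error: str = "raise",
             ) -> Union[Timeline, tuple[Timeline, list[Issue]]]:
    """Build a :class:`Timeline` from time-sorted markers.

    ``on_error="collect"`` returns ``(timeline, issues)`` instead of raising,
    for batch validation.  Processes still open at the end of the recording
    are closed there with a warning.
    """
    collect = on_error == "collect"
    markers = sorted(markers, key=lambda m: m.time)
    state = _Assembler(registry, collect)

    # bucket markers whose times coincide (within tolerance)
    i = 0
    while i < len(markers):
        j = i + 1
        while j < len(markers) and markers[j].time - markers[i].time <= TIME_TOL:
            j += 1
        bucket = markers[i:j]
        offsets, others = [], []
        for m in bucket:
            off, oth = state.classify_items(m)
            offsets.extend(off)
            others.extend(oth)
        for m, item in offsets:           # tie rule: Offsets before Onsets
            state.offset_group(m, item)
        for m, item in others:
            state.apply_other(m, item)
        i = j

    implied_end = max(
        [m.time for m in markers] + [p.offset_t for p in state.processes] + [0.0]
    )
    if recording_end is None:
        recording_end = implied_end
    elif implied_end - recording_end > TIME_TOL:
        warnings.warn(f"events extend to {implied_end} s, past the stated "
                      f"recording end {recording_end} s; clipping", stacklevel=2)
        for p in state.processes:
            p.offset_t = min(p.offset_t, recording_end)

    for key in list(state.open):
        proc = state.open.pop(key)
        warnings.warn(f"process {proc.anchor!r} still open at end of "
                      "recording; closed there", stacklevel=2)
        proc.offset_t = recording_end
        state.processes.append(proc)

    if recording_tags is None:
        rec_annotation = HedGroup()
    elif isinstance(recording_tags, HedString):
        rec_annotation = recording_tags.as_group()
    else:
        rec_annotation = recording_tags
    recording = EventProcess(anchor="Recording", onset_t=0.0,
                             offset_t=recording_end,
                             annotation=rec_annotation)
    state.processes.sort(key=lambda p: (p.onset_t, p.offset_t))
    tl = Timeline(recording=recording, processes=state.processes,
                  markers=markers)
    return (tl, state.issues) if collect else tl


# ----------------------------------------------------------------------
# context


def context_at(tl: Timeline, t: float) -> list[EventProcess]:
    """All processes whose half-open span contains ``t`` — the ongoing
    context: "the sum of all events located within its time location".
    Always includes the Recording process."""
    if t < -TIME_TOL or t - tl.recording_end > TIME_TOL:
        raise AssemblyError(ErrorCode.TIMELINE_OUT_OF_RANGE,
                            f"time {t} outside recording [0, {tl.recording_end}]")
    return [tl.recording] + [p for p in tl.processes if p.active_at(t)]


def preceding(tl: Timeline, marker: EventMarker, k: int = 1,
              filter: Optional[Union[Callable[[EventMarker], bool], object]] = None,
              schema=None) -> list[EventMarker]:
    """Up to ``k`` markers strictly earlier than ``marker``, most recent
    first; ties at equal times are ordered by row order.  ``filter`` may be
    a predicate or a query (requires ``schema``)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pred: Callable[[EventMarker], bool] | None
    if filter is None:
        pred = None
    elif callable(filter) and not hasattr(filter, "_is_query"):
        pred = filter
    else:
        from .query import matches  # local import avoids a cycle

        def pred(m, _q=filter, _s=schema):
            return matches(m.annotation, _q, _s)

    idx = next((i for i, m in enumerate(tl.markers) if m is marker), None)
    if idx is None:
        idx = tl.markers.index(marker)
    earlier = [m for m in tl.markers[:idx]
               if marker.time - m.time > TIME_TOL]
    earlier.reverse()  # most recent first; row order breaks ties
    if pred is not None:
        earlier = [m for m in earlier if pred(m)]
    return earlier[:k]


# ----------------------------------------------------------------------
# convenience: markers from assembled annotations


def markers_from_annotations(annotations: list[tuple[int, HedString]],
                             table, name: str | None = None,
                             ) -> list[EventMarker]:
    """Zip a table's rows with their assembled annotations into markers."""
    name = name if name is not None else table.source_path
    out = []
    for idx, hs in annotations:
        t = float(table.df.loc[idx, "onset"])
        out.append(EventMarker(time=t, annotation=hs, row_ref=(name, idx)))
    return out
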