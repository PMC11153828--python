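"""High-level pipeline: events + sidecar -> annotated file with timeline.

Thin glue over the per-module operations, used by the CLI and convenient in
scripts::

    schema = synth.sart_schema()
    af = api.annotate_table(table, sidecar, schema)
    hits = query.search([af], "Sensory-event", schema)
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from . import bids_io, strings as hstr
from .bids_io import AnnotatedFile, EventTable, Sidecar
from .errors import HedError, Issue
from .schema import Schema
from .strings import HedString
from .timeline import assemble, markers_from_annotations


def _recording_annotation(recording_tags, schema: Schema) -> HedString | None:
    """Accept a HedString, annotation text, or a list of tag strings."""
    if recording_tags is None:
        return None
    if isinstance(recording_tags, HedString):
        return recording_tags
    if isinstance(recording_tags, (list, tuple)):
        recording_tags = ", ".join(recording_tags)
    return hstr.parse_and_resolve(recording_tags, schema)


def annotate_table(table: EventTable, sidecar: Sidecar, schema: Schema,
                   recording_tags=None, name: str | None = None,
                   recording_end: float | None = None) -> AnnotatedFile:
    """Assemble per-row annotations and the event-process timeline."""
    name = name if name is not None else table.source_path
    registry = sidecar.build_registry(schema)
    annotations = bids_io.assemble_annotations(table, sidecar, schema,
                                               registry=registry)
    markers = markers_from_annotations(annotations, table, name=name)
    tl = assemble(markers, registry=registry, recording_end=recording_end,
                  recording_tags=_recording_annotation(recording_tags, schema))
    return AnnotatedFile(name=name, table=table, annotations=annotations,
                         timeline=tl)


def load_annotated_file(events_path: Union[str, Path],
                        sidecar_path: Union[str, Path], schema: Schema,
                        recording_tags=None) -> AnnotatedFile:
    table = bids_io.read_events(events_path)
    sidecar = bids_io.read_sidecar(sidecar_path)
    return annotate_table(table, sidecar, schema,
                          recording_tags=recording_tags,
                          name=str(events_path))


def validate_file(table: EventTable, sidecar: Sidecar, schema: Schema,
                  name: str | None = None) -> list[Issue]:
    """Collect (rather than raise) all annotation and assembly findings."""
    from .definitions import expand_all
    from .timeline import EventMarker

    name = name if name is not None else table.source_path
    issues: list[Issue] = []
    registry = sidecar.build_registry(schema)
    markers = []
    for idx in table.df.index:
        text = bids_io.row_annotation_text(table, idx, sidecar)
        hs = HedString()
        if text is not None:
            try:
                hs = hstr.resolve(hstr.parse(text), schema)
                from .definitions import strip_definitions
                hs = strip_definitions(hs)
                hs = expand_all(hs, registry, missing="error")
            except HedError as err:
                err.file, err.row = name, int(idx)
                issues.append(Issue.from_error(err))
                hs = HedString()
        markers.append(EventMarker(
            time=float(table.df.loc[idx, "onset"]), annotation=hs,
            row_ref=(name, int(idx))))
    _, assembly_issues = assemble(markers, registry=registry,
                                  on_error="collect")
    issues.extend(assembly_issues)
    return issues
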