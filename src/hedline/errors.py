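"""Error codes and exception hierarchy.

Every diagnostic the engine can raise carries a stable machine-readable code
so that batch validation output (``hedline validate --format json``) can be
consumed programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class ErrorCode(str, Enum):
    # schema
    SCHEMA_DUPLICATE_TERM = "SCHEMA_DUPLICATE_TERM"
    SCHEMA_EMPTY = "SCHEMA_EMPTY"
    SCHEMA_MALFORMED = "SCHEMA_MALFORMED"
    SCHEMA_CYCLE = "SCHEMA_CYCLE"
    SCHEMA_MERGE_COLLISION = "SCHEMA_MERGE_COLLISION"
    SCHEMA_ATTACH_MISSING = "SCHEMA_ATTACH_MISSING"
    TAG_UNKNOWN = "TAG_UNKNOWN"
    TAG_EXTENSION_FORBIDDEN = "TAG_EXTENSION_FORBIDDEN"
    TAG_VALUE_FORBIDDEN = "TAG_VALUE_FORBIDDEN"
    TAG_VALUE_INVALID = "TAG_VALUE_INVALID"
    # strings
    PARSE_UNBALANCED = "PARSE_UNBALANCED"
    PARSE_EMPTY_TAG = "PARSE_EMPTY_TAG"
    PARSE_EMPTY_GROUP = "PARSE_EMPTY_GROUP"
    PARSE_EMPTY_STRING = "PARSE_EMPTY_STRING"
    # definitions
    DEF_DUPLICATE = "DEF_DUPLICATE"
    DEF_MALFORMED = "DEF_MALFORMED"
    DEF_UNKNOWN = "DEF_UNKNOWN"
    DEF_VALUE_MISMATCH = "DEF_VALUE_MISMATCH"
    # events / sidecar
    EVENTS_NO_ONSET = "EVENTS_NO_ONSET"
    EVENTS_BAD_ONSET = "EVENTS_BAD_ONSET"
    EVENTS_RAGGED = "EVENTS_RAGGED"
    SIDECAR_MALFORMED = "SIDECAR_MALFORMED"
    # timeline
    TIMELINE_UNMATCHED_OFFSET = "TIMELINE_UNMATCHED_OFFSET"
    TIMELINE_UNMATCHED_INSET = "TIMELINE_UNMATCHED_INSET"
    TIMELINE_ONSET_NO_ANCHOR = "TIMELINE_ONSET_NO_ANCHOR"
    TIMELINE_OUT_OF_RANGE = "TIMELINE_OUT_OF_RANGE"
    # query
    QUERY_SYNTAX = "QUERY_SYNTAX"
    QUERY_BAD_TERM = "QUERY_BAD_TERM"
    QUERY_DUPLICATE_NAME = "QUERY_DUPLICATE_NAME"
    # summaries
    SUMMARY_MISSING_COLUMN = "SUMMARY_MISSING_COLUMN"
    # synth
    SYNTH_BAD_CONFIG = "SYNTH_BAD_CONFIG"


class HedError(Exception):
    """Base error; carries a code and optional file/row provenance."""

    def __init__(self, code: ErrorCode, message: str, *, file: str | None = None,
                 row: int | None = None):
        self.code = code
        self.file = file
        self.row = row
        super().__init__(message)

    def __str__(self) -> str:  # "file:row: [CODE] message"
        prefix = ""
        if self.file is not None:
            prefix = self.file if self.row is None else f"{self.file}:{self.row}"
            prefix += ": "
        return f"{prefix}[{self.code.value}] {self.args[0]}"


class SchemaError(HedError):
    pass


class ParseError(HedError):
    pass


class ResolutionError(SchemaError):
    """Tag-to-schema resolution failure (a schema-level finding)."""


class DefinitionError(HedError):
    pass


class EventsError(HedError):
    pass


class AssemblyError(HedError):
    pass


class QueryError(HedError):
    pass


@dataclass
class Issue:
    """A collected (non-raised) validation finding."""

    code: ErrorCode
    message: str
    file: str | None = None
    row: int | None = None

    @classmethod
    def from_error(cls, err: HedError) -> "Issue":
        return cls(code=err.code, message=err.args[0], file=err.file, row=err.row)

    def as_dict(self) -> dict:
        return {"code": self.code.value, "message": self.message,
                "file": self.file, "row": self.row}

    def __str__(self) -> str:
        loc = ""
        if self.file is not None:
            loc = self.file if self.row is None else f"{self.file}:{self.row}"
            loc += ": "
        return f"{loc}[{self.code.value}] {self.message}"
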