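"""Synthetic fixtures with exact ground truth.

Three generator families make every other module testable without any
download:

* SART sessions — a sustained-attention (go/no-go) task: digits 0-9 are
  shown in random order and the participant must press a key after every
  digit except the target.  Error probabilities (false alarms on targets,
  misses on non-targets) are configurable, and the generator returns the
  exact per-trial ground truth alongside the event table and sidecar.
* Overlap patterns — small event tables reproducing the canonical
  Duration / Onset-chain / Inset / nested-overlap timelines, together with
  the exact process list the assembler must produce.
* Mini-schema — a deterministic 14-term vocabulary fixture (plus a SART
  extension) exercising values, extensions, and structural tags.

All generators are seeded and byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bids_io import EventTable, Sidecar, write_events, write_sidecar
from .errors import ErrorCode, HedError
from .schema import Schema, load_schema

# ----------------------------------------------------------------------
# schema fixtures


def mini_schema_document() -> dict:
    """The 14-term fixture vocabulary as a schema document."""
    n = []

    def add(term, parent=None, ext=True, value=False, unit=None):
        n.append({"term": term, "parent": parent, "extension_allowed": ext,
                  "takes_value": value, "unit_class": unit})

    add("Item")
    add("Object", "Item")
    add("Ingestible-object", "Item/Object")
    add("2D-shape")
    add("Triangle", "2D-shape")
    add("Red")
    add("Duration", ext=False, value=True, unit="time")
    add("Onset", ext=False)
    add("Offset", ext=False)
    add("Inset", ext=False)
    add("Def", ext=False, value=True)
    add("Definition", ext=False, value=True)
    add("Label", ext=False, value=True)
    add("Description", ext=False, value=True)
    return {"version": "fixture-1.0", "nodes": n}


def generate_mini_schema() -> str:
    """The fixture schema as canonical JSON text (byte-identical per call)."""
    return json.dumps(mini_schema_document(), indent=2, sort_keys=True) + "\n"


def mini_schema() -> Schema:
    return load_schema(mini_schema_document())


def sart_schema_document() -> dict:
    """Mini schema extended with the event/agent/handedness vocabulary the
    SART fixtures annotate with."""
    doc = mini_schema_document()

    def add(term, parent=None):
        doc["nodes"].append({"term": term, "parent": parent,
                             "extension_allowed": True,
                             "takes_value": False, "unit_class": None})

    add("Event")
    add("Sensory-event", "Event")
    add("Agent-action", "Event")
    add("Agent")
    add("Experiment-participant", "Agent")
    add("Action")
    add("Press", "Action")
    add("Sensory-presentation")
    add("Visual-presentation", "Sensory-presentation")
    add("Handedness")
    add("Left-handed", "Handedness")
    add("Right-handed", "Handedness")
    doc["version"] = "fixture-sart-1.0"
    return doc


def sart_schema() -> Schema:
    return load_schema(sart_schema_document())


# ----------------------------------------------------------------------
# SART sessions

#: the go/no-go instruction set as successor rules: after a target only the
#: next stimulus may follow (no response); after a non-target a response must
#: follow; after a response the next stimulus follows.
SART_ALLOWED = {
    "target": ["target", "non_target"],
    "non_target": ["response"],
    "response": ["target", "non_target"],
}


@dataclass
class SartConfig:
    n_trials: int = 200
    target_digit: int = 3
    p_false_alarm: float = 0.10   # P(respond | target)
    p_miss: float = 0.05          # P(no response | non-target)
    stim_duration: float = 0.25   # s on screen
    isi: float = 1.15             # s from stimulus offset to next onset
    rt_range: tuple[float, float] = (0.2, 1.0)  # uniform response latency, s
    seed: int = 0

    def __post_init__(self) -> None:
        ok = (self.n_trials >= 1
              and 0 <= self.target_digit <= 9
              and 0.0 <= self.p_false_alarm <= 1.0
              and 0.0 <= self.p_miss <= 1.0
              and self.stim_duration > 0
              and 0 <= self.rt_range[0] < self.rt_range[1]
              and self.rt_range[1] < self.stim_duration + self.isi)
        if not ok:
            raise HedError(ErrorCode.SYNTH_BAD_CONFIG,
                           f"invalid SART configuration: {self}")


@dataclass
class TrialRecord:
    digit: int
    is_target: bool
    responded: bool
    correct: bool


@dataclass
class GroundTruth:
    n_stimuli: int = 0
    n_responses: int = 0
    n_targets: int = 0
    n_non_targets: int = 0
    n_false_alarms: int = 0
    n_misses: int = 0
    trials: list[TrialRecord] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_stimuli": self.n_stimuli, "n_responses": self.n_responses,
            "n_targets": self.n_targets, "n_non_targets": self.n_non_targets,
            "n_false_alarms": self.n_false_alarms, "n_misses": self.n_misses,
            "trials": [vars(t) for t in self.trials],
        }


def sart_sidecar_document(cfg: SartConfig) -> dict:
    return {
        "definitions": [
            "(Definition/Show-digit/#, "
            "(Sensory-event, Visual-presentation, (Label/#)))",
            "(Definition/Press-key, "
            "(Agent-action, (Experiment-participant, Press)))",
        ],
        "event_type": {"HED": {
            "target": "(Label/Target)",
            "non_target": "(Label/Non-target)",
            "response": "Def/Press-key",
        }},
        "digit": {"HED": f"(Duration/{cfg.stim_duration} s, (Def/Show-digit/#))"},
    }


def generate_sart(cfg: SartConfig) -> tuple[EventTable, Sidecar, GroundTruth]:
    """Simulate one SART session.

    Digits are i.i.d. uniform on 0-9.  A target is followed by a response
    with probability ``p_false_alarm``; a non-target is *not* followed by
    one with probability ``p_miss``.  Response latencies are uniform on
    ``rt_range``, always inside the trial, so row order is stimulus,
    (response), stimulus, ...  Identical seeds give identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    period = cfg.stim_duration + cfg.isi
    t0 = 0.5
    rows = []
    gt = GroundTruth()
    for i in range(cfg.n_trials):
        onset = round(t0 + i * period, 4)
        digit = int(rng.integers(0, 10))
        is_target = digit == cfg.target_digit
        # draw both variates every trial so the stream is digit-independent
        u_resp = rng.random()
        rt = float(rng.uniform(*cfg.rt_range))
        responded = u_resp < (cfg.p_false_alarm if is_target
                              else 1.0 - cfg.p_miss)
        etype = "target" if is_target else "non_target"
        rows.append({"onset": onset, "duration": cfg.stim_duration,
                     "event_type": etype, "digit": str(digit)})
        if responded:
            rows.append({"onset": round(onset + rt, 4), "duration": float("nan"),
                         "event_type": "response", "digit": "n/a"})
        correct = responded != is_target
        gt.trials.append(TrialRecord(digit=digit, is_target=is_target,
                                     responded=responded, correct=correct))
        gt.n_stimuli += 1
        gt.n_targets += int(is_target)
        gt.n_non_targets += int(not is_target)
        gt.n_responses += int(responded)
        gt.n_false_alarms += int(is_target and responded)
        gt.n_misses += int(not is_target and not responded)

    df = pd.DataFrame(rows, columns=["onset", "duration", "event_type", "digit"])
    table = EventTable(df, source_path=f"sart-seed{cfg.seed}_events.tsv")
    sidecar = Sidecar.from_dict(sart_sidecar_document(cfg))
    return table, sidecar, gt


def write_sart_session(cfg: SartConfig, outdir: str | Path) -> dict[str, Path]:
    """Write events.tsv / events.json / ground_truth.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, _, gt = generate_sart(cfg)
    paths = {
        "events": outdir / "events.tsv",
        "sidecar": outdir / "events.json",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_events(table, paths["events"])
    write_sidecar(sart_sidecar_document(cfg), paths["sidecar"])
    paths["ground_truth"].write_text(
        json.dumps(gt.as_dict(), indent=2) + "\n", encoding="utf-8")
    return paths


# ----------------------------------------------------------------------
# overlap patterns

OVERLAP_PATTERNS = ("fig2_duration", "fig2_onset_chain", "fig2_inset",
                    "fig3_nested")

_DEF_SIDECAR = {
    "definitions": [
        "(Definition/A, (Label/Process-A))",
        "(Definition/B, (Label/Process-B))",
        "(Definition/C, (Label/Process-C))",
    ],
}


def _table(rows: list[tuple[float, str]]) -> EventTable:
    df = pd.DataFrame(
        [{"onset": t, "duration": float("nan"), "HED": hed} for t, hed in rows],
        columns=["onset", "duration", "HED"])
    return EventTable(df, source_path="overlap_events.tsv")


def generate_overlap_fixture(pattern: str,
                             ) -> tuple[EventTable, Sidecar, list[dict]]:
    """An event table plus the exact expected process list.

    Expected processes are dicts ``{"anchor": name-or-None, "onset": s,
    "offset": s, "insets": [s, ...]}`` with anonymous Duration processes
    carrying ``anchor=None``.
    """
    sidecar = Sidecar.from_dict(_DEF_SIDECAR)
    if pattern == "fig2_duration":
        # three unrelated Duration processes; the last two overlap
        table = _table([
            (1.0, "(Duration/1.5 s, (Label/First))"),
            (2.0, "(Duration/2 s, (Label/Second))"),
            (3.0, "(Duration/2 s, (Label/Third))"),
        ])
        expected = [
            {"anchor": None, "onset": 1.0, "offset": 2.5, "insets": []},
            {"anchor": None, "onset": 2.0, "offset": 4.0, "insets": []},
            {"anchor": None, "onset": 3.0, "offset": 5.0, "insets": []},
        ]
    elif pattern == "fig2_onset_chain":
        # re-onset of the same anchor closes the previous process
        table = _table([
            (1.0, "(Def/A, (Label/X), Onset)"),
            (3.0, "(Def/A, (Label/Y), Onset)"),
            (5.0, "(Def/A, Offset)"),
        ])
        expected = [
            {"anchor": "A", "onset": 1.0, "offset": 3.0, "insets": []},
            {"anchor": "A", "onset": 3.0, "offset": 5.0, "insets": []},
        ]
    elif pattern == "fig2_inset":
        # the same span annotated as one process with two internal
        # phase transitions
        table = _table([
            (1.0, "(Def/A, (Label/X), Onset)"),
            (2.0, "(Def/A, Inset)"),
            (3.0, "(Def/A, Inset)"),
            (6.0, "(Def/A, Offset)"),
        ])
        expected = [
            {"anchor": "A", "onset": 1.0, "offset": 6.0, "insets": [2.0, 3.0]},
        ]
    elif pattern == "fig3_nested":
        # B and C overlap each other inside A
        table = _table([
            (1.0, "(Def/A, Onset)"),
            (2.0, "(Def/B, Onset)"),
            (4.0, "(Def/C, Onset)"),
            (6.0, "(Def/B, Offset)"),
            (8.0, "(Def/C, Offset)"),
            (10.0, "(Def/A, Offset)"),
        ])
        expected = [
            {"anchor": "A", "onset": 1.0, "offset": 10.0, "insets": []},
            {"anchor": "B", "onset": 2.0, "offset": 6.0, "insets": []},
            {"anchor": "C", "onset": 4.0, "offset": 8.0, "insets": []},
        ]
    else:
        raise HedError(ErrorCode.SYNTH_BAD_CONFIG,
                       f"unknown overlap pattern {pattern!r}; "
                       f"choose from {OVERLAP_PATTERNS}")
    return table, sidecar, expected
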