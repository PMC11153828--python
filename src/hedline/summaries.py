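"""Tag-frequency summaries and event transition graphs.

A transition graph is a directed multigraph over event-marker labels: an
edge A -> B with count c means marker type A was immediately followed by
marker type B exactly c times.  Per-file graphs consolidate by edge-wise
summation.  A task rule set (allowed successor labels per label) classifies
each edge as consistent or inconsistent with task instructions, yielding a
compliance report — e.g. a sustained-attention (go/no-go) task forbids a
response after the target digit and requires one after every other digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx

from .bids_io import AnnotatedFile, EventTable
from .errors import ErrorCode, HedError


@dataclass
class TransitionGraph:
    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    n_events: int = 0
    n_files: int = 0

    @property
    def n_transitions(self) -> int:
        """One fewer transition than markers in each contributing file."""
        return sum(self.edges.values())

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (a, b), count in self.edges.items():
            g.add_edge(a, b, count=count)
        return g

    def to_dot(self, rules: "TaskRuleSet | None" = None) -> str:
        """DOT export; rule-contravening edges are drawn red."""
        lines = ["digraph transitions {"]
        for node in sorted(self.nodes):
            lines.append(f'  "{node}";')
        for (a, b), count in sorted(self.edges.items()):
            attrs = [f'label="{count}"']
            if rules is not None and not rules.permits(a, b):
                attrs.append("color=red")
            lines.append(f'  "{a}" -> "{b}" [{", ".join(attrs)}];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def as_dict(self) -> dict:
        return {
            "nodes": sorted(self.nodes),
            "edges": [{"from": a, "to": b, "count": c}
                      for (a, b), c in sorted(self.edges.items())],
            "n_events": self.n_events,
            "n_files": self.n_files,
        }


@dataclass
class TaskRuleSet:
    """Permitted successor labels per label; unlisted labels allow anything."""

    allowed: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, doc: dict) -> "TaskRuleSet":
        allowed = {str(k): set(map(str, v))
                   for k, v in doc.get("allowed", doc).items()}
        return cls(allowed=allowed)

    def permits(self, a: str, b: str) -> bool:
        if a not in self.allowed:
            return True
        return b in self.allowed[a]


@dataclass
class ComplianceReport:
    edge_flags: dict[tuple[str, str], bool]  # True = consistent
    n_violations: int
    n_transitions: int
    pct_violations: float

    def as_dict(self) -> dict:
        return {
            "n_violations": self.n_violations,
            "n_transitions": self.n_transitions,
            "pct_violations": self.pct_violations,
            "inconsistent_edges": sorted(
                [list(e) for e, ok in self.edge_flags.items() if not ok]),
        }


# ----------------------------------------------------------------------


def transition_graph(table: EventTable, label_column: str = "event_type",
                     ) -> TransitionGraph:
    """Per-file graph of consecutive marker-label pairs in time order.

    Markers with equal onsets transition in file row order (rows are stably
    sorted by onset, so the original order is preserved).
    """
    if label_column not in table.columns:
        raise HedError(ErrorCode.SUMMARY_MISSING_COLUMN,
                       f"no column {label_column!r} in event table",
                       file=table.source_path)
    labels = [str(v) for v in table.df[label_column]]
    g = TransitionGraph(nodes=set(labels), n_events=len(labels), n_files=1)
    for a, b in zip(labels, labels[1:]):
        g.edges[(a, b)] = g.edges.get((a, b), 0) + 1
    return g


def consolidate(graphs: list[TransitionGraph]) -> TransitionGraph:
    """Edge-wise sum of per-file graphs (node union, counts added)."""
    if not graphs:
        raise ValueError("need at least one graph")
    out = TransitionGraph()
    for g in graphs:
        out.nodes |= g.nodes
        out.n_events += g.n_events
        out.n_files += g.n_files
        for edge, count in g.edges.items():
            out.edges[edge] = out.edges.get(edge, 0) + count
    return out


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify(g: TransitionGraph, rules: TaskRuleSet) -> ComplianceReport:
    """Flag rule-contravening transitions, weighted by edge multiplicity.

    The percentage is rounded to one decimal, half away from zero.
    """
    flags = {edge: rules.permits(*edge) for edge in g.edges}
    n_violations = sum(count for edge, count in g.edges.items()
                       if not flags[edge])
    total = g.n_transitions
    pct = _round_half_up(100.0 * n_violations / total) if total else 0.0
    return ComplianceReport(edge_flags=flags, n_violations=n_violations,
                            n_transitions=total, pct_violations=pct)


def tag_counts(dataset: list[AnnotatedFile], enrich: bool = False,
               ) -> dict[str, int]:
    """Occurrences of each long-form term over all marker annotations.

    A tag counts toward its own term only (not its schema ancestors);
    extension components are part of the term, values are not.
    """
    from .query import enriched_annotation  # lazy: avoids import cycle

    counts: dict[str, int] = {}
    for f in dataset:
        for idx, hs in f.annotations:
            if enrich:
                if f.timeline is None:
                    raise ValueError(f"{f.name}: enrich=True needs a timeline")
                t = float(f.table.df.loc[idx, "onset"])
                hs = enriched_annotation(hs, f.timeline, t)
            for tag in hs.tags():
                term = tag.path if tag.path is not None else tag.source
                if tag.extension:
                    term = f"{term}/{tag.extension}"
                counts[term] = counts.get(term, 0) + 1
    return counts
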