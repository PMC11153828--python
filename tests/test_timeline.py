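"""Event-process assembly, ongoing context, and preceding-event queries."""

import random

import pytest

from hedline import api, synth
from hedline.definitions import collect_definitions
from hedline.errors import AssemblyError
from hedline.strings import parse_and_resolve, serialize
from hedline.timeline import (EventMarker, assemble, context_at, preceding)


def _marker(t, text, schema, row=0):
    return EventMarker(time=t, annotation=parse_and_resolve(text, schema),
                       row_ref=("test_events.tsv", row))


def _registry(schema, *def_texts):
    return collect_definitions([parse_and_resolve(t, schema)
                                for t in def_texts])


@pytest.fixture()
def reg(mini_schema):
    return _registry(mini_schema,
                     "(Definition/A, (Label/Process-A))",
                     "(Definition/B, (Label/Process-B))",
                     "(Definition/C, (Label/Process-C))")


class TestAssemble:
    def test_duration_group_spawns_bounded_process(self, mini_schema):
        tl = assemble([_marker(2.0, "(Duration/0.5 s, (Label/X))",
                               mini_schema)])
        (proc,) = tl.processes
        assert proc.onset_t == 2.0
        assert proc.offset_t == pytest.approx(2.5)
        assert serialize(proc.annotation) == "((Label/X))"

    def test_onset_chain_gives_contiguous_processes(self, mini_schema, reg):
        tl = assemble([
            _marker(1.0, "(Def/A, (Label/X), Onset)", mini_schema, 0),
            _marker(3.0, "(Def/A, (Label/Y), Onset)", mini_schema, 1),
            _marker(5.0, "(Def/A, Offset)", mini_schema, 2),
        ], registry=reg)
        spans = [(p.onset_t, p.offset_t) for p in tl.processes]
        assert spans == [(1.0, 3.0), (3.0, 5.0)]
        assert all(p.anchor == "A" for p in tl.processes)

    def test_offset_without_open_process_rejected(self, mini_schema, reg):
        with pytest.raises(AssemblyError, match="no open"):
            assemble([_marker(2.0, "(Def/A, Offset)", mini_schema)],
                     registry=reg)

    def test_insets_recorded_inside_open_process(self, mini_schema, reg):
        tl = assemble([
            _marker(1.0, "(Def/A, Onset)", mini_schema, 0),
            _marker(2.0, "(Def/A, Inset)", mini_schema, 1),
            _marker(3.0, "(Def/A, Inset)", mini_schema, 2),
            _marker(6.0, "(Def/A, Offset)", mini_schema, 3),
        ], registry=reg)
        (proc,) = tl.processes
        assert (proc.onset_t, proc.offset_t) == (1.0, 6.0)
        assert proc.inset_ts == [2.0, 3.0]

    def test_onset_group_without_def_anchor_rejected(self, mini_schema, reg):
        with pytest.raises(AssemblyError, match="lacks a Def anchor"):
            assemble([_marker(1.0, "((Label/X), Onset)", mini_schema)],
                     registry=reg)

    def test_inset_on_anonymous_duration_process_rejected(self, mini_schema,
                                                          reg):
        with pytest.raises(AssemblyError, match="Inset"):
            assemble([_marker(1.0, "((Label/X), Inset)", mini_schema)],
                     registry=reg)

    def test_unclosed_process_closed_at_recording_end_with_warning(
            self, mini_schema, reg):
        with pytest.warns(UserWarning, match="still open"):
            tl = assemble([_marker(1.0, "(Def/A, Onset)", mini_schema)],
                          registry=reg, recording_end=9.0)
        assert tl.processes[0].offset_t == 9.0

    def test_overlapping_duration_processes_never_raise(self, mini_schema):
        tl = assemble([
            _marker(0.0, "(Duration/5 s, (Label/X))", mini_schema, 0),
            _marker(1.0, "(Duration/5 s, (Label/Y))", mini_schema, 1),
            _marker(1.0, "(Duration/1 s, (Label/Z))", mini_schema, 2),
        ])
        assert len(tl.processes) == 3

    def test_anchor_values_are_independent_processes(self, mini_schema):
        reg = _registry(mini_schema, "(Definition/P/#, (Label/#))")
        tl = assemble([
            _marker(1.0, "(Def/P/1, Onset)", mini_schema, 0),
            _marker(2.0, "(Def/P/2, Onset)", mini_schema, 1),
            _marker(3.0, "(Def/P/1, Offset)", mini_schema, 2),
            _marker(4.0, "(Def/P/2, Offset)", mini_schema, 3),
        ], registry=reg)
        spans = {p.anchor: (p.onset_t, p.offset_t) for p in tl.processes}
        assert spans == {"P/1": (1.0, 3.0), "P/2": (2.0, 4.0)}

    def test_same_time_offset_applied_before_onset(self, mini_schema, reg):
        # explicit Offset and a new Onset at the same marker time must not
        # leave the anchor closed or doubly open
        tl = assemble([
            _marker(1.0, "(Def/A, Onset)", mini_schema, 0),
            _marker(3.0, "(Def/A, Offset)", mini_schema, 1),
            _marker(3.0, "(Def/A, Onset)", mini_schema, 2),
            _marker(5.0, "(Def/A, Offset)", mini_schema, 3),
        ], registry=reg)
        spans = [(p.onset_t, p.offset_t) for p in tl.processes]
        assert spans == [(1.0, 3.0), (3.0, 5.0)]

    def test_recording_process_spans_whole_recording(self, mini_schema, reg):
        tl = assemble([_marker(1.0, "(Duration/1 s, (Label/X))", mini_schema)],
                      registry=reg, recording_end=30.0,
                      recording_tags=parse_and_resolve("Label/Session",
                                                       mini_schema))
        assert tl.recording.onset_t == 0.0
        assert tl.recording.offset_t == 30.0
        assert "Label/Session" in serialize(tl.recording.annotation)


class TestContext:
    @pytest.fixture()
    def fig3(self, sart_schema):
        table, sidecar, _ = synth.generate_overlap_fixture("fig3_nested")
        return api.annotate_table(table, sidecar, sart_schema)

    def test_overlap_interior_contains_all_three_and_recording(self, fig3):
        anchors = sorted(p.anchor for p in context_at(fig3.timeline, 5.0))
        assert anchors == ["A", "B", "C", "Recording"]

    def test_after_all_processes_only_recording(self, mini_schema, reg):
        tl = assemble([_marker(1.0, "(Duration/1 s, (Label/X))", mini_schema)],
                      registry=reg, recording_end=10.0)
        assert [p.anchor for p in context_at(tl, 9.0)] == ["Recording"]

    def test_contiguity_boundary_belongs_to_new_process_only(self, mini_schema,
                                                             reg):
        tl = assemble([
            _marker(1.0, "(Def/A, (Label/X), Onset)", mini_schema, 0),
            _marker(3.0, "(Def/A, (Label/Y), Onset)", mini_schema, 1),
            _marker(5.0, "(Def/A, Offset)", mini_schema, 2),
        ], registry=reg)
        active = [p for p in context_at(tl, 3.0) if p.anchor == "A"]
        assert len(active) == 1
        assert active[0].onset_t == 3.0

    def test_time_outside_recording_rejected(self, mini_schema):
        tl = assemble([_marker(1.0, "(Duration/1 s, (Label/X))", mini_schema)])
        with pytest.raises(AssemblyError, match="outside"):
            context_at(tl, 99.0)


class TestPreceding:
    @pytest.fixture()
    def tl(self, mini_schema):
        markers = [_marker(float(i), f"(Label/M{i})", mini_schema, i)
                   for i in range(6)]
        return assemble(markers)

    def test_first_marker_has_empty_history(self, tl):
        assert preceding(tl, tl.markers[0], k=3) == []

    def test_k_larger_than_history_returns_all(self, tl):
        got = preceding(tl, tl.markers[2], k=100)
        assert [m.time for m in got] == [1.0, 0.0]

    def test_most_recent_first(self, tl):
        got = preceding(tl, tl.markers[5], k=3)
        assert [m.time for m in got] == [4.0, 3.0, 2.0]

    def test_filtered_preceding_counts_match_brute_force(self, mini_schema):
        # oddball-style: count target markers among the 3 preceding each one
        rng = random.Random(7)
        kinds = [rng.choice(["target", "standard"]) for _ in range(30)]
        markers = [_marker(float(i), f"Label/{kind}", mini_schema, i)
                   for i, kind in enumerate(kinds)]
        tl = assemble(markers)
        is_target = lambda m: any(t.value == "target" for t in m.annotation.tags())
        for i in range(len(kinds)):
            got = preceding(tl, tl.markers[i], k=3, filter=is_target)
            brute = [m for m in tl.markers[:i][::-1] if is_target(m)][:3]
            assert [m.time for m in got] == [m.time for m in brute]


class TestOracleEquivalence:
    def _random_timeline(self, rng, schema):
        """Random mix of Duration processes and Onset/Offset chains."""
        reg = _registry(schema, "(Definition/A, (Label/Process-A))",
                        "(Definition/B, (Label/Process-B))")
        markers, row = [], 0
        for _ in range(rng.randint(1, 8)):
            t = round(rng.uniform(0, 50), 3)
            d = round(rng.uniform(0.1, 10), 3)
            markers.append(_marker(t, f"(Duration/{d} s, (Label/X))",
                                   schema, row))
            row += 1
        for anchor in ("A", "B"):
            t = 0.0
            for _ in range(rng.randint(0, 4)):
                t += round(rng.uniform(0.5, 10), 3)
                markers.append(_marker(t, f"(Def/{anchor}, Onset)", schema, row))
                row += 1
                t += round(rng.uniform(0.5, 10), 3)
                markers.append(_marker(t, f"(Def/{anchor}, Offset)", schema, row))
                row += 1
        markers.sort(key=lambda m: m.time)
        return assemble(markers, registry=reg, recording_end=120.0)

    def test_context_matches_brute_force_interval_scan(self, mini_schema):
        rng = random.Random(42)
        for _ in range(20):
            tl = self._random_timeline(rng, mini_schema)
            for _ in range(1000):
                t = rng.uniform(0, 120.0)
                got = {id(p) for p in context_at(tl, t)}
                brute = {id(tl.recording)} | {
                    id(p) for p in tl.processes
                    if p.onset_t <= t < p.offset_t}
                assert got == brute

    def test_contiguous_chains_cover_span_without_gaps(self, mini_schema, reg):
        markers = [
            _marker(1.0, "(Def/A, Onset)", mini_schema, 0),
            _marker(2.5, "(Def/A, Onset)", mini_schema, 1),
            _marker(4.0, "(Def/A, Onset)", mini_schema, 2),
            _marker(7.0, "(Def/A, Offset)", mini_schema, 3),
        ]
        tl = assemble(markers, registry=reg)
        spans = sorted((p.onset_t, p.offset_t) for p in tl.processes)
        assert spans[0][0] == 1.0 and spans[-1][1] == 7.0
        for (_, end), (start, _) in zip(spans, spans[1:]):
            assert end == start  # no gaps, no overlaps
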