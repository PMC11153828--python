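"""Abstraction-aware search, context enrichment, factor matrices."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hedline import api, synth
from hedline.errors import QueryError
from hedline.query import (And, GroupQuery, Not, Or, TermQuery, factor_matrix,
                           matches, parse_query, search, validate_query)
from hedline.strings import parse_and_resolve


def _hs(text, schema):
    return parse_and_resolve(text, schema)


class TestParseQuery:
    def test_plain_term(self):
        assert parse_query("2D-shape") == TermQuery("2D-shape")

    def test_comma_list_in_parens_is_group_query(self):
        q = parse_query("(Red, Triangle)")
        assert isinstance(q, GroupQuery)
        assert q.subqueries == [TermQuery("Red"), TermQuery("Triangle")]

    def test_boolean_keywords_case_insensitive(self):
        q = parse_query("Red and not Triangle or Label")
        assert isinstance(q, Or)
        assert isinstance(q.items[0], And)
        assert isinstance(q.items[0].items[1], Not)

    def test_not_outside_and_rejected(self):
        with pytest.raises(QueryError, match="NOT"):
            parse_query("NOT Red")
        with pytest.raises(QueryError, match="NOT"):
            validate_query(Or([Not(TermQuery("Red")), TermQuery("Triangle")]))

    @pytest.mark.parametrize("text", ["", "(Red", "Red AND", "AND Red"])
    def test_malformed_queries_rejected(self, text):
        with pytest.raises(QueryError):
            parse_query(text)


class TestMatches:
    def test_parent_term_matches_schema_child(self, mini_schema):
        ann = _hs("(Red, Triangle)", mini_schema)
        assert matches(ann, TermQuery("2D-shape"), mini_schema)

    def test_parent_term_matches_extension_child(self, mini_schema):
        ann = _hs("2D-shape/Star", mini_schema)
        assert matches(ann, TermQuery("2D-shape"), mini_schema)

    def test_group_query_requires_shared_group(self, mini_schema):
        # direct enumeration of the groups of the two fixture strings:
        # "(Red, Triangle)" has one group holding both; in
        # "Red, (2D-shape, Triangle)" no single group holds Red and Triangle
        q = GroupQuery([TermQuery("Red"), TermQuery("Triangle")])
        assert matches(_hs("(Red, Triangle)", mini_schema), q, mini_schema)
        assert not matches(_hs("Red, (2D-shape, Triangle)", mini_schema),
                           q, mini_schema)

    def test_group_query_matches_at_any_nesting_level(self, mini_schema):
        q = GroupQuery([TermQuery("Red"), TermQuery("Triangle")])
        assert matches(_hs("Label/Q, (Item, (Red, Triangle))", mini_schema),
                       q, mini_schema)

    def test_description_text_excluded_from_term_search(self, mini_schema):
        ann = _hs("Description/A red thing, Triangle", mini_schema)
        assert not matches(ann, TermQuery("Red"), mini_schema)
        assert matches(ann, TermQuery("Description"), mini_schema)

    def test_unresolvable_term_rejected(self, mini_schema):
        with pytest.raises(QueryError, match="not resolvable"):
            matches(_hs("Red", mini_schema), TermQuery("Banana"), mini_schema)

    def test_boolean_combinators(self, mini_schema):
        ann = _hs("(Red, Triangle)", mini_schema)
        assert matches(ann, And([TermQuery("Red"), TermQuery("2D-shape")]),
                       mini_schema)
        assert matches(ann, And([TermQuery("Red"), Not(TermQuery("Label"))]),
                       mini_schema)
        assert matches(ann, Or([TermQuery("Label"), TermQuery("Red")]),
                       mini_schema)


class TestSearch:
    @pytest.fixture()
    def left_handed_file(self, sart_schema):
        table, sidecar, _ = synth.generate_sart(
            synth.SartConfig(n_trials=20, seed=3))
        return api.annotate_table(table, sidecar, sart_schema,
                                  recording_tags=["Left-handed"])

    def test_recording_tag_hits_every_marker_when_enriched(
            self, left_handed_file, sart_schema):
        n_markers = len(left_handed_file.annotations)
        hits = search([left_handed_file], "Left-handed", sart_schema,
                      enrich=True)
        assert len(hits) == n_markers

    def test_recording_tag_invisible_without_enrichment(
            self, left_handed_file, sart_schema):
        assert search([left_handed_file], "Left-handed", sart_schema,
                      enrich=False) == []

    def test_no_match_returns_empty_list(self, left_handed_file, sart_schema):
        assert search([left_handed_file], "Triangle", sart_schema) == []

    def test_enrichment_never_shrinks_hit_sets(self, left_handed_file,
                                               sart_schema):
        for term in ("Sensory-event", "Agent-action", "Label"):
            plain = {(h.file, h.row)
                     for h in search([left_handed_file], term, sart_schema)}
            enriched = {(h.file, h.row)
                        for h in search([left_handed_file], term, sart_schema,
                                        enrich=True)}
            assert plain <= enriched

    def test_process_scope_finds_stimulus_processes(self, left_handed_file,
                                                    sart_schema):
        hits = search([left_handed_file], "Sensory-event", sart_schema,
                      scope="processes")
        n_stimuli = sum(
            1 for _, r in left_handed_file.table.df.iterrows()
            if r["event_type"] in ("target", "non_target"))
        assert len(hits) == n_stimuli


class TestFactorMatrix:
    @pytest.fixture()
    def sart_file(self, sart_schema):
        table, sidecar, gt = synth.generate_sart(
            synth.SartConfig(n_trials=60, seed=5))
        return api.annotate_table(table, sidecar, sart_schema), gt

    def test_exclusive_event_type_queries(self, sart_file, sart_schema):
        af, gt = sart_file
        fm = factor_matrix(
            [af],
            {"target": "(Label/Target)", "non_target": "(Label/Non-target)",
             "response": "Agent-action"},
            sart_schema)
        assert (fm[["target", "non_target", "response"]].sum(axis=1) <= 1).all()
        assert fm["target"].sum() == gt.n_targets
        assert fm["non_target"].sum() == gt.n_non_targets
        assert fm["response"].sum() == gt.n_responses

    def test_sensory_event_count_equals_stimulus_rows(self, sart_file,
                                                      sart_schema):
        af, gt = sart_file
        fm = factor_matrix([af], {"stim": "Sensory-event"}, sart_schema)
        assert fm["stim"].sum() == gt.n_stimuli

    def test_absent_term_gives_all_zero_column(self, sart_file, sart_schema):
        af, _ = sart_file
        fm = factor_matrix([af], {"shape": "2D-shape"}, sart_schema)
        assert fm["shape"].sum() == 0

    def test_duplicate_names_rejected(self, sart_file, sart_schema):
        af, _ = sart_file
        with pytest.raises(QueryError, match="duplicate"):
            factor_matrix([af], [("x", "Red"), ("x", "Triangle")], sart_schema)

    def test_column_sum_equals_search_hits(self, sart_file, sart_schema):
        af, _ = sart_file
        fm = factor_matrix([af], {"press": "Press"}, sart_schema)
        assert fm["press"].sum() == len(search([af], "Press", sart_schema))


# ----------------------------------------------------------------------
# property: abstraction monotonicity along schema edges

_TAG_POOL = ["Red", "Triangle", "2D-shape", "Item", "Object",
             "Ingestible-object", "Ingestible-object/Apple", "Label/Q",
             "2D-shape/Star"]


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.sampled_from(_TAG_POOL), min_size=1, max_size=5))
def test_hits_of_parent_contain_hits_of_child(tags):
    from hedline.synth import mini_schema as _ms
    schema = _ms()
    ann = parse_and_resolve(", ".join(tags), schema)
    edges = [(node.parent_path.rsplit("/", 1)[-1], node.term)
             for node in schema.iter_nodes() if node.parent_path]
    for parent, child in edges:
        if matches(ann, TermQuery(child), schema):
            assert matches(ann, TermQuery(parent), schema)
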