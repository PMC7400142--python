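"""Degree tables, motif census, and influence-path analysis."""

import numpy as np
import pytest

from panelfcm import SystemModel, degree_table, influence_paths, motif_census
from panelfcm.metrics import render_degree_table

from conftest import build_model, random_model


class TestDegreeTable:
    def test_final_model_social_contacts_has_six_incoming_ties(self, final_model):
        df = degree_table(final_model).set_index("factor")
        assert df.loc["social_contacts", "indegree_abs"] == 6
        assert df.loc["social_contacts", "outdegree_abs"] == 3

    def test_source_only_factor_has_zero_weighted_indegree(self, final_model):
        df = degree_table(final_model).set_index("factor")
        assert df.loc["political_climate", "indegree_abs"] == 0
        assert df.loc["political_climate", "indegree_weight_pct"] == 0.0

    def test_rows_sorted_by_impact_descending_ties_by_id(self, final_model):
        df = degree_table(final_model)
        assert df["factor"].iloc[0] == "social_contacts"
        imps = df["impact"].tolist()
        assert imps == sorted(imps, reverse=True)
        tied = df[df["impact"] == 0.77]["factor"].tolist()
        assert tied == sorted(tied)

    def test_empty_graph_gives_all_zero_rows(self):
        m = SystemModel(factors=["a", "b"])
        df = degree_table(m)
        assert (df[["indegree_abs", "indegree_weight_pct",
                    "outdegree_abs", "outdegree_weight_pct"]] == 0).all().all()

    def test_matches_bruteforce_summation_on_random_models(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            m = random_model(rng, allow_nondisplay=True)
            for disp in (True, False):
                df = degree_table(m, display_only=disp).set_index("factor")
                edges = [(u, v, d["weight"]) for u, v, d in m.edges()
                         if d["display"] or not disp]
                total = sum(w for _, _, w in edges)
                for f in m.factor_ids:
                    assert df.loc[f, "indegree_abs"] == \
                        sum(1 for _, v, _ in edges if v == f)
                    expect = 100 * sum(w for _, v, w in edges if v == f) / total \
                        if total else 0.0
                    assert df.loc[f, "indegree_weight_pct"] == pytest.approx(expect)
                    assert df.loc[f, "outdegree_abs"] == \
                        sum(1 for u, _, _ in edges if u == f)

    def test_degree_conservation_and_percent_totals(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            m = random_model(rng)
            df = degree_table(m)
            assert df["indegree_abs"].sum() == df["outdegree_abs"].sum() == m.n_edges
            if m.n_edges:
                assert df["indegree_weight_pct"].sum() == pytest.approx(100.0)
                assert df["outdegree_weight_pct"].sum() == pytest.approx(100.0)

    def test_display_only_flag_excludes_hidden_edges(self, final_model_full):
        shown = degree_table(final_model_full, display_only=True)
        all_e = degree_table(final_model_full, display_only=False)
        assert shown["indegree_abs"].sum() == 24
        assert all_e["indegree_abs"].sum() == 29

    def test_rendering_rounds_like_the_published_table(self, final_model):
        df = render_degree_table(degree_table(final_model))
        assert df["indegree_weight_pct"].dtype.kind == "i"
        assert df.set_index("factor").loc["social_contacts", "impact"] == 0.78


class TestMotifCensus:
    def test_final_model_flagship_fully_reciprocal_triad(self, final_model):
        census = motif_census(final_model)
        assert ("german_language", "social_contacts", "sociocultural_adaptation") \
            in census.fully_reciprocal_triads

    def test_single_edge_has_no_motifs(self):
        census = motif_census(build_model([("A", "B", 6.0)]))
        assert not census.reciprocal_pairs
        assert not census.three_cycles
        assert not census.fully_reciprocal_triads

    def test_complete_bidirectional_graph_counts_are_combinatorial(self):
        ids = ["a", "b", "c", "d"]
        edges = [(s, t, 6.0) for s in ids for t in ids if s != t]
        census = motif_census(build_model(edges))
        assert len(census.reciprocal_pairs) == 6      # C(4,2)
        assert len(census.fully_reciprocal_triads) == 4  # C(4,3)
        assert len(census.three_cycles) == 4

    def test_one_directional_cycle_is_not_fully_reciprocal(self):
        census = motif_census(build_model(
            [("a", "b", 6.0), ("b", "c", 6.0), ("c", "a", 6.0)]))
        assert census.three_cycles == [("a", "b", "c")]
        assert not census.fully_reciprocal_triads
        assert not census.reciprocal_pairs

    def test_every_listed_motif_edge_exists(self, final_model):
        census = motif_census(final_model)
        g = final_model.graph
        for a, b in census.reciprocal_pairs:
            assert g.has_edge(a, b) and g.has_edge(b, a)
        for a, b, c in census.fully_reciprocal_triads:
            for x, y in ((a, b), (b, a), (b, c), (c, b), (a, c), (c, a)):
                assert g.has_edge(x, y)


class TestInfluencePaths:
    def test_line_graph_full_strength(self):
        m = build_model([("A", "B", 10.0), ("B", "C", 10.0)])
        paths = influence_paths(m, "A", "C", max_len=3)
        assert paths == [(["A", "B", "C"], pytest.approx(1.0))]

    def test_indirect_route_from_climate_to_language(self, final_model):
        paths = influence_paths(final_model, "political_climate",
                                "german_language", max_len=2)
        assert ["political_climate", "social_contacts", "german_language"] \
            in [p for p, _ in paths]

    def test_strengths_are_signed_weight_products(self):
        m = build_model([("A", "B", 8.0), ("B", "C", 5.0, -1), ("A", "C", 6.0)])
        paths = dict((tuple(p), s) for p, s in influence_paths(m, "A", "C", 3))
        assert paths[("A", "C")] == pytest.approx(0.6)
        assert paths[("A", "B", "C")] == pytest.approx(-0.4)

    def test_sorted_by_strength_descending(self):
        rng = np.random.default_rng(3)
        m = random_model(rng, n_factors=6, density=0.6)
        ids = m.factor_ids
        paths = influence_paths(m, ids[0], ids[1], max_len=4)
        strengths = [s for _, s in paths]
        assert strengths == sorted(strengths, reverse=True)

    def test_no_route_gives_empty_list(self):
        m = build_model([("A", "B", 6.0)], factors=["A", "B", "C"])
        assert influence_paths(m, "C", "A", 3) == []

    def test_unknown_factor_and_bad_args_raise(self, final_model):
        with pytest.raises(KeyError, match="nowhere"):
            influence_paths(final_model, "nowhere", "housing", 2)
        with pytest.raises(ValueError, match="differ"):
            influence_paths(final_model, "housing", "housing", 2)
        with pytest.raises(ValueError, match="max_len"):
            influence_paths(final_model, "housing", "income_security", 0)
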