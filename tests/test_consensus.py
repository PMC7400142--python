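"""Quorum-and-mean consensus rule and panel aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panelfcm import (ConsensusConfig, ExpertPanel, ExpertRatings, MainFactor,
                      aggregate_panel, categorize_impact, categorize_weight,
                      consensus_weight)

DEFAULT = ConsensusConfig()


def panel_of(ratings_by_expert, factors, impacts=None):
    mains = [MainFactor(id=f, name=f) for f in factors]
    experts = [
        ExpertRatings(expert_id=f"E{k}", influence=dict(infl),
                      impact=dict((impacts or {}).get(f"E{k}", {})))
        for k, infl in enumerate(ratings_by_expert)]
    return ExpertPanel(factors=mains, experts=experts)


# ------------------------------------------------------- consensus_weight

def test_quorum_reproduces_at_least_four_of_six():
    assert DEFAULT.quorum(6) == 4
    assert DEFAULT.quorum(5) == 4
    assert DEFAULT.quorum(3) == 2


@pytest.mark.parametrize("ratings,expected", [
    ([0, 0, 0, 0, 0, 0], None),                 # nobody rated above zero
    ([8, 7, 6, 6, 5, 0], 32 / 6),               # 5 raters, group mean 5.33
    ([6, 6, 6, 6, 0, 0], None),                 # quorum met, mean 4.0 <= 5.0
    ([10, 10, 10, 10, 10, 10], 10.0),
    ([5, 5, 5, 5, 5, 5], None),                 # strict: mean 5.0 is not > 5.0
    ([9, 9, 9, 0, 0, 0], None),                 # only 3 raters < quorum 4
])
def test_consensus_weight_examples(ratings, expected):
    got = consensus_weight(ratings, 6, DEFAULT)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected, abs=1e-12)


def test_mean_over_raters_only_variant():
    cfg = DEFAULT.with_(mean_over="raters_only")
    # same vector that fails under the all-experts mean passes here: 24/4 = 6
    assert consensus_weight([6, 6, 6, 6, 0, 0], 6, cfg) == pytest.approx(6.0)
    assert consensus_weight([8, 7, 6, 6, 5, 0], 6, cfg) == pytest.approx(32 / 5)


def test_out_of_range_rating_is_a_domain_error():
    with pytest.raises(ValueError, match=r"\[0, 10\]"):
        consensus_weight([11, 0, 0, 0, 0, 0], 6, DEFAULT)
    with pytest.raises(ValueError, match="expected 6 ratings"):
        consensus_weight([1, 2, 3], 6, DEFAULT)


@given(st.lists(st.floats(0, 10), min_size=1, max_size=8),
       st.integers(0, 7))
@settings(max_examples=200, deadline=None)
def test_raising_one_rating_never_removes_an_edge(ratings, idx):
    """Monotone in ratings: bumping any single rating keeps a retained edge."""
    idx = idx % len(ratings)
    before = consensus_weight(ratings, len(ratings), DEFAULT)
    bumped = list(ratings)
    bumped[idx] = min(10.0, bumped[idx] + 2.0)
    after = consensus_weight(bumped, len(bumped), DEFAULT)
    if before is not None:
        assert after is not None and after >= before - 1e-12


@given(st.lists(st.floats(0, 10), min_size=2, max_size=8),
       st.floats(0, 10), st.floats(0.1, 1.0))
@settings(max_examples=200, deadline=None)
def test_tightening_thresholds_never_adds_an_edge(ratings, thr, q):
    loose = consensus_weight(ratings, len(ratings), DEFAULT)
    tight = consensus_weight(
        ratings, len(ratings),
        DEFAULT.with_(mean_threshold=max(thr, DEFAULT.mean_threshold),
                      quorum_fraction=max(q, DEFAULT.quorum_fraction)))
    if loose is None:
        assert tight is None


def test_retained_weight_is_exactly_the_configured_mean():
    r = [7.3, 8.1, 6.6, 9.9, 5.5, 6.2]
    assert consensus_weight(r, 6, DEFAULT) == np.mean(r)
    cfg = DEFAULT.with_(mean_over="raters_only")
    r0 = [7.3, 8.1, 6.6, 9.9, 0.0, 0.0]
    assert consensus_weight(r0, 6, cfg) == np.mean([7.3, 8.1, 6.6, 9.9])


# --------------------------------------------------------- aggregate_panel

def test_unanimous_single_pair_yields_single_edge():
    infl = {("A", "B"): 10.0}
    panel = panel_of([infl] * 6, ["A", "B", "C"])
    model = aggregate_panel(panel, DEFAULT)
    assert [(u, v) for u, v, _ in model.edges()] == [("A", "B")]
    assert model.graph.edges["A", "B"]["weight"] == 10.0


def test_node_impact_is_mean_rating_over_ten():
    impacts = {f"E{k}": {"A": 7.8} for k in range(6)}
    panel = panel_of([{}, {}, {}, {}, {}, {}], ["A", "B"], impacts)
    model = aggregate_panel(panel, DEFAULT)
    assert model.impact("A") == pytest.approx(0.78)
    assert model.impact("B") == 0.0


def test_empty_panel_is_rejected():
    with pytest.raises(ValueError, match="at least one expert"):
        ExpertPanel(factors=[MainFactor(id="A", name="A")], experts=[])


def test_self_pair_rejected_at_construction():
    with pytest.raises(ValueError, match="self-pair"):
        ExpertRatings(expert_id="E", influence={("A", "A"): 3.0})


def test_sub_display_edges_are_retained_but_flagged():
    cfg = DEFAULT.with_(mean_threshold=3.0, display_threshold=5.0)
    panel = panel_of([{("A", "B"): 4.0, ("B", "A"): 9.0}] * 6, ["A", "B"])
    model = aggregate_panel(panel, cfg)
    assert model.graph.edges["A", "B"]["display"] is False
    assert model.graph.edges["B", "A"]["display"] is True
    assert model.n_edges == 2
    assert [(u, v) for u, v, _ in model.edges(display_only=True)] == [("B", "A")]


def test_aggregate_matches_bruteforce_on_small_panels():
    """Whole-panel aggregation equals per-pair brute-force enumeration."""
    rng = np.random.default_rng(7)
    grid = [0.0, 3.0, 6.0, 9.0]
    for _ in range(60):
        n_f = int(rng.integers(2, 5))
        n_e = int(rng.integers(1, 5))
        factors = [f"f{i}" for i in range(n_f)]
        experts = []
        for k in range(n_e):
            infl = {(s, t): float(rng.choice(grid))
                    for s in factors for t in factors if s != t}
            experts.append({p: r for p, r in infl.items() if r > 0})
        panel = panel_of(experts, factors)
        model = aggregate_panel(panel, DEFAULT)
        import math
        for s in factors:
            for t in factors:
                if s == t:
                    continue
                vec = [experts[k].get((s, t), 0.0) for k in range(n_e)]
                raters = sum(1 for r in vec if r > 0)
                mean = sum(vec) / n_e
                keep = raters >= math.ceil(2 / 3 * n_e) and mean > 5.0
                assert model.graph.has_edge(s, t) == keep
                if keep:
                    assert model.graph.edges[s, t]["weight"] == pytest.approx(mean)


# ------------------------------------------------------------- categories

@pytest.mark.parametrize("weight,cat", [
    (0.0, "below"), (4.999, "below"),
    (5.0, "medium"), (5.5, "medium"), (5.9, "medium"),
    (6.0, "strong"), (6.9, "strong"),
    (7.0, "powerful"), (7.2, "powerful"), (10.0, "powerful"),
])
def test_weight_categories_partition_the_scale(weight, cat):
    assert categorize_weight(weight) == cat


def test_impact_categories_use_the_same_bins_times_ten():
    assert categorize_impact(0.72) == "powerful"   # daily activities
    assert categorize_impact(0.70) == "powerful"   # boundary: closed-left bin
    assert categorize_impact(0.53) == "medium"     # political and social climate
    with pytest.raises(ValueError):
        categorize_weight(10.5)
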