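"""Degree/weight statistics, motif census, and path analysis on a system model.

The degree table mirrors the published summary of the final model: per
factor the impact score, absolute in/out degree (edge counts) and weighted
in/out degree expressed as the percentage of the total edge weight in the
model carried by that factor's incoming (outgoing) edges.  Each percentage
column therefore sums to 100 at full precision on any non-empty model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .model import SystemModel

__all__ = ["degree_table", "render_degree_table", "MotifCensus",
           "motif_census", "influence_paths"]

DEGREE_COLUMNS = [
    "factor", "impact",
    "indegree_abs", "indegree_weight_pct",
    "outdegree_abs", "outdegree_weight_pct",
]


def degree_table(model: SystemModel, display_only: bool = True) -> pd.DataFrame:
    """Per-factor degree metrics, sorted by impact descending (ties by id).

    ``display_only`` (default) restricts to edges at or above the display
    threshold, matching the published final-model table; with ``False``
    retained sub-display edges also count.  Percentages are computed at
    full precision; round only when rendering.
    """
    edges = list(model.edges(display_only=display_only))
    total_w = sum(d["weight"] for _, _, d in edges)
    rows = []
    for fid in model.factor_ids:
        in_e = [(u, v, d) for u, v, d in edges if v == fid]
        out_e = [(u, v, d) for u, v, d in edges if u == fid]
        in_w = sum(d["weight"] for _, _, d in in_e)
        out_w = sum(d["weight"] for _, _, d in out_e)
        rows.append({
            "factor": fid,
            "impact": model.impact(fid),
            "indegree_abs": len(in_e),
            "indegree_weight_pct": 100.0 * in_w / total_w if total_w else 0.0,
            "outdegree_abs": len(out_e),
            "outdegree_weight_pct": 100.0 * out_w / total_w if total_w else 0.0,
        })
    df = pd.DataFrame(rows, columns=DEGREE_COLUMNS)
    df = df.sort_values(["impact", "factor"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df


def render_degree_table(df: pd.DataFrame) -> pd.DataFrame:
    """Published rendering: impact to 2 decimals, percentages to integers."""
    out = df.copy()
    out["impact"] = out["impact"].round(2)
    for c in ("indegree_weight_pct", "outdegree_weight_pct"):
        out[c] = out[c].round(0).astype(int)
    return out


@dataclass
class MotifCensus:
    """Mutual dyads and 3-node feedback structures of a directed model.

    * ``reciprocal_pairs``: unordered pairs {a, b} with both a->b and b->a.
    * ``three_cycles``: factor triples carrying at least one directed
      3-cycle (a->b->c->a in either orientation); each triple listed once.
    * ``fully_reciprocal_triads``: triples in which all six directed edges
      are present - the self-reinforcing triad pattern.
    """

    reciprocal_pairs: list[tuple[str, str]] = field(default_factory=list)
    three_cycles: list[tuple[str, str, str]] = field(default_factory=list)
    fully_reciprocal_triads: list[tuple[str, str, str]] = field(default_factory=list)


def motif_census(model: SystemModel, display_only: bool = True) -> MotifCensus:
    """Enumerate mutual dyads, directed 3-cycles and fully reciprocal triads."""
    g = nx.DiGraph()
    g.add_nodes_from(model.graph.nodes)
    for u, v, _ in model.edges(display_only=display_only):
        g.add_edge(u, v)
    census = MotifCensus()
    nodes = sorted(g.nodes)
    for a, b in combinations(nodes, 2):
        if g.has_edge(a, b) and g.has_edge(b, a):
            census.reciprocal_pairs.append((a, b))
    for a, b, c in combinations(nodes, 3):
        fwd = g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(c, a)
        bwd = g.has_edge(a, c) and g.has_edge(c, b) and g.has_edge(b, a)
        if fwd or bwd:
            census.three_cycles.append((a, b, c))
        if fwd and bwd:  # both orientations present <=> all 6 directed edges
            census.fully_reciprocal_triads.append((a, b, c))
    return census


def influence_paths(model: SystemModel, source: str, target: str,
                    max_len: int = 3, display_only: bool = True
                    ) -> list[tuple[list[str], float]]:
    """All simple directed paths source -> target up to ``max_len`` edges.

    Path strength is the product of (sign * weight / 10) along the path, a
    reporting convention for comparing indirect influence channels; sorted
    by strength descending, ties by path (shorter, then lexicographic).
    """
    if source not in model or target not in model:
        missing = source if source not in model else target
        raise KeyError(f"unknown factor {missing!r}")
    if source == target:
        raise ValueError("source and target must differ")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    g = nx.DiGraph()
    g.add_nodes_from(model.graph.nodes)
    for u, v, d in model.edges(display_only=display_only):
        g.add_edge(u, v, weight=d["weight"], sign=d.get("sign", 1))
    out = []
    for path in nx.all_simple_paths(g, source, target, cutoff=max_len):
        strength = 1.0
        for u, v in zip(path, path[1:]):
            d = g.edges[u, v]
            strength *= d["sign"] * d["weight"] / 10.0
        out.append((list(path), strength))
    out.sort(key=lambda p: (-p[1], len(p[0]), p[0]))
    return out
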