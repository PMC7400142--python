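"""Core containers shared across the pipeline.

A :class:`SystemModel` is a weighted, signed, directed graph over a set of
main risk factors, together with a per-factor impact score on the modeled
outcome (here: mental health) on a 0-1 scale.  Edge weights live on the
elicitation scale 0-10; signs encode whether an increase in the source
factor increases (+1) or decreases (-1) the target factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = ["MainFactor", "SystemModel"]


@dataclass(frozen=True)
class MainFactor:
    """A consolidated factor of the final system model.

    ``id`` is a short stable identifier (snake_case) used internally and in
    all file formats; ``name`` is the display name.
    """

    id: str
    name: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("MainFactor id must be non-empty")
        if not self.name:
            raise ValueError("MainFactor name must be non-empty")


class SystemModel:
    """Weighted signed digraph over main factors plus impact scores.

    Parameters
    ----------
    factors:
        The node set, as :class:`MainFactor` instances (or bare ids, which
        are promoted to factors whose name equals the id).
    impacts:
        Mapping factor id -> impact score in [0, 1] (group-average impact
        rating divided by 10).  Factors without an entry get impact 0.0.
    provenance:
        Free-form metadata describing how the model was produced
        (aggregation config, panel summary, fixture name ...).
    """

    def __init__(
        self,
        factors: Iterable[MainFactor | str] = (),
        impacts: Mapping[str, float] | None = None,
        provenance: dict | None = None,
    ) -> None:
        self.graph = nx.DiGraph()
        self.provenance: dict = dict(provenance or {})
        for f in factors:
            self.add_factor(f)
        for fid, imp in (impacts or {}).items():
            self.set_impact(fid, imp)

    # -- nodes ---------------------------------------------------------

    def add_factor(self, factor: MainFactor | str, impact: float = 0.0) -> None:
        if isinstance(factor, str):
            factor = MainFactor(id=factor, name=factor)
        self.graph.add_node(factor.id, name=factor.name,
                            description=factor.description, impact=float(impact))

    def set_impact(self, factor_id: str, impact: float) -> None:
        if factor_id not in self.graph:
            raise KeyError(f"unknown factor {factor_id!r}")
        if not 0.0 <= impact <= 1.0:
            raise ValueError(f"impact {impact} outside [0, 1] for {factor_id!r}")
        self.graph.nodes[factor_id]["impact"] = float(impact)

    def impact(self, factor_id: str) -> float:
        return float(self.graph.nodes[factor_id]["impact"])

    @property
    def factor_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    def factor(self, factor_id: str) -> MainFactor:
        d = self.graph.nodes[factor_id]
        return MainFactor(id=factor_id, name=d.get("name", factor_id),
                          description=d.get("description", ""))

    # -- edges ---------------------------------------------------------

    def add_edge(self, source: str, target: str, weight: float,
                 sign: int = 1, display: bool = True, **attrs) -> None:
        """Add a directed influence.  Self-loops are rejected; retained
        edges must carry positive weight on the 0-10 scale."""
        if source == target:
            raise ValueError(f"self-loop on {source!r} not allowed")
        for fid in (source, target):
            if fid not in self.graph:
                raise KeyError(f"unknown factor {fid!r}")
        if not 0.0 < weight <= 10.0:
            raise ValueError(f"edge weight {weight} outside (0, 10]")
        if sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        self.graph.add_edge(source, target, weight=float(weight),
                            sign=int(sign), display=bool(display), **attrs)

    def edges(self, display_only: bool = False) -> Iterator[tuple[str, str, dict]]:
        """Edges in deterministic (source, target) lexicographic order."""
        for u, v in sorted(self.graph.edges):
            d = self.graph.edges[u, v]
            if display_only and not d.get("display", True):
                continue
            yield u, v, d

    def subgraph_display(self) -> "SystemModel":
        """Copy containing only edges at or above the display threshold."""
        out = SystemModel(provenance=dict(self.provenance))
        for fid in self.graph.nodes:
            out.add_factor(self.factor(fid), impact=self.impact(fid))
        for u, v, d in self.edges(display_only=True):
            out.add_edge(u, v, d["weight"], d.get("sign", 1), display=True)
        return out

    # -- misc ----------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, factor_id: str) -> bool:
        return factor_id in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SystemModel):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        for fid in self.graph.nodes:
            if abs(self.impact(fid) - other.impact(fid)) > 1e-9:
                return False
        if set(self.graph.edges) != set(other.graph.edges):
            return False
        for u, v in self.graph.edges:
            a, b = self.graph.edges[u, v], other.graph.edges[u, v]
            if abs(a["weight"] - b["weight"]) > 1e-9:
                return False
            if a.get("sign", 1) != b.get("sign", 1):
                return False
            if bool(a.get("display", True)) != bool(b.get("display", True)):
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover
        return (f"SystemModel({self.graph.number_of_nodes()} factors, "
                f"{self.graph.number_of_edges()} edges)")
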