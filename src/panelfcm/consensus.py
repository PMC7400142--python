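"""Quorum-and-mean consensus aggregation of expert rating panels.

Each expert independently rates every ordered factor pair on a 0-10
influence scale (0 = no influence) and every factor's direct impact on the
outcome on the same scale.  A directed edge enters the consensus model iff

* a quorum of experts - at least ``ceil(quorum_fraction * n_experts)``,
  i.e. "two thirds of the group" with the default 2/3 - rated the pair
  strictly above 0, and
* the group-average rating is strictly above ``mean_threshold``
  (default 5.0).

The retained edge weight is that group mean.  A second, purely cosmetic
``display_threshold`` flags (but keeps) edges below the published display
cutoff.  Whether the group average runs over all experts (zeros of
non-raters included, the default) or over raters only is configurable; the
elicitation protocol's wording ("aggregated average score") does not pin
this down, see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import MainFactor, SystemModel

__all__ = [
    "ExpertRatings",
    "ExpertPanel",
    "ConsensusConfig",
    "consensus_weight",
    "aggregate_panel",
    "categorize_weight",
    "categorize_impact",
    "WEIGHT_CATEGORIES",
]

#: Influence/impact categories on the 0-10 scale, closed-left bins.
WEIGHT_CATEGORIES = (
    ("below", 0.0, 5.0),
    ("medium", 5.0, 6.0),
    ("strong", 6.0, 7.0),
    ("powerful", 7.0, 10.0),
)


@dataclass(frozen=True)
class ConsensusConfig:
    quorum_fraction: float = 2.0 / 3.0
    mean_threshold: float = 5.0
    display_threshold: float = 5.0
    mean_over: str = "all_experts"  # or "raters_only"

    def __post_init__(self) -> None:
        if not 0.0 < self.quorum_fraction <= 1.0:
            raise ValueError("quorum_fraction must be in (0, 1]")
        for name in ("mean_threshold", "display_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 10.0:
                raise ValueError(f"{name} must be in [0, 10], got {v}")
        if self.mean_over not in ("all_experts", "raters_only"):
            raise ValueError("mean_over must be 'all_experts' or 'raters_only'")

    def quorum(self, n_experts: int) -> int:
        """Minimum number of positive raters, ceil(fraction * n)."""
        return math.ceil(self.quorum_fraction * n_experts - 1e-12)

    def with_(self, **kw) -> "ConsensusConfig":
        return replace(self, **kw)


@dataclass
class ExpertRatings:
    """One expert's influence and impact ratings.

    ``influence`` maps ordered (source, target) factor-id pairs to ratings
    in [0, 10]; missing pairs count as 0.  ``impact`` maps factor id to the
    rated direct impact on the outcome, also 0-10.
    """

    expert_id: str
    influence: dict[tuple[str, str], float] = field(default_factory=dict)
    impact: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (s, t), r in self.influence.items():
            if s == t:
                raise ValueError(
                    f"expert {self.expert_id}: self-pair ({s!r}, {t!r}) not allowed")
            _check_rating(r, f"expert {self.expert_id}, pair ({s!r}, {t!r})")
        for f, r in self.impact.items():
            _check_rating(r, f"expert {self.expert_id}, impact of {f!r}")

    def rating(self, source: str, target: str) -> float:
        return float(self.influence.get((source, target), 0.0))


def _check_rating(r: float, where: str) -> None:
    if not 0.0 <= r <= 10.0:
        raise ValueError(f"rating {r} outside [0, 10] ({where})")


@dataclass
class ExpertPanel:
    """All experts' ratings over one shared factor set."""

    factors: list[MainFactor]
    experts: list[ExpertRatings]

    def __post_init__(self) -> None:
        if not self.experts:
            raise ValueError("panel must contain at least one expert")
        if len({f.id for f in self.factors}) != len(self.factors):
            raise ValueError("duplicate factor ids in panel")
        known = {f.id for f in self.factors}
        for ex in self.experts:
            for (s, t) in ex.influence:
                if s not in known or t not in known:
                    raise ValueError(
                        f"expert {ex.expert_id} rates unknown pair ({s!r}, {t!r})")
            for f in ex.impact:
                if f not in known:
                    raise ValueError(
                        f"expert {ex.expert_id} rates impact of unknown factor {f!r}")

    @property
    def n_experts(self) -> int:
        return len(self.experts)

    @property
    def factor_ids(self) -> list[str]:
        return [f.id for f in self.factors]

    def ratings_for_pair(self, source: str, target: str) -> np.ndarray:
        """Rating vector over experts for one ordered pair (0 for non-raters)."""
        return np.array([ex.rating(source, target) for ex in self.experts])


def consensus_weight(ratings_for_pair: Sequence[float], n_experts: int,
                     config: ConsensusConfig = ConsensusConfig()) -> float | None:
    """Consensus weight of one ordered pair, or ``None`` if filtered out.

    ``ratings_for_pair`` must have one entry per expert, zeros standing in
    for experts who saw no influence.  Both filters use strict
    inequalities: raters are those with rating > 0, and the configured mean
    must exceed ``mean_threshold``.
    """
    r = np.asarray(ratings_for_pair, dtype=float)
    if len(r) != n_experts:
        raise ValueError(f"expected {n_experts} ratings, got {len(r)}")
    if np.any(r < 0) or np.any(r > 10):
        raise ValueError("ratings must lie in [0, 10]")
    raters = int(np.sum(r > 0))
    if raters < config.quorum(n_experts):
        return None
    mean = float(r.mean()) if config.mean_over == "all_experts" \
        else float(r[r > 0].mean())
    if mean <= config.mean_threshold:
        return None
    return mean


def aggregate_panel(panel: ExpertPanel,
                    config: ConsensusConfig = ConsensusConfig()) -> SystemModel:
    """Aggregate a panel into a consensus :class:`SystemModel`.

    Every ordered factor pair whose rating vector passes
    :func:`consensus_weight` becomes an edge weighted by the consensus
    mean; edges below ``display_threshold`` are retained with
    ``display=False``.  Node impact is the plain mean impact rating
    divided by 10 (no quorum applies to impacts).
    """
    n = panel.n_experts
    model = SystemModel(provenance={
        "n_experts": n,
        "expert_ids": [e.expert_id for e in panel.experts],
        "quorum_fraction": config.quorum_fraction,
        "mean_threshold": config.mean_threshold,
        "display_threshold": config.display_threshold,
        "mean_over": config.mean_over,
    })
    for f in panel.factors:
        impacts = np.array([ex.impact.get(f.id, 0.0) for ex in panel.experts])
        model.add_factor(f, impact=float(impacts.mean()) / 10.0)
    ids = sorted(panel.factor_ids)
    for s in ids:
        for t in ids:
            if s == t:
                continue
            w = consensus_weight(panel.ratings_for_pair(s, t), n, config)
            if w is not None:
                model.add_edge(s, t, w, sign=1,
                               display=(w >= config.display_threshold))
    return model


def categorize_weight(weight: float) -> str:
    """Bin an influence weight: [0,5) below, [5,6) medium, [6,7) strong, [7,10] powerful."""
    if not 0.0 <= weight <= 10.0:
        raise ValueError(f"weight {weight} outside [0, 10]")
    for name, lo, hi in WEIGHT_CATEGORIES:
        if lo <= weight < hi:
            return name
    return "powerful"  # weight == 10.0


def categorize_impact(impact: float) -> str:
    """Bin a 0-1 impact score with the same bins applied to impact * 10."""
    if not 0.0 <= impact <= 1.0:
        raise ValueError(f"impact {impact} outside [0, 1]")
    return categorize_weight(impact * 10.0)
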