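"""Synthetic ground-truth models and noisy expert panels.

No raw workshop ratings are published for the study system, so the
consensus pipeline is exercised end-to-end against simulated panels: a
sparse ground-truth weighted digraph is drawn, then K experts rate it
independently with additive Gaussian noise, edge-detection dropout
(an expert misses a true influence and rates it 0), and occasional
false-positive ratings on non-edges.  Recovery of the truth by
:func:`panelfcm.consensus.aggregate_panel` is then scored as a confusion
matrix over directed pairs.

Defaults mirror the study conditions: six experts, 0-10 ratings, true
influences above the 5.0 retention threshold, impact scores in the
published 0.5-0.8 range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .consensus import ExpertPanel, ExpertRatings
from .model import MainFactor, SystemModel

__all__ = ["PanelSimConfig", "RecoveryReport", "generate_truth",
           "simulate_panel", "recovery_metrics"]


@dataclass(frozen=True)
class PanelSimConfig:
    """Simulation conditions for one synthetic panel experiment.

    ``weight_law`` / ``false_pos_law`` draw true-edge weights from (5, 10]
    and spurious ratings from (0, 5]; both take a Generator and a size and
    default to uniform laws on those intervals.
    """

    n_factors: int = 10
    edge_density: float = 0.3
    n_experts: int = 6
    rating_noise_sd: float = 1.0
    miss_prob: float = 0.1
    false_pos_prob: float = 0.05
    integer_ratings: bool = False
    seed: int = 0
    weight_law: Callable[[np.random.Generator, int], np.ndarray] | None = None
    false_pos_law: Callable[[np.random.Generator, int], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_factors < 2:
            raise ValueError("n_factors must be >= 2")
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        for name in ("edge_density", "miss_prob", "false_pos_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be >= 0")

    def with_(self, **kw) -> "PanelSimConfig":
        return replace(self, **kw)

    def draw_weights(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.weight_law is not None:
            return np.asarray(self.weight_law(rng, size), dtype=float)
        return rng.uniform(5.0, 10.0, size)

    def draw_false_pos(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.false_pos_law is not None:
            return np.asarray(self.false_pos_law(rng, size), dtype=float)
        return rng.uniform(0.0, 5.0, size)


def _factor_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"f{str(i).zfill(width)}" for i in range(n)]


def generate_truth(config: PanelSimConfig,
                   rng: np.random.Generator | None = None) -> SystemModel:
    """Draw a ground-truth model: directed Erdos-Renyi edges at
    ``edge_density`` (no self-loops), weights from ``weight_law``, impact
    scores uniform on [0.5, 0.8]."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ids = _factor_ids(config.n_factors)
    model = SystemModel(provenance={"kind": "synthetic_truth", "seed": config.seed})
    impacts = rng.uniform(0.5, 0.8, config.n_factors)
    for fid, imp in zip(ids, impacts):
        model.add_factor(MainFactor(id=fid, name=fid), impact=float(imp))
    pairs = [(s, t) for s in ids for t in ids if s != t]
    present = rng.random(len(pairs)) < config.edge_density
    weights = config.draw_weights(rng, len(pairs))
    for (s, t), p, w in zip(pairs, present, weights):
        if p:
            model.add_edge(s, t, float(w), sign=1, display=True)
    return model


def simulate_panel(truth: SystemModel, config: PanelSimConfig,
                   rng: np.random.Generator | None = None) -> ExpertPanel:
    """Simulate K experts rating a ground-truth model.

    Per expert and true edge: with probability ``miss_prob`` the edge is
    missed (rated 0); otherwise the rating is the true weight plus
    N(0, rating_noise_sd) noise, clipped to [0, 10].  Per non-edge pair:
    with probability ``false_pos_prob`` a spurious rating is drawn from
    ``false_pos_law``.  Impact ratings are the true impact * 10 plus the
    same noise, clipped.  When ``rng`` is omitted a fresh generator is
    derived from ``config.seed`` (offset so truth and panel draws differ).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    ids = truth.factor_ids
    true_w = {(u, v): d["weight"] for u, v, d in truth.edges()}
    pairs = [(s, t) for s in ids for t in ids if s != t]
    experts = []
    for k in range(config.n_experts):
        influence: dict[tuple[str, str], float] = {}
        for s, t in pairs:
            if (s, t) in true_w:
                if rng.random() < config.miss_prob:
                    continue
                r = true_w[(s, t)]
                if config.rating_noise_sd > 0:
                    r += rng.normal(0.0, config.rating_noise_sd)
                r = float(np.clip(r, 0.0, 10.0))
            else:
                if rng.random() >= config.false_pos_prob:
                    continue
                r = float(config.draw_false_pos(rng, 1)[0])
            if config.integer_ratings:
                r = float(np.clip(round(r), 0, 10))
            if r > 0:
                influence[(s, t)] = r
        impact = {}
        for fid in ids:
            r = truth.impact(fid) * 10.0
            if config.rating_noise_sd > 0:
                r += rng.normal(0.0, config.rating_noise_sd)
            r = float(np.clip(r, 0.0, 10.0))
            if config.integer_ratings:
                r = float(np.clip(round(r), 0, 10))
            impact[fid] = r
        experts.append(ExpertRatings(expert_id=f"E{k + 1}",
                                     influence=influence, impact=impact))
    return ExpertPanel(factors=[truth.factor(f) for f in ids], experts=experts)


@dataclass
class RecoveryReport:
    """Confusion summary of an estimated model against the ground truth."""

    sensitivity: float
    specificity: float
    f1: float
    weight_rmse: float  # over true-positive edges; nan if none
    confusion: pd.DataFrame = field(repr=False, default=None)  # per-pair labels

    def as_dict(self) -> dict[str, float]:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "f1": self.f1, "weight_rmse": self.weight_rmse}


def recovery_metrics(truth: SystemModel, estimated: SystemModel) -> RecoveryReport:
    """Score edge recovery: confusion over all ordered factor pairs plus
    RMSE of weights on true positives."""
    if set(truth.factor_ids) != set(estimated.factor_ids):
        raise ValueError("truth and estimate must share the same factor set")
    ids = truth.factor_ids
    t_edges = {(u, v): d["weight"] for u, v, d in truth.edges()}
    e_edges = {(u, v): d["weight"] for u, v, d in estimated.edges()}
    rows = []
    tp = fp = tn = fn = 0
    sq_err = []
    for s in ids:
        for t in ids:
            if s == t:
                continue
            in_t, in_e = (s, t) in t_edges, (s, t) in e_edges
            if in_t and in_e:
                label = "tp"
                tp += 1
                sq_err.append((t_edges[s, t] - e_edges[s, t]) ** 2)
            elif in_t:
                label = "fn"
                fn += 1
            elif in_e:
                label = "fp"
                fp += 1
            else:
                label = "tn"
                tn += 1
            rows.append({"source": s, "target": t, "label": label})
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 1.0
    rmse = float(np.sqrt(np.mean(sq_err))) if sq_err else float("nan")
    return RecoveryReport(sensitivity=sens, specificity=spec, f1=f1,
                          weight_rmse=rmse, confusion=pd.DataFrame(rows))
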