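"""Scenario propagation over a system model (standard FCM inference).

The elicited model is static; this module adds the classical cognitive-map
inference step so that what-if scenarios can be run on it.  Activations
live in (0, 1).  One synchronous update of factor *i* is

    a'_i = logistic( lam * ( m * (2 a_i - 1) + sum_j s_ji (w_ji / 10) a_j ) )

where ``lam`` is the squashing steepness, ``m`` the optional self-memory
coefficient (its argument recentred to [-1, 1] so that a memory-only node
rests at 0.5), ``w_ji`` / ``s_ji`` the weight and sign of edge j -> i.
Clamped factors are held at their scenario value.  With no inputs and no
memory a factor settles at logistic(0) = 0.5, read as "no information".

This inference layer is an extension of the elicitation study it serves:
the update rule follows the common FCM tradition and is not itself part of
the expert-derived model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .model import SystemModel

__all__ = ["ScenarioConfig", "ScenarioTrajectory", "step",
           "run_scenario", "compare_scenarios", "ScenarioError"]

_CYCLE_DECIMALS = 12  # state rounding for exact-recurrence cycle detection


class ScenarioError(RuntimeError):
    """A scenario run failed to reach a fixed point where one was required."""


@dataclass(frozen=True)
class ScenarioConfig:
    squash_steepness: float = 1.0
    self_memory: float = 0.0
    clamped: Mapping[str, float] = field(default_factory=dict)
    max_iter: int = 200
    tol: float = 1e-6
    initial: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.squash_steepness <= 0:
            raise ValueError("squash_steepness must be positive")
        if not 0.0 <= self.self_memory <= 1.0:
            raise ValueError("self_memory must be in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        for name, m in (("clamped", self.clamped), ("initial", self.initial)):
            for f, a in m.items():
                if not 0.0 <= a <= 1.0:
                    raise ValueError(f"{name} activation {a} for {f!r} outside [0, 1]")

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


@dataclass
class ScenarioTrajectory:
    """Time-ordered activation states and the termination status."""

    states: pd.DataFrame  # rows = iterations (0 = initial), columns = factor ids
    status: str  # "converged" | "limit_cycle" | "max_iter"

    @property
    def final(self) -> pd.Series:
        return self.states.iloc[-1]

    @property
    def n_steps(self) -> int:
        return len(self.states) - 1


def _arrays(model: SystemModel, config: ScenarioConfig):
    ids = model.factor_ids
    idx = {f: i for i, f in enumerate(ids)}
    n = len(ids)
    w = np.zeros((n, n))  # w[i, j] = signed normalized weight of edge j -> i
    for u, v, d in model.edges():
        w[idx[v], idx[u]] = d.get("sign", 1) * d["weight"] / 10.0
    clamp_idx = np.array([idx[f] for f in config.clamped], dtype=int)
    clamp_val = np.array([config.clamped[f] for f in config.clamped])
    return ids, w, clamp_idx, clamp_val


def _check_clamps(model: SystemModel, config: ScenarioConfig) -> None:
    for f in list(config.clamped) + list(config.initial):
        if f not in model:
            raise KeyError(f"unknown factor in scenario config: {f!r}")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def step(state: Mapping[str, float] | np.ndarray, model: SystemModel,
         config: ScenarioConfig = ScenarioConfig()) -> pd.Series:
    """One synchronous update; returns the next activation vector."""
    _check_clamps(model, config)
    ids, w, ci, cv = _arrays(model, config)
    if isinstance(state, Mapping):
        a = np.array([float(state[f]) for f in ids])
    else:
        a = np.asarray(state, dtype=float)
        if a.shape != (len(ids),):
            raise ValueError(f"state has shape {a.shape}, expected ({len(ids)},)")
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("activations must lie in [0, 1]")
    nxt = _step_arr(a, w, ci, cv, config)
    return pd.Series(nxt, index=ids)


def _step_arr(a: np.ndarray, w: np.ndarray, clamp_idx: np.ndarray,
              clamp_val: np.ndarray, config: ScenarioConfig) -> np.ndarray:
    drive = config.self_memory * (2.0 * a - 1.0) + w @ a
    nxt = _logistic(config.squash_steepness * drive)
    if len(clamp_idx):
        nxt[clamp_idx] = clamp_val
    return nxt


def run_scenario(model: SystemModel,
                 config: ScenarioConfig = ScenarioConfig()) -> ScenarioTrajectory:
    """Iterate the update map until convergence, a limit cycle, or max_iter.

    Starts from 0.5 everywhere unless overridden by ``config.initial``;
    clamps are applied from iteration 0 on.  Convergence means max-norm
    change below ``tol``; a limit cycle is an exact recurrence of a
    previously seen state after rounding to 12 decimals.
    """
    _check_clamps(model, config)
    ids, w, ci, cv = _arrays(model, config)
    a = np.full(len(ids), 0.5)
    for f, v in config.initial.items():
        a[ids.index(f)] = v
    if len(ci):
        a[ci] = cv
    states = [a.copy()]
    seen = {tuple(np.round(a, _CYCLE_DECIMALS)): 0}
    status = "max_iter"
    for _ in range(config.max_iter):
        nxt = _step_arr(a, w, ci, cv, config)
        states.append(nxt.copy())
        if np.max(np.abs(nxt - a)) < config.tol:
            status = "converged"
            break
        key = tuple(np.round(nxt, _CYCLE_DECIMALS))
        if key in seen:
            status = "limit_cycle"
            break
        seen[key] = len(states) - 1
        a = nxt
    df = pd.DataFrame(states, columns=ids)
    df.index.name = "iteration"
    return ScenarioTrajectory(states=df, status=status)


def compare_scenarios(model: SystemModel, baseline: ScenarioConfig,
                      intervention: ScenarioConfig) -> pd.DataFrame:
    """Steady-state factor deltas (intervention - baseline).

    Both runs must converge; otherwise :class:`ScenarioError` names the
    offending run.  The returned frame carries per-factor baseline,
    intervention, and delta columns; the attribute ``composite`` holds the
    impact-weighted sum of deltas, a convenience read-out of the modeled
    net effect on the outcome.
    """
    results = {}
    for name, cfg in (("baseline", baseline), ("intervention", intervention)):
        traj = run_scenario(model, cfg)
        if traj.status != "converged":
            raise ScenarioError(f"{name} run did not converge (status: {traj.status})")
        results[name] = traj.final
    df = pd.DataFrame({
        "baseline": results["baseline"],
        "intervention": results["intervention"],
    })
    df["delta"] = df["intervention"] - df["baseline"]
    impacts = pd.Series({f: model.impact(f) for f in model.factor_ids})
    df.attrs["composite"] = float((impacts * df["delta"]).sum())
    df.index.name = "factor"
    return df
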