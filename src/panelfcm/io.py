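"""Readers, writers and packaged fixtures.

File formats
------------
* influence ratings: CSV ``expert_id,source,target,rating`` (long format,
  one row per rated pair; unrated pairs are implicit zeros);
* impact ratings: CSV ``expert_id,factor,impact_rating``;
* consolidation mapping: YAML with ``main_factors`` and ``actions``;
* raw factor lists: CSV ``label,source_panel``;
* qualitative workshop models: CSV ``source,target,sign,strength`` where
  strength is either categorical (light/medium/strong) or numeric in
  [-1, 1] - never mixed within one file;
* system models: GraphML (lossless round-trip) or DOT (export for
  rendering, re-readable by this module).

All readers raise :class:`ParseError` naming the file and data row on
malformed input.  ``#`` lines in CSV inputs are comments.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .consolidation import ConsolidationAction, RawFactor
from .consensus import ExpertPanel, ExpertRatings, categorize_weight
from .model import MainFactor, SystemModel

__all__ = [
    "ParseError", "QualitativeModel",
    "read_raw_factors", "read_mapping", "read_panel", "write_panel",
    "read_qualitative", "write_model", "read_model", "write_metrics",
    "load_consolidation_mapping", "load_workshop_factors", "load_final_model",
]

#: Display-only numeric stand-ins for categorical relation strengths.
CATEGORICAL_STRENGTHS = {"light": 0.33, "medium": 0.66, "strong": 1.0}


class ParseError(ValueError):
    """Malformed input file; message carries file and row context."""


def _rows(path: str | Path, expected: list[str], what: str):
    """Yield (row_number, dict) from a headered CSV, skipping # comments."""
    path = Path(path)
    with open(path, newline="") as fh:
        filtered = ((i, line) for i, line in enumerate(fh, start=1)
                    if not line.lstrip().startswith("#") and line.strip())
        try:
            first_no, header_line = next(filtered)
        except StopIteration:
            raise ParseError(f"{path}: empty {what} file") from None
        header = next(csv.reader([header_line]))
        if [h.strip() for h in header] != expected:
            raise ParseError(
                f"{path}, line {first_no}: expected header {','.join(expected)}")
        for line_no, line in filtered:
            rec = next(csv.reader([line]))
            if len(rec) != len(expected):
                raise ParseError(
                    f"{path}, line {line_no}: expected {len(expected)} fields, "
                    f"got {len(rec)}")
            yield line_no, dict(zip(expected, (v.strip() for v in rec)))


def _float(value: str, path, line_no, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}, line {line_no}: {what} {value!r} is not a number") \
            from None


# ---------------------------------------------------------------- factors

def read_raw_factors(path: str | Path) -> list[RawFactor]:
    out = []
    for line_no, rec in _rows(path, ["label", "source_panel"], "raw-factor"):
        try:
            out.append(RawFactor(label=rec["label"], source_panel=rec["source_panel"]))
        except ValueError as e:
            raise ParseError(f"{path}, line {line_no}: {e}") from None
    return out


def read_mapping(path: str | Path) -> list[ConsolidationAction]:
    """Read a YAML consolidation mapping into actions with resolved targets."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "actions" not in doc:
        raise ParseError(f"{path}: mapping file must contain an 'actions' list")
    mains = {}
    for m in doc.get("main_factors", []):
        mf = MainFactor(id=m["id"], name=m.get("name", m["id"]),
                        description=m.get("description", ""))
        if mf.id in mains:
            raise ParseError(f"{path}: duplicate main factor id {mf.id!r}")
        mains[mf.id] = mf
    actions = []
    for i, a in enumerate(doc["actions"], start=1):
        try:
            raws = tuple(RawFactor(label=r["label"], source_panel=r["panel"])
                         for r in a.get("raw", []))
            targets = []
            for tid in a.get("targets", []):
                if tid not in mains:
                    raise ValueError(f"unknown main factor {tid!r}")
                targets.append(mains[tid])
            actions.append(ConsolidationAction(
                raw_labels=raws, action=a.get("action", ""),
                main_targets=tuple(targets), rationale=a.get("rationale", "")))
        except (KeyError, TypeError, ValueError) as e:
            raise ParseError(f"{path}: action #{i}: {e}") from None
    return actions


# ------------------------------------------------------------------ panel

def read_panel(influence_path: str | Path, impact_path: str | Path | None = None,
               factors: list[MainFactor] | None = None) -> ExpertPanel:
    """Read long-format rating files into an :class:`ExpertPanel`.

    When ``factors`` is omitted the factor set is the union of ids seen in
    the files.  Out-of-range ratings and self-pairs are rejected with the
    offending row named.
    """
    influence: dict[str, dict[tuple[str, str], float]] = {}
    impact: dict[str, dict[str, float]] = {}
    seen_factors: dict[str, None] = {}
    for line_no, rec in _rows(influence_path,
                              ["expert_id", "source", "target", "rating"],
                              "influence-rating"):
        r = _float(rec["rating"], influence_path, line_no, "rating")
        if not 0.0 <= r <= 10.0:
            raise ParseError(
                f"{influence_path}, line {line_no}: rating {r} outside [0, 10]")
        if rec["source"] == rec["target"]:
            raise ParseError(
                f"{influence_path}, line {line_no}: self-loop on {rec['source']!r}")
        pair = (rec["source"], rec["target"])
        ex = influence.setdefault(rec["expert_id"], {})
        if pair in ex:
            raise ParseError(
                f"{influence_path}, line {line_no}: duplicate rating for expert "
                f"{rec['expert_id']!r}, pair {pair}")
        ex[pair] = r
        seen_factors.setdefault(pair[0])
        seen_factors.setdefault(pair[1])
    if impact_path is not None:
        for line_no, rec in _rows(impact_path,
                                  ["expert_id", "factor", "impact_rating"],
                                  "impact-rating"):
            r = _float(rec["impact_rating"], impact_path, line_no, "impact rating")
            if not 0.0 <= r <= 10.0:
                raise ParseError(
                    f"{impact_path}, line {line_no}: rating {r} outside [0, 10]")
            impact.setdefault(rec["expert_id"], {})[rec["factor"]] = r
            seen_factors.setdefault(rec["factor"])
    expert_ids = sorted(set(influence) | set(impact))
    if not expert_ids:
        raise ParseError(f"{influence_path}: no experts found")
    if factors is None:
        factors = [MainFactor(id=f, name=f) for f in seen_factors]
    try:
        return ExpertPanel(
            factors=factors,
            experts=[ExpertRatings(expert_id=e, influence=influence.get(e, {}),
                                   impact=impact.get(e, {}))
                     for e in expert_ids])
    except ValueError as e:
        raise ParseError(f"{influence_path}: {e}") from None


def write_panel(panel: ExpertPanel, influence_path: str | Path,
                impact_path: str | Path | None = None) -> None:
    """Write a panel in the long formats read by :func:`read_panel`,
    deterministically ordered (expert, then source, target)."""
    with open(influence_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["expert_id", "source", "target", "rating"])
        for ex in panel.experts:
            for (s, t) in sorted(ex.influence):
                w.writerow([ex.expert_id, s, t, repr(ex.influence[s, t])])
    if impact_path is not None:
        with open(impact_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["expert_id", "factor", "impact_rating"])
            for ex in panel.experts:
                for f in sorted(ex.impact):
                    w.writerow([ex.expert_id, f, repr(ex.impact[f])])


# ------------------------------------------------------ qualitative models

@dataclass
class QualitativeModel:
    """A signed workshop model in one of two dialects: categorical
    strengths (light/medium/strong) or numeric strengths in [-1, 1]."""

    nodes: list[str]
    edges: list[tuple[str, str, int, object]]  # (source, target, sign, strength)
    dialect: str  # "categorical" | "numeric"

    def numeric_strength(self, edge_index: int) -> float:
        """Display-only numeric value of one edge's strength."""
        _, _, sign, strength = self.edges[edge_index]
        v = CATEGORICAL_STRENGTHS[strength] if self.dialect == "categorical" \
            else abs(float(strength))
        return sign * v


def read_qualitative(path: str | Path) -> QualitativeModel:
    edges = []
    dialect = None
    nodes: dict[str, None] = {}
    for line_no, rec in _rows(path, ["source", "target", "sign", "strength"],
                              "qualitative-model"):
        if rec["sign"] not in ("+", "-"):
            raise ParseError(f"{path}, line {line_no}: sign must be '+' or '-', "
                             f"got {rec['sign']!r}")
        sign = 1 if rec["sign"] == "+" else -1
        if rec["source"] == rec["target"]:
            raise ParseError(f"{path}, line {line_no}: self-loop on {rec['source']!r}")
        raw = rec["strength"].lower()
        if raw in CATEGORICAL_STRENGTHS:
            kind, strength = "categorical", raw
        else:
            v = _float(raw, path, line_no, "strength")
            if not -1.0 <= v <= 1.0:
                raise ParseError(f"{path}, line {line_no}: numeric strength {v} "
                                 "outside [-1, 1]")
            if (v < 0) != (sign < 0) and v != 0:
                raise ParseError(f"{path}, line {line_no}: numeric strength sign "
                                 "contradicts sign column")
            kind, strength = "numeric", v
        if dialect is None:
            dialect = kind
        elif dialect != kind:
            raise ParseError(f"{path}, line {line_no}: mixed categorical and "
                             "numeric strengths in one model")
        nodes.setdefault(rec["source"])
        nodes.setdefault(rec["target"])
        edges.append((rec["source"], rec["target"], sign, strength))
    return QualitativeModel(nodes=list(nodes), edges=edges,
                            dialect=dialect or "categorical")


# ---------------------------------------------------------- system models

def write_model(model: SystemModel, path: str | Path, format: str = "graphml") -> None:
    """Export a model as GraphML (lossless) or DOT.

    Both carry weight, sign, display, category and node impact attributes;
    both are re-readable by :func:`read_model`.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.DiGraph()
        g.graph["provenance"] = json.dumps(model.provenance, sort_keys=True)
        for fid in model.factor_ids:
            f = model.factor(fid)
            g.add_node(fid, name=f.name, description=f.description,
                       impact=model.impact(fid))
        for u, v, d in model.edges():
            g.add_edge(u, v, weight=d["weight"], sign=d.get("sign", 1),
                       display=bool(d.get("display", True)),
                       category=categorize_weight(d["weight"]))
        nx.write_graphml(g, path)
    elif format == "dot":
        lines = ["digraph system_model {"]
        for fid in model.factor_ids:
            f = model.factor(fid)
            lines.append(
                f'  "{fid}" [label="{f.name}", impact="{model.impact(fid)!r}"];')
        for u, v, d in model.edges():
            disp = "true" if d.get("display", True) else "false"
            lines.append(
                f'  "{u}" -> "{v}" [weight="{d["weight"]!r}", '
                f'sign="{d.get("sign", 1)}", display="{disp}", '
                f'category="{categorize_weight(d["weight"])}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r} (use 'graphml' or 'dot')")


_DOT_NODE = re.compile(r'^\s*"([^"]+)" \[label="([^"]*)", impact="([^"]+)"\];$')
_DOT_EDGE = re.compile(
    r'^\s*"([^"]+)" -> "([^"]+)" \[weight="([^"]+)", sign="(-?1)", '
    r'display="(true|false)", category="[^"]*"\];$')


def read_model(path: str | Path) -> SystemModel:
    """Read a model previously written by :func:`write_model`."""
    path = Path(path)
    if path.suffix == ".dot" or path.read_text().lstrip().startswith("digraph"):
        model = SystemModel()
        for line in path.read_text().splitlines():
            if m := _DOT_NODE.match(line):
                fid, name, imp = m.groups()
                model.add_factor(MainFactor(id=fid, name=name), impact=float(imp))
            elif m := _DOT_EDGE.match(line):
                u, v, w, sign, disp = m.groups()
                model.add_edge(u, v, float(w), sign=int(sign),
                               display=(disp == "true"))
        return model
    g = nx.read_graphml(path)
    model = SystemModel(provenance=json.loads(g.graph.get("provenance", "{}")))
    for n, d in g.nodes(data=True):
        model.add_factor(MainFactor(id=n, name=d.get("name", n),
                                    description=d.get("description", "")),
                         impact=float(d.get("impact", 0.0)))
    for u, v, d in g.edges(data=True):
        model.add_edge(u, v, float(d["weight"]), sign=int(d.get("sign", 1)),
                       display=bool(d.get("display", True)))
    return model


def write_metrics(df: pd.DataFrame, path: str | Path) -> None:
    """Write a degree table as CSV in the published column order."""
    df.to_csv(path, index=False)


# -------------------------------------------------------------- fixtures

def _data_path(name: str):
    return resources.files("panelfcm.data").joinpath(name)


def load_workshop_factors() -> list[RawFactor]:
    """Raw factor lists of the two elicitation workshops."""
    with resources.as_file(_data_path("workshop_factors.csv")) as p:
        return read_raw_factors(p)


def load_consolidation_mapping() -> list[ConsolidationAction]:
    """Packaged keep/merge/split/exclude mapping onto the 11 main factors."""
    with resources.as_file(_data_path("consolidation_mapping.yaml")) as p:
        return read_mapping(p)


def load_final_model(include_sub_display: bool = False) -> SystemModel:
    """The text-attested final consensus model: 11 factors with published
    impact scores and 24 attested directed edges.

    Edge weights are synthetic category stand-ins (the study publishes
    categories, not numbers) - see the fixture header.  With
    ``include_sub_display`` the five below-display-threshold relations
    named in the study's limitations are added with ``display=False``.
    """
    model = SystemModel(provenance={"kind": "final_model_fixture",
                                    "weights": "category midpoints (synthetic)"})
    with resources.as_file(_data_path("final_model_impacts.csv")) as p:
        for _, rec in _rows(p, ["factor", "impact"], "impact"):
            model.add_factor(rec["factor"], impact=float(rec["impact"]))
    files = ["final_model_edges.csv"]
    if include_sub_display:
        files.append("final_model_limitations_edges.csv")
    cols = ["source", "target", "weight", "sign", "display", "category",
            "attestation"]
    for name in files:
        with resources.as_file(_data_path(name)) as p:
            for _, rec in _rows(p, cols, "edge"):
                model.add_edge(rec["source"], rec["target"], float(rec["weight"]),
                               sign=1 if rec["sign"] == "+" else -1,
                               display=(rec["display"] == "true"),
                               attestation=rec["attestation"])
    return model
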