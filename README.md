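# panelfcm

Consensus fuzzy cognitive maps (FCMs) from multi-expert rating panels.

`panelfcm` builds and analyses semi-quantitative system models of
interacting risk factors — the kind elicited in stakeholder workshops
where domain experts first name and consolidate factors, then
independently rate every pairwise influence on a 0–10 scale. The
motivating application is a model of post-migration risk factors for the
mental health of unaccompanied minor refugees (housing, residence
security, language skills, social contacts, access to care, …), but the
pipeline is generic: any panel that produces per-expert influence and
impact ratings over a shared factor set can be aggregated and analysed
with it. It is aimed at researchers in participatory modelling, public
health and systems science.

## The model

An FCM is a weighted, signed digraph \(G = (V, E)\) over concepts
\(V\). Each directed edge \(j \to i\) carries a weight
\(w_{ji} \in (0, 10]\) and a sign \(s_{ji} \in \{+1, -1\}\); each node
carries an impact score (its direct, group-averaged effect on the
modelled outcome, scaled to \([0, 1]\)).

**Consensus rule.** Given \(K\) experts whose ratings of an ordered pair
are \(r_1, \dots, r_K \in [0, 10]\) (0 = no influence), the pair becomes
an edge iff

1. *quorum*: \(\#\{k : r_k > 0\} \ge \lceil \tfrac{2}{3} K \rceil\), and
2. *strength*: \(\bar r > 5.0\), where \(\bar r\) is the group mean
   (by default over all \(K\) experts, zeros included),

and its weight is \(\bar r\). A separate display threshold (5.0) flags
retained edges as hidden rather than deleting them. Weights and impacts
are binned as medium \([5,6)\), strong \([6,7)\), powerful \([7,10]\).

**Analyses.** Impact-ranked degree tables (absolute degree plus the
percentage of total edge weight carried by each node's in/out edges), a
motif census (mutual dyads, directed 3-cycles, fully reciprocal —
self-reinforcing — triads), simple-path indirect-influence analysis, and
scenario propagation \(a_i' = \sigma\!\big(\lambda (m\,(2a_i-1) +
\sum_j s_{ji} \tfrac{w_{ji}}{10} a_j)\big)\) with clamped interventions.

Because raw workshop ratings are typically unpublished, the package
includes a fully seeded synthetic panel generator (ground-truth digraph
+ noisy expert ratings with dropout and false positives) and recovery
scoring (sensitivity/specificity/F1/weight RMSE), so the whole pipeline
is testable end-to-end.

## Worked example

```python
import panelfcm as p
from panelfcm import io as pio

raw = pio.load_workshop_factors()                  # 30 raw workshop factors
mains = p.apply_consolidation(raw, pio.load_consolidation_mapping())
print(len(mains))                                  # 11

model = pio.load_final_model()                     # 11 factors, 24 attested edges
df = p.degree_table(model).set_index("factor")
print(int(df.loc["social_contacts", "indegree_abs"]))   # 6
print(p.motif_census(model).fully_reciprocal_triads)
# [('german_language', 'social_contacts', 'sociocultural_adaptation')]
```

The two workshop factor lists consolidate into 11 main factors; in the
final consensus model, social contacts is the hub with 6 incoming ties,
and German language skills, social contacts and sociocultural adaptation
form a fully reciprocal (self-reinforcing) triad. Note the fixture's
edge *weights* are synthetic category stand-ins (the study publishes
influence categories, not numbers); counts, directions and categories
are the attested content.

The same steps are packaged as narrative drivers:

```sh
python analysis/01_consolidate_factors.py   # 30 raw -> 11 main factors
python analysis/02_final_model_metrics.py   # degree table, motifs, paths
python analysis/03_panel_recovery.py        # synthetic recovery sweep
python analysis/04_scenarios.py             # political-climate what-if
```

with outputs under `results/`, or as a CLI (`panelfcm consolidate`,
`aggregate`, `metrics`, `motifs`, `scenario`, `simulate-panel`,
`report`).

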