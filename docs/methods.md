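# Methods

This note documents the models, conventions and design choices behind
`panelfcm`, in the package's own terms.

## Factor consolidation

Raw factors are free-text labels elicited on moderation cards from two
panels (scientists, practitioners). A consolidation mapping assigns every
raw factor to exactly one action — keep, merge (n→1), split (1→n, n ≥ 2)
or exclude — whose targets are main factors with stable ids. Labels are
matched case-insensitively after trimming and collapsing whitespace,
because hand-written cards are not orthographically stable. Targets with
the same id across actions (e.g. both panels' "Housing") unify into one
main factor. Coverage is strict: an uncovered or doubly covered raw
factor is an error, and `validate_mapping` returns the full problem list
for interactive use.

Consolidation deliberately produces only the node set. Ratings are not
inherited from raw factors (a split factor's history is *not* copied to
both targets): in the elicitation protocol the influence ratings were
collected against the consolidated main factors directly, so there is
nothing to inherit.

The packaged mapping encodes one documented ambiguity: the practitioners'
"Contact with family and family remittances" is filed under income
security, following the published consolidation table, although the
accompanying narrative says it was later excluded; the fixture carries a
comment at that action.

## Consensus aggregation

The edge rule has two independent filters, both using *strict*
inequalities as worded in the elicitation protocol:

* **quorum** — at least ⌈q·K⌉ experts rated the pair above 0
  (q = 2/3 by default, giving "at least 4 of 6");
* **strength** — the group mean exceeds `mean_threshold` (5.0).

The retained weight *is* the configured mean, exactly (no re-scaling), so
retained weights always exceed the mean threshold.

**Which mean?** The protocol's "aggregated average score" does not say
whether zeros of non-raters enter the average. The default is
`mean_over="all_experts"` (zeros included), the literal reading of a
group average; `mean_over="raters_only"` is provided as a config. The
choice matters under missingness: if each expert independently misses a
true influence with probability *m*, the all-experts mean has expectation
(1 − m)·w for a true weight w, so true edges with w just above
`mean_threshold` (specifically w < threshold/(1 − m)) are systematically
suppressed, while the raters-only mean is unbiased for w under that
dropout model. The recovery sweep (`analysis/03_panel_recovery.py`) and
the acceptance script report both variants side by side so this
operating-characteristic gap is visible rather than hidden in a default.

Impacts are aggregated as plain means over all experts, divided by 10 to
the 0–1 scale; no quorum is applied to impacts (nothing in the protocol
suggests one).

A second, purely presentational `display_threshold` (5.0) marks retained
edges below it as `display=false`; degree tables and motif censuses take
a `display_only` flag (default true, mirroring the published final-model
table). With both thresholds at their defaults the non-display set is
empty; configuring `mean_threshold` below `display_threshold` produces
retained-but-hidden edges, which is how the below-cutoff relations listed
in the source study's limitations are representable.

**Categories.** Influence weights and impact×10 share the bins
below [0,5), medium [5,6), strong [6,7), powerful [7,10]. The published
wording leaves a gap between 6.9 and 7.0 ("&gt;7.0" for powerful); the
closed-left [7,10] bin is used so the categories partition the scale, and
7.0 is "powerful" (consistent with a 0.70-impact factor being grouped
with the high-impact factors in the source narrative).

## Network metrics

Per factor: absolute in/out degree (edge counts) and weighted in/out
degree as 100 × (sum of incident edge weights) / (sum of all edge
weights). The total-edge-weight normalisation is used because it makes
each percentage column sum to exactly 100 at full precision, which
matches how the published table's integer columns behave. Percentages are
computed at full precision and rounded only by `render_degree_table`
(impact to 2 dp, percentages to integers). Rows sort by impact
descending, ties broken by factor id for determinism. An edgeless model
defines all percentages as 0.

The motif census enumerates each unordered structure exactly once:
mutual dyads; node triples carrying a directed 3-cycle in either
orientation; and fully reciprocal triads (all six directed edges — which
is equivalent to both 3-cycle orientations being present).

Path strength of a simple directed path is the product of
(sign · weight/10) along it. This is a reporting convention for ranking
indirect influence channels, not an elicited quantity.

## Scenario dynamics

The elicitation study itself performs no simulation; the dynamics module
is an inference extension in the standard FCM tradition. Activations
a ∈ [0,1]; the synchronous update is

    a'_i = σ( λ · ( m·(2a_i − 1) + Σ_j s_ji (w_ji/10) a_j ) )

with logistic σ, steepness λ (default 1), self-memory m ∈ [0,1]
(default 0) and clamped factors held fixed. Conventions:

* weights normalised by 10 so drives are O(1) at λ = 1;
* the self-memory argument is recentred to [−1, 1] so a memory-only node
  rests at 0.5; with m = 0 a disconnected node settles at σ(0) = 0.5,
  read as "no information" rather than "no risk";
* runs start from 0.5 everywhere (overridable), iterate to a fixed point
  (max-norm change < tol, default 1e−6, max 200 iterations), and detect
  limit cycles by exact recurrence of a state rounded to 12 decimals —
  robust to floating-point noise while still catching the period-2
  oscillations that high steepness with negative feedback produces.

On all-positive models the update map is monotone, so componentwise
larger clamped inputs give componentwise ≥ steady states; this is a
structural sanity check exercised by the tests. `compare_scenarios`
additionally reports Σ impact_i · Δa_i, an impact-weighted composite;
the outcome (mental health) is not itself a node, so this read-out is a
convention and labelled as such.

## Synthetic panel generator

The generator emulates the elicitation statistically, and its defaults
are the study conditions: K = 6 experts, 0–10 ratings, true-edge weights
uniform on (5, 10] (above the retention threshold, so the noise-free
recovery test isolates the quorum-and-mean rule rather than the
threshold), node impacts uniform on [0.5, 0.8] (the published impact
range), directed Erdős–Rényi edges at density 0.3 (a mid-sparse regime
comparable to the final model's 24 edges on 110 possible pairs, kept
moderate so confusion counts are informative on both classes).

Expert behaviour per true edge: miss with probability `miss_prob`
(rate 0), else rate weight + N(0, `rating_noise_sd`) clipped to [0, 10];
per non-edge: a false positive with probability `false_pos_prob`
(default 0.05), drawn uniform on (0, 5]. Ratings are continuous by
default (the 0–10 instruction does not state granularity) with an
integer-rounding option. All randomness flows from a single seed.

What the generator does **not** model: expert correlation and herding
(workshop group dynamics), systematic per-expert bias, signed/negative
relations, and semantic disagreement about factor identity. Passing
recovery tests therefore show the *aggregation rule's* operating
characteristics under independent noise, not robustness to social
dynamics of real panels.

Recovery is scored as a confusion matrix over all ordered factor pairs
(sensitivity, specificity, F1) plus RMSE of weights on true positives.

## Numerical and formatting choices

* Quorum ⌈q·K⌉ is computed with a 1e−12 guard against float fuzz in q·K.
* Deterministic ordering everywhere: edges lexicographic by
  (source, target), experts by id, degree rows by (−impact, id).
* GraphML is the lossless model format (weight, sign, display, category,
  impact, provenance as JSON); DOT export is re-readable by the package's
  own reader. Categorical workshop strengths (light/medium/strong) map to
  0.33/0.66/1.0 for display only and never enter aggregation.
* Parse errors name the file and data row.

## Known limitations

* The packaged final-model fixture contains only the 24 prose-attested
  edges; the ~5 remaining edges of the published drawing are omitted as
  non-citable, so weighted-degree percentages computed from the fixture
  are not comparable to the published integer percentages (which also
  depend on unpublished true weights). Tests assert counts, categories
  and structure, never fixture weight magnitudes.
* The consensus rule's mean ambiguity (above) changes recovery
  sensitivity materially under dropout; users analysing panels with
  expected non-response should consider `mean_over="raters_only"`.
* Scenario dynamics are an interpretive layer: steady states depend on
  the squashing convention and weight normalisation, and should be read
  ordinally (which factors move, in which direction), not as calibrated
  magnitudes.
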