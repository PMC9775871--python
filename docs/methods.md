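# Methods

## Fluency networks

### From word lists to a weighted graph

A semantic fluency task yields one ordered word list per participant.
`build_incidence` collapses these into a binary incidence matrix
(participants × distinct words, first-appearance column order;
within-participant repetitions collapse to a single 1). Words produced by
zero participants are kept as all-zero columns so the node set reflects the
full vocabulary handed in; participants with empty lists are kept as
all-zero rows with a warning.

`correlation_matrix` correlates word columns across participants. The
default is Pearson, which on binary columns is the phi coefficient — the
natural co-production association measure, and the default of the R/igraph
ecosystem these analyses are usually run in. Words produced by everyone or
no one have zero variance and no defined correlation; the default policy
keeps the node and zeroes its correlations (flagged), with `nan` and `drop`
alternatives. Negative correlations are retained: the graph-construction
policy (`all` / `positive` / `threshold τ`) decides what becomes an edge,
and the node set is never changed by the policy.

`spanning_tree` extracts a backbone. Because edge weights are similarities,
the default objective is **maximize-similarity**: the spanning tree of
maximal total correlation, identical to the minimal spanning tree under the
distance transform `1 − r` (a property the tests verify). A
`minimize-distance` objective is provided for networks whose weights
already are distances. Ties are broken by lexicographic node-pair order so
results are deterministic. Reported metrics default to the **full weighted
network**, not the tree: a spanning tree has clustering coefficient 0 by
construction, so tree-based CC values near 1 — the empirically interesting
regime for dense fluency networks — are only meaningful on the full graph.
Both targets are available (`metrics_on: full | tree`).

### Network parameters

All metrics follow brute-force-verifiable definitions (the test suite
checks each against exhaustive enumeration on small random graphs):

- **CC** — mean local clustering; unweighted (Watts–Strogatz) or weighted
  (Barrat). Nodes of degree < 2 contribute 0 (stated convention; it changes
  means). The Barrat formula divides clustering mass `(w_ij + w_ih)/2` over
  ordered neighbor pairs by strength × (degree − 1); edges with
  non-positive weight carry no clustering mass and are ignored in weighted
  mode, which is how a similarity interpretation extends to signed
  correlation weights. networkx's weighted clustering implements the Onnela
  geometric-mean variant, not Barrat, so the Barrat coefficient is
  implemented here and cross-checked against igraph's
  `transitivity_avglocal_undirected` in the tests.
- **ASPL** — mean shortest-path length over unordered pairs; `hops` mode
  (default) treats edges as unit length, `weighted-distance` runs Dijkstra
  on `1 − r`. Disconnected graphs fall back to the largest component with a
  warning.
- **S = (CC/CCran)/(ASPL/ASPLran)**; `S > 1` classifies the network as
  small-world. The function validates positivity and is scale-invariant in
  each ratio.
- **Q** — `Σ_c [e_c/m − (d_c/2m)²]` with weights. Community detection
  defaults to Louvain with a fixed seed (deterministic given seed); a
  deterministic CNM greedy and an exhaustive partition search (≤ 12 nodes,
  for oracle testing) are selectable. The reported `q` is always recomputed
  from the returned assignment via the definition, never taken from the
  heuristic's internal bookkeeping.

The default metric modes for the reporting pipeline are weighted (Barrat)
CC and hop ASPL. On near-complete correlation graphs the unweighted CC and
ASPL saturate at 1 (every pair adjacent), so the weighted CC is what keeps
the clustering side informative while hops keep the path side comparable
with the unweighted ER baseline. Every report states the modes used.

### Null validation

`null_ensemble(n, p, reps, seed)` draws Erdős–Rényi graphs `G(n, p)` with
exactly the empirical node count ("similar number of nodes" is read
strictly as equal), default `p = 0.5` and 1000 replicates. Random graphs
are unweighted, so unweighted metric definitions are used inside the
ensemble. Replicate *r* uses seed `seed + r`.

`compare_to_null` reports two statistics. The one-sample *t* of the
ensemble against the empirical value (df = reps − 1, sign positive when the
empirical value exceeds the ensemble mean) is the ensemble-mean comparison;
because its SE shrinks with √reps it is huge for any genuinely different
network and is the reporting convention of the validation literature. The
*z* score `(empirical − mean)/SD` locates the value in the null
distribution itself; it is the calibrated quantity — when the empirical
value is itself drawn from the same ER law, `|z| > 1.96` rejects at ≈ 5%,
which the suite verifies. A pooled variant t-tests per-network z-scores
against zero across several networks.

Note that for ER graphs `E[CC] ≈ p`, so a `p = 0.5` ensemble has CCran near
0.5. Published CCran values near 0.95 for dense empirical networks cannot
arise from an unweighted ER ensemble at `p = 0.5`; this implementation
tests its ensemble against ER theory (binomial edge counts, CC → p), and
the ensemble parameters are fully configurable.

## Priming analysis

### Filtering

Order of operations, each idempotent: (1) drop all trials of subjects whose
overall accuracy is below 0.80 — the boundary case exactly at threshold is
retained, per the strict reading of "lower than"; (2) keep correct trials
only; (3) one non-recursive trimming pass removing trials with
`|rt − mean| > 2.5 SD`, where mean and SD (ddof = 1) are computed within
the trimming scope. The scope is not dictated by the procedure being
reproduced; the default is the dominant RT convention, per
subject × stimulus-type cell, with `subject` and `global` alternatives
exposed because the choice changes what is removed. Scopes with fewer than
two trials are skipped with a warning. Surviving trials gain
`log_rt = ln(rt_ms)`.

### Model

Per language condition: `log_rt ~ stimulus_type`, treatment-coded with
unlearned as the reference level, so the coefficient is the learned-item
shift on the log scale. Under facilitation this coefficient is negative
while the ms priming effect `mean(unlearned) − mean(learned)` is positive —
the two signs are opposite by construction, and both are reported.

Random effects are crossed by-subject and by-item terms fitted as
statsmodels MixedLM variance components (a single all-encompassing group
with `0 + C(subject)`, `0 + C(item)` and their stimulus-type interactions).
Variance components are mutually uncorrelated; lme4-style intercept–slope
correlation terms are not representable in this parameterization, so the
selection ladder operates on uncorrelated terms. A test cross-checks the
crossed-intercepts fit against an lme4 REML fit (fixed effect and SE).

The maximal structure is subject intercept + subject slope + item intercept
+ item slope. Backward selection repeatedly removes the weakest removable
term — slopes are removable immediately, an intercept only after its slope
is gone — using REML likelihood-ratio tests between nested structures
(χ², df = 1, α = 0.05; an AIC mode is available; `none` keeps the starting
structure). If every term is removed the fit collapses to OLS, whose slope
on a balanced design equals the difference of cell means. Non-convergence
of a starting structure triggers an automatic fallback down the same
ladder, recorded in the selection trace. Items are nested within stimulus
type (an item is either learned or unlearned), so the by-item slope is only
weakly identified and is typically pruned first.

Fixed-effect *t* statistics are referred to a between-within (containment)
*t* distribution — df = n_items − 2 for stimulus type (the treatment varies
between items), n_subjects − 1 for the intercept. A plain normal reference
is anti-conservative at the tens-of-items scale typical of these designs;
with containment df the suite's null simulations reject at the nominal 5%
level within Monte-Carlo error.

## Synthetic generators

`simulate_fluency` draws from a planted-cluster Bernoulli model: the
vocabulary is partitioned into latent clusters; each participant owns a
fixed number of clusters (sampled without replacement, keeping expectations
analytic) and produces each owned-cluster word with `p_within`, every other
word with `p_between`. Defaults emulate the empirical study conditions: 32
participants, 5 clusters × 9 words = 45 words (the empirical networks span
40–55), `p_within = 0.9`, `p_between = 0.05`, 3 clusters per participant.
The realized assignments are stored in `dataset.meta` so tests can
recompute exact binomial expectations. What the model does **not** emulate:
retrieval order and clustering/switching dynamics, word frequency effects,
phonological/morphological similarity structure, and cross-language overlap
— so passing tests show the pipeline recovers planted co-production
structure, not that real fluency data have such structure.

`simulate_rt` draws `log RT = μ + b_subject + b_item + β·[learned] + ε`
with independent Gaussian effects, and exponentiates — exactly the
generative process the mixed model assumes, which makes parameter recovery
well-posed. Defaults: 32 subjects, 20 items per
condition × stimulus-type cell, `μ = 6.0` log-ms (≈ 403 ms, within the
empirical range of condition means), `β = −0.12` (the magnitude of the
reported log-scale stimulus-type effect), SDs (0.2, 0.1, 0.3) log-ms for
subject/item/residual, accuracy 0.95. Correctness is drawn independently of
RT; real error processes (speed–accuracy trade-offs, fatigue, sequential
effects) are not modeled.

## Numerical choices

- Spanning-tree and community ids are made deterministic (lexicographic
  tie-breaks; fixed seeds) so pipeline outputs are byte-reproducible; every
  output embeds the config hash and seed.
- Correlations are clipped to [−1, 1] to absorb floating-point excursions;
  edge lists are written at 6 decimal places.
- Degenerate cases raise typed errors (`ValidationError`,
  `UndefinedMetricError`) rather than returning NaN silently: metrics on
  sub-minimal graphs, zero ensemble SD, all-subjects-excluded filters.
- Simulation-based checks in the test suite run at reduced problem sizes
  (e.g. 20 subjects × 20 items/cell, 100–150 replicate datasets), chosen so
  Monte-Carlo error bands — 3 SE throughout — stay meaningful while the
  suite stays fast; the crossed-VC fits dominate the cost and scale roughly
  linearly in replicates × trials.

## Known limitations

- No Satterthwaite/Kenward-Roger df; containment df is a deliberate,
  simpler approximation.
- No intercept–slope correlation in random structures (see above).
- The weighted-CC treatment of negative correlations (no clustering mass)
  is one defensible convention among several; use the `positive` edge
  policy to make the choice explicit upstream.
- Exhaustive modularity search is factorially bounded (≤ 12 nodes); beyond
  that only heuristics are available, and Louvain/greedy carry no
  optimality guarantee.
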