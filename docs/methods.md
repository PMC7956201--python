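# Methods

## Model

`cytobn` models a discretized cytometry panel as a discrete Bayesian
network: a DAG over marker variables (plus categorical clinical variables)
with one conditional probability table per node. The network is a
factorization of the joint distribution of cell-level marker intensities;
an edge means the two variables remain dependent given everything else in
the modelling scope. The clinical response node's direct links (its Markov
neighborhood) are the panel's multivariately direct correlates of outcome.

Assumptions worth stating explicitly:

- **Cells are exchangeable within a dataset.** All cells are pooled across
  patients, so patients contribute proportionally to their cell counts and
  every cell inherits its patient's clinical label. Response probabilities
  in configuration tables are therefore cell-level frequencies, not
  patient-level probabilities; with ~13 patients the effective sample size
  for anything patient-level is 13, not 26,000.
- **Discretization is full-sample.** Bin edges come from the pooled sample
  of the dataset being analyzed, never per patient; per-patient binning
  would silently remove exactly the location differences the analysis is
  meant to find.
- **Intensities are taken as exported** (compensated, untransformed);
  negative post-compensation values are accepted.

## Scoring and search

Family scores are the BDeu log marginal likelihood with equivalent sample
size `ess` (default 1.0). BDeu is score-equivalent — Markov-equivalent
DAGs score identically — so learned edge directions within an equivalence
class are not biologically interpretable; only the skeleton and the
strengths are. The score is decomposable, which makes greedy search and
edge strengths cheap.

The search is sparse-candidates + hill climbing:

- Candidate parent pools: the `k_candidates` (default 8) variables of
  highest plug-in pairwise mutual information, ties broken by column
  order. Indicator variables in contrast analyses bypass this filter (see
  below).
- Moves: add / delete / reverse, restricted to candidate pools; reverse is
  included to escape equivalence-class plateaus. A move must improve the
  total score by more than 1e-9; the best move is taken, ties resolved by
  enumeration order, so the search is deterministic given the seed.
- Restarts (default 20): the first climb starts from the empty graph, the
  rest from random acyclic graphs drawn inside the candidate pools; the
  best local optimum wins.
- `max_parents` (default 4) bounds q, the number of parent configurations;
  at 8 bins q can reach 4096, which ~10^4 cells can still populate
  informatively because BDeu's prior penalizes unsupported complexity.

CPTs are posterior means under the same BDeu pseudo-counts (no zero rows).
Edge strength is the log marginal-likelihood ratio with/without the edge,
local to the child's family. Strengths are comparable within one network
only; the package never compares raw strengths across networks.

## Discretization

Equal-frequency bins, k ∈ [2, 8]. Edge i is the smallest observed value
whose empirical CDF exceeds i/k, so edges are always data values and a run
of tied values can never straddle a boundary; duplicate edges collapse,
shrinking the effective bin count for heavily tied markers. The mapping is
half-open: a value equal to an edge belongs to the upper bin. For distinct
values, per-bin counts differ by at most 1.

## Markov neighborhood and configuration tables

MN = parents ∪ children; blanket additionally includes children's other
parents ("two degrees of separation"), needed when a v-structure hides a
dependence. Both are provided; which to use is the analyst's call.

Strong/weak classification is relative: a member is strong iff its
strength ≥ `rel_threshold` (default 0.3) × the MN maximum. A relative rule
is scale-free, which matters because strengths grow linearly with sample
size. A weak MN edge whose endpoint shares a much stronger edge (default
3×) with another MN member is flagged "possible artifact" — advisory
only, never removed.

Configuration tables use raw conditional frequencies: frequency =
count(config)/n, p_response = responder cells / cells with that config,
unsmoothed, so two conservation laws hold exactly and are tested:
Σ freq = 1 and Σ freq·p_response = overall responder-cell fraction.
Unobserved configurations are omitted. The row cutoff is the first
relative frequency drop ≥ `min_rel_drop` (default 0.15, which fires on a
~0.02 → ~0.017 step) within `max_rows` (default 40). Two sort orders:
keep-most-frequent-then-sort-by-probability (the headline layout, which
ranks only patterns common enough to be population-like) and plain
probability sorting (which surfaces rare, possibly spurious,
high-response patterns).

## Contrast analysis

Regimes are pooled with a categorical indicator column. Indicator columns
are exempt from discretization, are forced into every node's candidate
pool, and have no parent-count cap: the entire point is detecting
indicator linkage, and MI pruning or a parent cap could mask a weak but
real difference. Detection logic: if P(A,B | C=0) ≠ P(A,B | C=1), no
factorization can keep C isolated, so the learned supergraph connects C
within the Markov blanket of {A,B} given enough data — this holds both for
edge appearance/disappearance and for pure location shifts. Conditioning
is implemented as relearning on the state's rows (not CPT slicing), which
matches how stratified networks are actually produced and reported.

Default bins: 8 for stratified/contrast analyses (specificity), 3 for
whole-panel response analyses (sensitivity); both configurable.

## Distances

EMD is computed exactly as the area between the two ECDFs over merged
breakpoints (equal to the sorted-sample mean absolute difference when
sample sizes match). Energy distance is E² = 2E|X−Y| − E|X−X′| − E|Y−Y′|
over the empirical samples, computed in O(n log n) via merged order
statistics and verified against the O(n²) pairwise oracle; it is returned
rooted (√E²) by default with the squared form behind a flag, since both
conventions circulate and E² is the one linear in the Cramér distance.
Distances are computed on raw intensities — no normalization — so EMD is
in fluorescence units. Point-biserial correlation uses the population-SD
form, identical to Pearson correlation with 0/1 labels.

## Synthetic cohorts

The generator emulates the study shape: 13 patients (4 responders), a
14-marker panel, 1000 cells per patient per day, days 1 and 21. Latent
discrete states (3 per marker) are ancestrally sampled from a ground-truth
network; intensities are log-normal around state-dependent log-means
(base log-location 5.0 ≈ 150 a.u., state step 0.8, log-scale 0.5 —
right-skewed, strictly positive, heavy-tailed like compensated cytometry
exports). Regime differences are location shifts (in units of the
marker's nominal SD) and/or edge removals; removal replaces the child's
CPT with the exact conditional under the original joint (computed by
enumeration — generator networks are small), so the only distributional
change is the targeted dependence.

The default contrast-power scenario uses 6 ternary markers, one edge with
CPT contrast 0.85 removed in regime 1, and 4000 cells per regime with
3-bin learning — 3 bins because an 8-bin contrast analysis needs more
cells per parent configuration than the scenario provides.

What the generator does **not** emulate: spillover/compensation artifacts,
autofluorescence, batch effects, doublets/debris, patient-level random
effects, or realistic marker-specific dynamic ranges. Passing tests
therefore demonstrate correctness of the algorithms under the stated
model, not robustness to instrument artifacts; on real data the gating and
QC upstream of this package still matter.

## Numerical choices and problem sizes

- Move acceptance threshold 1e-9 (log-score units); CPT rows sum to 1
  within 1e-9; equivalence-class score identity tested at 1e-9.
- All RNG is `numpy.random.default_rng` seeded explicitly; searches and
  generators are bit-for-bit reproducible given a seed.
- Validation sizes: structure recovery uses 8-node/8-edge networks at
  n = 10,000 over 10 seeds (success = skeleton SHD ≤ 2, ≥ 8/10); contrast
  power/specificity use 20 seeds at 4000 cells/regime; distance oracles
  use 100 random instances at n ≤ 200; conservation uses 50 random
  datasets. These sizes give stable pass/fail behavior across seeds while
  keeping the full validation suite in the seconds-to-minutes range.

## Known limitations

- Edge strengths are not p-values; follow-up with conventional tests is
  expected for any specific marker claim.
- Cell-level pooling means one high-cell-count patient can dominate a
  configuration table; no per-patient weighting option is offered (it
  would change the estimator the tables are defined by).
- The FCS reader covers FCS 3.0/3.1 list-mode files with float (F/D) or
  uniform-width integer (I) data — the common instrument-export case —
  not the full keyword surface of the standard.
- Hill climbing finds local optima; restarts mitigate but do not eliminate
  this, and with ~13 patients the networks should be read as exploratory.
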