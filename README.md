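# cytobn

Bayesian-network secondary analysis of flow-cytometry marker panels.

Standard cytometry analysis reduces each marker to a per-patient summary
and tests markers one at a time. `cytobn` instead treats the cell-level
compensated fluorescence intensities of a whole panel as draws from a joint
distribution and asks which markers are *directly* informative about a
clinical outcome once all the others are accounted for. It is aimed at
immunologists and computational biologists doing secondary analysis of
small immunotherapy cohorts — a dozen patients, a 14-marker T-cell panel,
thousands of cells per sample — where multivariate structure is the signal
and per-marker univariate tests are underpowered or confounded.

## Method

1. **Equal-frequency discretization.** Each marker is binned into
   k ∈ [2, 8] equal-frequency bins on the full pooled sample (label 0 =
   "low", k−1 = "high"). Fewer bins increase sensitivity (denser
   networks), more bins increase specificity. Tied values never straddle a
   bin boundary.
2. **Structure learning.** A discrete Bayesian network is learned over the
   binned markers plus any categorical clinical variables (responder
   label, timepoint). Families are scored with the BDeu log marginal
   likelihood

   `score(X | Pa) = Σ_j [lnΓ(α_j) − lnΓ(α_j + N_j)] + Σ_{j,k} [lnΓ(α_jk + N_jk) − lnΓ(α_jk)]`

   with α_j = ess/q, α_jk = ess/(q·r), and the search is sparse-candidates
   (top-k mutual-information parent pools) plus greedy add/delete/reverse
   hill climbing with random restarts. Each retained edge carries a
   **strength**: the log marginal-likelihood ratio of the network with and
   without that edge (comparable within one network only).
3. **Markov neighborhood.** The markers directly linked to the response
   node — its Markov neighborhood (MN), or optionally the full Markov
   blanket — are the panel's direct correlates of outcome, split into
   strong and weak links by a relative strength threshold.
4. **Configuration tables.** The joint level combinations of the MN
   markers (3^5 = 243 for five ternary markers) are ranked by frequency,
   truncated at a frequency dropoff, and re-sorted by the empirical
   probability of response given the configuration — a compact rule set
   mapping marker patterns to outcome.
5. **Contrast analysis.** To compare conditions (responder vs
   nonresponder, pre vs post therapy), stratified datasets are pooled with
   an indicator ("contrast") variable and a supergraph is learned. Any
   regime difference — an edge appearing/disappearing, or a single marker
   shifting — pulls the contrast node into the Markov blanket of the
   affected markers. Conditioning the supergraph on a contrast state
   recovers the stratified network.
6. **Distribution distances.** Per-marker responder/nonresponder
   differences are quantified with the exact 1-D Earth Mover's Distance
   (area between the two ECDFs, in fluorescence units), the energy
   distance, and the point-biserial correlation.

Cells can first be gated into the four major T-cell subsets (naive /
non-naive × CD4 / CD8) by panel-specific thresholds on CD4, CD8, CCR7 and
CD45RA, and a synthetic-cohort generator produces study-shaped data with
known ground truth for validation.

## Worked example

Simulate a study-shaped cohort (13 patients, 4 responders, 14 markers,
500 cells/patient/day, responders' TIGIT shifted up by 1.5 SD), then run
the pipeline:

```python
from cytobn.synthetic import CohortSpec, simulate_cohort
from cytobn.io import write_table

spec = CohortSpec(cells_per_patient=500,
                  location_effects=[("TIGIT", "day1_R", 1.5),
                                    ("TIGIT", "day21_R", 1.5)])
cells, _ = simulate_cohort(spec, seed=7)
write_table("cohort.csv", cells)
```

```bash
cytobn learn     --input cohort.csv --bins 3 --seed 1 --out out_learn
cytobn distances --input cohort.csv --out out_dist
```

`out_learn/mn_report.tsv` — the Markov neighborhood of the response node:

```
member  direction  strength            class   flag
TIGIT   child      1856.2882333060552  strong
```

The network links response directly to TIGIT alone — exactly the marker
that was shifted — with an edge strength of ~1856 (log marginal-likelihood
units). `out_learn/config_table.tsv` then gives response probability by
TIGIT level:

```
config  frequency            p_response
(2)     0.3333846153846154   0.47231195200738346
(1)     0.3333076923076923   0.4373413339487653
(0)     0.3333076923076923   0.013385645049619201
```

Cells with low TIGIT (bin 0) respond at ~1%, cells in the upper bins at
~44–47%. `out_dist/distances.tsv` ranks markers by responder-vs-
nonresponder EMD:

```
Feature  Earth Mover's Distance  Energy Distance
TIGIT    138.3157537937122       8.675560362312998
TIM-3    6.708590142324327       0.4459712289709451
KLRG1    6.328080714283014       0.37470602491335625
```

The shifted marker's EMD (~138 fluorescence units) dwarfs the null
markers' (~5–7), which reflect only sampling noise.

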