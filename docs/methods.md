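# Methods

## Data model and alteration calling

Expression travels as a genes × samples matrix with a flagged reference
("diploid") panel. For gene *g* and tumor sample *s* the reference-relative
z-score is

    z_gs = (x_gs − mean_ref(g)) / sd_ref(g)

with the unbiased (n−1) SD; at least two reference samples are required and
a zero reference SD is an error naming the gene (no silent imputation —
missing values are rejected at load time). A gene is *altered* in a sample
when |z| > 2 strictly; the interval [−2, 2] including the endpoints is
non-altered. A sample's status for a signature is the union rule: altered
iff at least one signature gene is altered. Under pure noise the two-tailed
call rate is 2·Φ(−2) ≈ 4.55%, which the test suite verifies within binomial
error. Gene identifiers match case-sensitively after whitespace stripping.

## Survival engine

Kaplan–Meier estimation and Cox proportional-hazards regression are backed
by lifelines (Efron handling of tied event times; Wald 95% CIs and p-values,
matching how portal outputs report HR with symmetric-looking CIs). Median
survival is the first event time where S(t) ≤ 0.5. The k-sample log-rank
test is implemented in-package with numpy — the cut-point scans and the SGR
loop evaluate it tens of thousands of times per analysis — using the
standard hypergeometric moments at each distinct event time and the
quadratic form over the first k−1 groups; the tests verify exact agreement
with lifelines and with a hand-coded O/E/V oracle on exhaustive small
datasets (all event/group assignments, n ≤ 8, with and without ties).
Monotone partial likelihood (perfect separation) is reported as
`converged=False` rather than raising or returning silently.

## Signature refinement

**SGR (single-gene removal).** At each step all |S| one-gene removals are
evaluated by the log-rank p of the remaining signature's
altered-vs-unaltered split; the minimum wins, ties break to the
lexicographically smallest removed gene and are flagged on the trace. A
candidate whose removal makes the status vector constant scores p = 1.
Stopping is either at a target size or at the first step where no removal
improves the current p. The procedure is deterministic; the full
p-trajectory is recorded.

**k-TSP.** For every unordered gene pair, Δ is the absolute between-class
difference of the within-sample order frequency P(X_i < X_j), with ties
counting 0.5; γ, the secondary score, is the absolute between-class
difference of the mean within-sample rank gap. Both are rank statistics,
invariant to any strictly increasing per-sample transform (verified by
test). Selection takes pairs in decreasing (Δ, γ) order, skipping pairs
sharing a gene; classification is the majority vote of the k (odd) pair
comparisons, a within-sample tie voting against the pair's "less"
orientation. Survival data are reduced to two classes at a horizon T
(default 120 months): event before T vs event-free follow-up ≥ T, dropping
samples censored before T — the horizon is a parameter because no single
convention exists.

**Combination rule.** The final signature is the de-duplicated union of the
SGR core, the genes of the selected k-TSP pairs and the single-marker genes
(those whose individual altered-vs-unaltered log-rank p clears `singles_alpha`,
default 0.05), in that order.

## Risk stratification

The prognostic index is PI_s = Σ_g β_g z_gs with β from a multivariable Cox
fit of the signature genes (an equal-weight meta-gene mean is available as
an alternative scorer). Splitters:

- *maximized risk groups*: exhaustive scan of cut-points (midpoints between
  consecutive distinct sorted scores; all ordered pairs for 3 groups) under
  a minimum group fraction (`min_frac`, default 0.1 — the portals do not
  publish their constraint, so it is explicit and configurable), keeping
  the partition with minimum log-rank p. Ties in score at a cut go to the
  lower group; ties in p go to the first (lowest) cut, deterministically.
  The median-split p is reported alongside for contrast.
- *quantile splits*: median; Q1 vs Q4; T1 vs T3 with the middle omitted —
  omitted samples are labelled `excluded` and take no part in testing.
- *best-cutoff with FDR*: candidates restricted to the interquartile window
  (configurable), BH correction across the candidate family of one scan,
  selection by minimum raw p with both raw p and adjusted q reported.

All splitters depend on the scores only through ranks, so they are
invariant under strictly increasing transforms (except the cut-point
coordinates themselves).

## Over-representation

Upper-tail hypergeometric probability of the observed query/set overlap in
an explicitly supplied universe (portal analyses rely on an implicit
platform universe, which is not reproducible offline; here it is an
argument). Query or set genes outside the universe are dropped with a
logged count. The tail probability comes from `scipy.stats.hypergeom.sf`;
tests pin it to exhaustive enumeration for N ≤ 12 and to Monte-Carlo draw
frequencies. BH q-values use the standard step-up procedure
(statsmodels), returned in input order.

## Synthetic cohorts

The generator emulates the statistical shape of a portal cohort so the
whole pipeline is testable offline:

- reference samples: standard normal per gene (n_reference = 50 by
  default);
- tumor samples (n_tumor = 300): standard normal, except each prognostic
  gene is shifted by +`alteration_shift` (default 4 SD, so carriers are
  called altered at |z| > 2 with probability ≈ 0.98) in a latent high-risk
  carrier subset of fraction `risk_frac` (default 0.25). `carrier_mode`
  chooses independent per-gene carrier subsets (default — genes are
  individually informative) or one shared subgroup (genes mutually
  redundant);
- survival: exponential event times with hazard
  `baseline_hazard · exp(lp)`. Under the default `hazard_model="carrier"`,
  lp = Σ_g β_g·shift·carrier_gs, i.e. each carried gene multiplies the
  hazard by exp(β·shift) — 2.0 at the defaults (β = ln 2 / shift), the
  "alteration doubles hazard" planting. `hazard_model="z"` instead uses the
  continuous lp = Σ_g β_g z_gs, which leaks hazard into sub-threshold
  samples and is kept for proportional-hazards parameter-recovery studies;
- censoring: independent exponential (`censor_rate`, default 0.0043/month ≈
  30% censoring against the 0.01/month baseline) truncated at an
  administrative horizon (240 months, a >20-year follow-up);
- two-class labelling at `class_horizon_T` (120 months) for k-TSP, with an
  optional injected "switched pair" whose class-typical order is enforced
  with probability `fidelity` per sample (expected Δ = |2·fidelity − 1|).

Exponential (constant-baseline-hazard) survival is the simplest law
satisfying proportional hazards; the downstream tests are rank-based, so
the baseline shape is immaterial. One seeded `numpy.random.Generator`
drives all draws in a fixed order, so a config + seed pins every output
bit-for-bit.

What the generator does **not** emulate: microarray probe effects, batch
structure, copy-number-driven expression, correlated co-expression modules,
non-proportional hazards, informative censoring. Passing tests demonstrate
the statistical machinery is correct and calibrated under this clean model,
not that any particular real-data signature is valid.

## Behaviour of minimum-p selection (measured, and a known limitation)

Two procedures here select the minimum p-value over a family — the
maximized risk-group cut and the SGR removal step — and both inherit the
well-known optimism and instability of that selection:

- the maximized-partition p is a minimum over all feasible cuts and is
  always ≤ the median-split p; it is not a calibrated p-value. The
  best-cutoff scan makes the cost visible: under the null the uncorrected
  selected-cut p is < 0.05 in ~20–25% of runs, while the BH-adjusted q
  restores ~nominal control (both measured by the acceptance script).
- cut-point recovery: with a planted 50/50 N(0,1) / N(3,1) score mixture
  and hazard doubled in the upper component (n = 400), the maximized cut
  centres on the component boundary but with sampling SD ≈ 0.55, so only
  ~60–70% of runs land within ±0.5 of the boundary.
- feature recovery: with three planted genes (alteration doubles hazard,
  prevalence 0.25, n = 300) among seven noise genes, SGR to size 3 returns
  exactly the planted triple in only ~20% of cohorts, and even exhaustive
  minimum-p search over all 3-subsets does no better — moving one gene's
  unique carriers into the majority group can *raise* the log-rank
  statistic (a smaller, purer high-risk group), so the objective's argmin
  is not the true carrier set at these effect sizes. Reliable exact
  recovery under this objective needs per-gene hazard ratios well above 3
  or much larger cohorts.

These rates are recomputed, not assumed: `scripts/acceptance.py` reports
them (`cutpoint_recovery_pct`, `sgr_recovery_pct`, `bestcut_*_fpr`) and two
acceptance tests assert the stricter recovery levels one might hope for —
they fail at the default study conditions, quantifying the limitation
rather than hiding it.

## Numerical and design choices

- Log-rank covariance uses the pooled hypergeometric variance with the
  (n_j − d_j)/(n_j − 1) tie factor; a singular covariance falls back to the
  pseudo-inverse and the statistic is clipped at 0.
- Cut-point candidates are midpoints between consecutive distinct sorted
  scores: this exhausts all distinct partitions without inventing a grid.
- BH correction in the best-cutoff scan is per-scan (the candidate family
  of one search), not global across analyses.
- The pipeline report is schema-versioned JSON with sorted keys and no
  timestamps; plots (optional) are side artifacts never read back by code.
- CLI exit codes: 0 success, 2 validation error, 1 runtime error.
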