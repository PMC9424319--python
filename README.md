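# sigforge

Discovery and evaluation of prognostic gene-expression signatures, of the
kind used in breast-cancer outcome studies: call per-gene *alterations* from
expression z-scores relative to a diploid/reference panel, test their
association with censored survival, shrink a candidate signature to a
minimal prognostic core, and stratify patients into risk groups.

It is written for computational biologists who have a gene-by-sample
expression matrix, a clinical follow-up table and a candidate gene list, and
want the portal-style analyses (cBioPortal / KM-plotter / SurvExpress
conventions) as reproducible, scriptable library calls — plus a synthetic
cohort generator with planted prognostic structure so every stage can be
validated without downloading patient data.

## What it computes

- **Alteration calling** — z-score each gene against the reference panel,
  `z_gs = (x_gs − mean_ref) / sd_ref` (n−1 SD), and call a gene *altered* in
  a sample when |z| > 2 (values in [−2, 2] inclusive are non-altered). A
  sample's signature status is 1 if any signature gene is altered.
- **Survival engine** — Kaplan–Meier product-limit curves, the k-sample
  log-rank test (hypergeometric O/E/V at each event time, χ² with k−1 df),
  and Cox proportional-hazards regression (Efron ties, Wald CIs).
- **Signature refinement**
  - *Single-gene removal (SGR)*: greedy backward elimination; at each step
    the gene whose removal minimises the log-rank p of the remaining
    signature's altered-vs-unaltered split is dropped.
  - *k-top-scoring pairs (k-TSP)*: rank-based two-class scoring of gene
    pairs by Δ = |P(X_i < X_j | class 1) − P(X_i < X_j | class 2)| with the
    mean rank-gap difference γ as tie-break; greedy selection of k disjoint
    pairs and majority-vote classification.
  - *Combination rule*: union of the SGR core, the k-TSP pair genes and the
    single-marker genes (the rule that assembles a 7-gene core plus 2
    single markers into a 9-gene signature).
- **Risk stratification** — prognostic index `PI_s = Σ_g β_g z_gs` from Cox
  betas (or an equal-weight meta-gene), then maximized risk groups (minimum
  log-rank p over all cut-points, 2 or 3 groups, group-size constraint),
  median/quartile/tertile quantile splits, and best-cutoff search between
  the quartiles with Benjamini–Hochberg correction across the candidate
  family.
- **Over-representation** — upper-tail hypergeometric overlap of a query
  list against a GMT collection with an explicit universe, BH q-values.
- **Synthetic cohorts** — reference panel + tumors with latent high-risk
  carrier subsets for planted prognostic genes, exponential survival with
  hazard multiplying per carried gene, independent censoring truncated at
  an administrative horizon, and outcome classes at a configurable horizon
  for k-TSP. Fully deterministic given a seed.

The nine-gene ET-9 signature (ADGRG1, FIBCD1, GDPD5, SUSD2, CACNG4, CX3CL1,
IGFBP5, MAP6, CCDC69) ships as a packaged fixture (`sigforge.et9()`).

## Worked example

```python
import sigforge as sf

expr, clin, truth = sf.simulate_cohort(sf.CohortConfig(seed=1))
alt = sf.call_alterations(sf.zscore_vs_reference(expr))
status = sf.signature_status(alt, sf.GeneSignature("planted", truth.prognostic_genes))

lr = sf.logrank_test(clin.time, clin.event, status)
cox = sf.cox_fit(status.astype(float), clin.time, clin.event, names=["altered"])
```

Running `examples/02_survival_association.py` (the code above plus KM
medians) prints:

```
altered arm: n=209, median survival 35.6 months
unaltered arm: n=91, median survival 58.7 months
log-rank: chi2=7.8 (df=1), p=5.13e-03
Cox HR=1.51 (95% CI 1.13-2.02)
```

i.e. tumors altered in at least one planted gene have a 23-month shorter
median survival, a significant log-rank separation, and a ~1.5-fold hazard —
the qualitative pattern of an adverse prognostic signature. The other
scripts in `examples/` walk through SGR refinement, k-TSP pair selection,
risk-group maximization and enrichment, one capability each.

A thin CLI mirrors the library (`sigforge simulate | zscore | alter |
enrich | sgr | ktsp | stratify | run`); see `sigforge --help`.

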