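"""Signature reduction: single-gene screening, SGR and k-TSP.

Three routes to a compact prognostic subset of a starting signature:

* ``single_gene_significance`` - per-gene altered-vs-unaltered log-rank and
  Cox hazard ratio, to find genes prognostic as single markers;
* ``sgr_refine`` - single-gene-removal (SGR) backward elimination: at each
  step every one-gene removal is evaluated by the log-rank p of the
  remaining signature's altered-vs-unaltered status, and the removal giving
  the lowest p is kept;
* ``ktsp_score_pairs`` / ``ktsp_select`` / ``ktsp_classify`` - k-top-scoring
  pairs, a rank-based two-class method scoring gene pairs by how
  consistently their within-sample ordering flips between classes
  (invariant to any monotone per-sample normalisation).

``combine_candidates`` merges the SGR core, the k-TSP pair genes and the
single-marker genes into one de-duplicated signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ValidationError
from .io import AlterationMatrix, ClinicalTable, ExpressionMatrix, GeneSignature, signature_status
from .survival import cox_fit, logrank_test

__all__ = [
    "SGRStep",
    "SGRTrace",
    "TSPPairScore",
    "TSPClassifier",
    "single_gene_significance",
    "sgr_refine",
    "ktsp_score_pairs",
    "ktsp_select",
    "ktsp_classify",
    "combine_candidates",
]


# ---------------------------------------------------------------------------
# single-gene screening


def single_gene_significance(
    a: AlterationMatrix, clin: ClinicalTable, genes: list[str] | None = None
) -> pd.DataFrame:
    """Altered-vs-unaltered survival association per gene.

    Returns a DataFrame with log-rank p and Cox HR (plus 95% CI) for every
    gene; genes altered in zero or all samples are flagged untestable
    (``testable=False``) rather than dropped.
    """
    if genes is None:
        genes = list(a.gene_ids)
    idx = a.gene_index(genes)
    sub = clin.subset(a.sample_ids)
    rows = []
    for g, i in zip(genes, idx):
        status = a.calls[i]
        n_alt = int(status.sum())
        if n_alt == 0 or n_alt == len(status):
            rows.append(
                dict(gene=g, n_altered=n_alt, testable=False,
                     logrank_p=np.nan, hr=np.nan, hr_ci_low=np.nan,
                     hr_ci_high=np.nan, cox_p=np.nan)
            )
            continue
        lr = logrank_test(sub.time, sub.event, status)
        cox = cox_fit(status.astype(float), sub.time, sub.event, names=[g])
        rows.append(
            dict(gene=g, n_altered=n_alt, testable=True,
                 logrank_p=lr.p, hr=float(cox.hr[0]),
                 hr_ci_low=float(cox.ci_low[0]), hr_ci_high=float(cox.ci_high[0]),
                 cox_p=float(cox.wald_p[0]))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SGR backward elimination


@dataclass
class SGRStep:
    removed_gene: str
    remaining: list[str]
    logrank_p: float
    tie: bool = False  # candidate p tied with another removal at this step


@dataclass
class SGRTrace:
    start: list[str]
    start_p: float
    steps: list[SGRStep] = field(default_factory=list)

    @property
    def final_signature(self) -> GeneSignature:
        genes = self.steps[-1].remaining if self.steps else self.start
        return GeneSignature("SGR-final", list(genes))

    def as_dict(self) -> dict:
        return {
            "start": self.start,
            "start_p": self.start_p,
            "steps": [vars(s) for s in self.steps],
            "final_signature": self.final_signature.genes,
        }


def _status_logrank_p(a: AlterationMatrix, clin: ClinicalTable, genes: list[str]) -> float:
    """Log-rank p of altered-vs-unaltered status; constant status scores 1."""
    status = signature_status(a, GeneSignature("tmp", genes))
    if status.min() == status.max():
        return 1.0
    return logrank_test(clin.time, clin.event, status).p


def sgr_refine(
    a: AlterationMatrix,
    clin: ClinicalTable,
    start: GeneSignature,
    target_size: int | None = None,
    stop_rule: str = "size",
) -> SGRTrace:
    """Greedy single-gene-removal refinement of a signature.

    At each step all ``|S|`` one-gene removals are evaluated by the log-rank
    p of the remaining signature's sample status; the removal with the
    lowest p wins (ties broken by lexicographically smallest removed gene,
    and flagged on the step). Stops at ``target_size`` (``stop_rule="size"``)
    or as soon as no removal improves on the current p
    (``stop_rule="no-improvement"``). Deterministic: no randomness inside.
    """
    if stop_rule not in ("size", "no-improvement"):
        raise ValidationError(f"unknown stop_rule {stop_rule!r}")
    if stop_rule == "size":
        if target_size is None or not 1 <= target_size < len(start):
            raise ValidationError(
                f"target_size must be in [1, {len(start) - 1}], got {target_size}"
            )
    sub = clin.subset(a.sample_ids)
    current = list(start.genes)
    current_p = _status_logrank_p(a, sub, current)
    trace = SGRTrace(start=list(start.genes), start_p=current_p)

    while len(current) > 1:
        if stop_rule == "size" and len(current) <= target_size:
            break
        best_gene, best_p, tie = None, None, False
        for g in sorted(current):
            p = _status_logrank_p(a, sub, [x for x in current if x != g])
            if best_p is None or p < best_p:
                best_gene, best_p, tie = g, p, False
            elif p == best_p:
                tie = True
        if stop_rule == "no-improvement" and best_p > current_p:
            break
        current = [x for x in current if x != best_gene]
        current_p = best_p
        trace.steps.append(SGRStep(best_gene, list(current), float(best_p), tie))
    return trace


# ---------------------------------------------------------------------------
# k-TSP


@dataclass
class TSPPairScore:
    """Ordered gene pair with its order-flip score.

    ``delta`` is the absolute difference between the two classes in the
    empirical frequency of ``X_i < X_j`` within a sample (ties count 0.5);
    ``gamma`` is the secondary score, the absolute between-class difference
    of the mean within-sample rank gap. ``less_predicts_class1`` records the
    vote orientation: True when ``X_i < X_j`` is the class-1-typical order.
    """

    gene_i: str
    gene_j: str
    delta: float
    gamma: float
    p_class1: float
    p_class2: float

    @property
    def less_predicts_class1(self) -> bool:
        return self.p_class1 >= self.p_class2


@dataclass
class TSPClassifier:
    pairs: list[TSPPairScore]
    k: int

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k < 1:
            raise ValidationError("k must be a positive odd integer")
        genes = [g for p in self.pairs for g in (p.gene_i, p.gene_j)]
        if len(genes) != len(set(genes)):
            raise ValidationError("k-TSP pairs must be gene-disjoint")

    @property
    def genes(self) -> list[str]:
        return [g for p in self.pairs for g in (p.gene_i, p.gene_j)]

    def as_dict(self) -> dict:
        return {"k": self.k, "pairs": [vars(p) for p in self.pairs]}


def ktsp_score_pairs(z: ExpressionMatrix, labels) -> list[TSPPairScore]:
    """Score every unordered gene pair by its class-conditional order flip.

    ``labels`` is a per-sample binary vector; label 1 is class 1. Returned
    pairs are oriented lexicographically (gene_i < gene_j) and sorted by
    decreasing (delta, gamma), then pair name for determinism.
    """
    labels = np.asarray(labels)
    if not np.isin(labels, [0, 1]).all():
        raise ValidationError("labels must be binary 0/1")
    if labels.shape != (z.n_samples,):
        raise ValidationError("one label per sample required")
    if labels.min() == labels.max():
        raise ValidationError("both classes must be non-empty")
    if z.n_genes < 2:
        raise ValidationError("need >=2 genes to form pairs")

    order = np.argsort(z.gene_ids)  # lexicographic gene orientation
    genes = [z.gene_ids[i] for i in order]
    X = z.values[order]
    G, _ = X.shape
    less = (X[:, None, :] < X[None, :, :]) + 0.5 * (X[:, None, :] == X[None, :, :])
    c1, c2 = labels == 1, labels == 0
    p1 = less[:, :, c1].mean(axis=2)
    p2 = less[:, :, c2].mean(axis=2)
    ranks = np.apply_along_axis(rankdata, 0, X)  # within-sample ranks
    rd = ranks[:, None, :] - ranks[None, :, :]
    g1 = rd[:, :, c1].mean(axis=2)
    g2 = rd[:, :, c2].mean(axis=2)

    out = []
    for i in range(G):
        for j in range(i + 1, G):
            out.append(
                TSPPairScore(
                    gene_i=genes[i],
                    gene_j=genes[j],
                    delta=float(abs(p1[i, j] - p2[i, j])),
                    gamma=float(abs(g1[i, j] - g2[i, j])),
                    p_class1=float(p1[i, j]),
                    p_class2=float(p2[i, j]),
                )
            )
    out.sort(key=lambda s: (-s.delta, -s.gamma, s.gene_i, s.gene_j))
    return out


def ktsp_select(scores: list[TSPPairScore], k: int) -> TSPClassifier:
    """Greedy selection of the top k gene-disjoint pairs by (delta, gamma)."""
    if k < 1 or k % 2 == 0:
        raise ValidationError(f"k must be a positive odd integer, got {k}")
    chosen: list[TSPPairScore] = []
    used: set[str] = set()
    for s in scores:
        if s.gene_i in used or s.gene_j in used:
            continue
        chosen.append(s)
        used.update((s.gene_i, s.gene_j))
    if len(chosen) < k:
        raise ValidationError(
            f"only {len(chosen)} disjoint pairs available, cannot select k={k}"
        )
    return TSPClassifier(pairs=chosen[:k], k=k)


def ktsp_classify(z: ExpressionMatrix, model: TSPClassifier) -> np.ndarray:
    """Majority vote of the k pair comparisons; odd k rules out ties.

    A within-sample tie ``X_i == X_j`` counts as "not less", i.e. votes
    against the pair's "less" orientation.
    """
    votes = np.zeros(z.n_samples, dtype=int)
    for pair in model.pairs:
        idx = z.gene_index([pair.gene_i, pair.gene_j])
        is_less = z.values[idx[0]] < z.values[idx[1]]
        votes += (is_less == pair.less_predicts_class1).astype(int)
    return (votes > model.k / 2).astype(int)


# ---------------------------------------------------------------------------
# combination rule


def combine_candidates(
    sgr: SGRTrace | GeneSignature,
    tsp: TSPClassifier | None,
    singles: list[str],
    name: str = "combined",
) -> GeneSignature:
    """Union of the SGR core, the selected k-TSP pair genes and the single
    markers, de-duplicated in that order."""
    sgr_genes = sgr.final_signature.genes if isinstance(sgr, SGRTrace) else list(sgr.genes)
    tsp_genes = tsp.genes if tsp is not None else []
    combined: list[str] = []
    for g in [*sgr_genes, *tsp_genes, *singles]:
        if g not in combined:
            combined.append(g)
    if not combined:
        raise ValidationError("combined signature is empty")
    return GeneSignature(name, combined)
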