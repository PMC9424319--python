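"""Risk scoring and cohort-splitting strategies.

A signature is turned into a per-sample *prognostic index*
``PI_s = sum_g beta_g * z_gs`` (Cox coefficients times expression), or into
an equal-weight meta-gene score. The index is then dichotomised or
trichotomised by one of the strategies used by the survival portals:

* ``maximize_risk_groups`` - exhaustive scan over cut-points, keeping the
  partition with the minimum log-rank p-value (the "maximized risk groups"
  strategy; note the selected p is optimistically biased by construction),
* ``quantile_split`` - median split, Q1 vs Q4, or T1 vs T3 with the middle
  omitted,
* ``best_cutoff_fdr`` - best cut-point between the lower and upper
  quartiles with Benjamini-Hochberg correction across the candidate family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .exceptions import GeneLookupError, ValidationError
from .io import ClinicalTable, ExpressionMatrix, GeneSignature
from .survival import CoxResult, LogRankResult, cox_fit, logrank_test

__all__ = [
    "RiskScoreVector",
    "RiskPartition",
    "CutoffScan",
    "prognostic_index",
    "metagene_score",
    "maximize_risk_groups",
    "quantile_split",
    "best_cutoff_fdr",
]

_GROUP_NAMES = {2: ("low", "high"), 3: ("low", "medium", "high")}
EXCLUDED = "excluded"


@dataclass
class RiskScoreVector:
    sample_ids: list[str]
    score: np.ndarray

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, float)
        if self.score.shape != (len(self.sample_ids),):
            raise ValidationError("one score per sample required")
        if not np.isfinite(self.score).all():
            raise ValidationError("risk scores must be finite")


@dataclass
class RiskPartition:
    """Risk-group assignment with the survival statistics of the split.

    ``group`` holds one label per sample; samples omitted by a quantile
    strategy carry the label ``"excluded"`` and take no part in testing.
    """

    sample_ids: list[str]
    group: list[str]
    cutpoints: list[float]
    logrank: LogRankResult | None
    cox: CoxResult | None
    n_per_group: dict[str, int]
    median_split_p: float | None = None

    def as_dict(self) -> dict:
        return {
            "cutpoints": [float(c) for c in self.cutpoints],
            "n_per_group": self.n_per_group,
            "logrank": None if self.logrank is None else vars(self.logrank),
            "cox": None if self.cox is None else self.cox.as_dict(),
            "median_split_p": self.median_split_p,
            "group": dict(zip(self.sample_ids, self.group)),
        }


@dataclass
class CutoffScan:
    cutoffs: np.ndarray
    p: np.ndarray
    q: np.ndarray
    selected_cutoff: float
    selected_p: float
    selected_q: float


def prognostic_index(
    beta: dict[str, float], z: ExpressionMatrix, sig: GeneSignature
) -> RiskScoreVector:
    """Per-sample prognostic index: sum of beta coefficients times z-scores."""
    missing = [g for g in sig if g not in beta]
    if missing:
        raise GeneLookupError(f"no beta coefficient for genes: {missing}")
    idx = z.gene_index(list(sig))
    w = np.array([float(beta[g]) for g in sig])
    return RiskScoreVector(list(z.sample_ids), w @ z.values[idx])


def metagene_score(z: ExpressionMatrix, sig: GeneSignature) -> RiskScoreVector:
    """Equal-weight meta-gene: mean z-score of the signature genes per sample."""
    idx = z.gene_index(list(sig))
    return RiskScoreVector(list(z.sample_ids), z.values[idx].mean(axis=0))


def _evaluate(
    sample_ids, labels, clin: ClinicalTable, cutpoints, fit_cox: bool,
    median_split_p=None,
) -> RiskPartition:
    tested = [i for i, g in enumerate(labels) if g != EXCLUDED]
    ids = [sample_ids[i] for i in tested]
    sub = clin.subset(ids)
    grp = np.array([labels[i] for i in tested])
    lr = logrank_test(sub.time, sub.event, grp)
    cox = None
    if fit_cox:
        levels = [g for g in ("low", "medium", "high") if g in set(grp)]
        dummies = np.column_stack([(grp == g).astype(float) for g in levels[1:]])
        cox = cox_fit(dummies, sub.time, sub.event, names=list(levels[1:]))
    n_per = {g: int((np.asarray(labels) == g).sum()) for g in sorted(set(labels))}
    return RiskPartition(
        sample_ids=list(sample_ids),
        group=list(labels),
        cutpoints=[float(c) for c in cutpoints],
        logrank=lr,
        cox=cox,
        n_per_group=n_per,
        median_split_p=median_split_p,
    )


def _assign(score: np.ndarray, cuts: list[float]) -> list[str]:
    """Label samples by cut-points; ties go to the lower group."""
    names = _GROUP_NAMES[len(cuts) + 1]
    idx = np.zeros(score.size, dtype=int)
    for c in cuts:
        idx += score > c
    return [names[i] for i in idx]


def _candidate_cuts(score: np.ndarray) -> np.ndarray:
    u = np.unique(score)
    return (u[:-1] + u[1:]) / 2.0


def _group_logrank_p(score, cut_low, cut_high, time, event) -> float:
    if cut_high is None:
        grp = score > cut_low
    else:
        grp = (score > cut_low).astype(int) + (score > cut_high)
    return logrank_test(time, event, grp).p


def maximize_risk_groups(
    scores: RiskScoreVector,
    clin: ClinicalTable,
    n_groups: int = 2,
    min_frac: float = 0.1,
    fit_cox: bool = True,
) -> RiskPartition:
    """Minimum-p-value risk-group maximization.

    Scans every cut-point (midpoints between consecutive distinct sorted
    scores; all ordered pairs for three groups) subject to each group
    holding at least ``min_frac`` of the cohort, and returns the partition
    whose log-rank p-value is smallest. Ties in p go to the first cut in
    ascending score order. The median-split p-value is reported alongside
    for comparison; the maximized p is a minimum over many tests and is not
    calibrated.
    """
    if n_groups not in (2, 3):
        raise ValidationError("n_groups must be 2 or 3")
    if not 0 < min_frac < 1:
        raise ValidationError("min_frac must be in (0,1)")
    n = len(scores.sample_ids)
    min_count = max(1, math.ceil(min_frac * n))
    if min_count * n_groups > n:
        raise ValidationError(
            f"infeasible: {n_groups} groups of >= {min_count} samples from n={n}"
        )
    sub = clin.subset(scores.sample_ids)
    s = scores.score
    cuts = _candidate_cuts(s)
    counts_le = np.searchsorted(np.sort(s), cuts, side="right")

    best: tuple[float, list[float]] | None = None
    if n_groups == 2:
        feasible = (counts_le >= min_count) & (n - counts_le >= min_count)
        for c in cuts[feasible]:
            p = _group_logrank_p(s, c, None, sub.time, sub.event)
            if best is None or p < best[0]:
                best = (p, [c])
    else:
        for i, c1 in enumerate(cuts):
            n_low = counts_le[i]
            if n_low < min_count or n - n_low < 2 * min_count:
                continue
            for j in range(i + 1, cuts.size):
                n_mid = counts_le[j] - n_low
                n_high = n - counts_le[j]
                if n_mid < min_count or n_high < min_count:
                    continue
                p = _group_logrank_p(s, c1, cuts[j], sub.time, sub.event)
                if best is None or p < best[0]:
                    best = (p, [c1, float(cuts[j])])
    if best is None:
        raise ValidationError("no feasible cut-point satisfies the group-size constraint")

    # median split for reference (may itself be infeasible under heavy ties)
    med_p = None
    med_cut = float(np.median(s))
    n_low_med = int((s <= med_cut).sum())
    if 0 < n_low_med < n:
        med_p = _group_logrank_p(s, med_cut, None, sub.time, sub.event)

    labels = _assign(s, best[1])
    return _evaluate(scores.sample_ids, labels, clin, best[1], fit_cox, med_p)


def quantile_split(
    scores: RiskScoreVector,
    clin: ClinicalTable | None = None,
    mode: str = "median",
    fit_cox: bool = True,
) -> RiskPartition:
    """Quantile-based splits: median, Q1-vs-Q4, or T1-vs-T3 (middle omitted)."""
    s = scores.score
    n = s.size
    if n < 4:
        raise ValidationError("quantile splits need n >= 4")
    if mode == "median":
        cut = float(np.quantile(s, 0.5))
        labels = ["low" if v <= cut else "high" for v in s]
        cuts = [cut]
    elif mode in ("quartile", "tertile-omit-middle"):
        lo_q, hi_q = (0.25, 0.75) if mode == "quartile" else (1 / 3, 2 / 3)
        lo, hi = float(np.quantile(s, lo_q)), float(np.quantile(s, hi_q))
        labels = [
            "low" if v <= lo else ("high" if v >= hi else EXCLUDED) for v in s
        ]
        cuts = [lo, hi]
    else:
        raise ValidationError(f"unknown split mode {mode!r}")
    n_low = labels.count("low")
    n_high = labels.count("high")
    if n_low == 0 or n_high == 0 or n_low == n or n_high == n:
        raise ValidationError("degenerate quantile boundary (tied scores)")
    if clin is None:
        n_per = {g: labels.count(g) for g in sorted(set(labels))}
        return RiskPartition(list(scores.sample_ids), labels, cuts, None, None, n_per)
    return _evaluate(scores.sample_ids, labels, clin, cuts, fit_cox)


def best_cutoff_fdr(
    scores: RiskScoreVector,
    clin: ClinicalTable,
    window: tuple[float, float] = (0.25, 0.75),
) -> CutoffScan:
    """Best-cutoff search within a quantile window, BH-corrected.

    Every candidate cut-point between the window quantiles is tested with a
    two-group log-rank; BH adjustment runs across the candidate family of
    one scan. The selected cut is the minimum *raw* p; its adjusted q is
    reported next to it so the multiplicity cost of the search is visible.
    """
    lo, hi = window
    if not (0 < lo < hi < 1):
        raise ValidationError(f"window must satisfy 0 < lo < hi < 1, got {window}")
    sub = clin.subset(scores.sample_ids)
    s = scores.score
    cuts = _candidate_cuts(s)
    q_lo, q_hi = np.quantile(s, lo), np.quantile(s, hi)
    cuts = cuts[(cuts >= q_lo) & (cuts <= q_hi)]
    if cuts.size < 3:
        raise ValidationError(
            f"need >=3 candidate cutoffs inside the window, got {cuts.size}"
        )
    p = np.array([_group_logrank_p(s, c, None, sub.time, sub.event) for c in cuts])
    q = multipletests(p, method="fdr_bh")[1]
    i = int(np.argmin(p))
    return CutoffScan(
        cutoffs=cuts,
        p=p,
        q=q,
        selected_cutoff=float(cuts[i]),
        selected_p=float(p[i]),
        selected_q=float(q[i]),
    )
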