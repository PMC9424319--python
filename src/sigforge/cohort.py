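"""Synthetic cohorts with planted prognostic structure.

The generator emulates the statistical shape of a portal-style breast-cancer
cohort: a reference ("diploid") expression panel for z-scoring, tumor
samples in which a latent high-risk subgroup over-expresses a planted set of
prognostic genes, exponential survival whose hazard follows a
proportional-hazards model on those genes' z-scores, independent exponential
censoring truncated at an administrative horizon, and a two-class labelling
(event before T vs event-free at T) for k-TSP.

All randomness flows through one ``numpy.random.default_rng(seed)`` stream
in a fixed draw order, so a seed pins the cohort bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import ValidationError
from .io import ClinicalTable, ExpressionMatrix

__all__ = ["CohortConfig", "CohortTruth", "simulate_cohort", "simulate_two_class"]

#: log-hazard per unit z chosen so an altered sample (z ~ alteration_shift)
#: carries roughly a twofold hazard per altered prognostic gene.
_DEFAULT_SHIFT = 4.0
_DEFAULT_BETA = math.log(2.0) / _DEFAULT_SHIFT


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults are the "demo" cohort: 300 tumors, 50 reference samples,
    10 genes of which 3 are prognostic, each prognostic gene over-expressed
    (+4 SD, hence called altered at |z| > 2) in a latent high-risk carrier
    subset covering 25% of tumors, hazard ratio ~2 per altered gene,
    baseline hazard 0.01/month, ~30% censoring and a 240-month
    administrative horizon.

    ``carrier_mode`` controls the latent structure: ``"independent"`` draws
    a separate carrier subset per prognostic gene (genes are individually
    informative), ``"shared"`` shifts all prognostic genes in one common
    subgroup (genes are mutually redundant).
    """

    n_tumor: int = 300
    n_reference: int = 50
    n_genes: int = 10
    prognostic_genes: list[str] = field(default_factory=lambda: ["G001", "G002", "G003"])
    effect_beta: dict[str, float] = field(
        default_factory=lambda: {g: _DEFAULT_BETA for g in ("G001", "G002", "G003")}
    )
    alteration_shift: float = _DEFAULT_SHIFT
    risk_frac: float = 0.25
    carrier_mode: str = "independent"
    hazard_model: str = "carrier"
    baseline_hazard: float = 0.01
    censor_rate: float = 0.0043
    admin_horizon: float = 240.0
    class_horizon_T: float = 120.0
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:03d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if min(self.n_tumor, self.n_reference, self.n_genes) < 1:
            raise ValidationError("counts must be positive")
        if self.n_reference < 2:
            raise ValidationError("need >=2 reference samples for z-scoring")
        if not 0 <= self.risk_frac <= 1:
            raise ValidationError("risk_frac must be in [0,1]")
        if self.carrier_mode not in ("independent", "shared"):
            raise ValidationError("carrier_mode must be 'independent' or 'shared'")
        if self.hazard_model not in ("carrier", "z"):
            raise ValidationError("hazard_model must be 'carrier' or 'z'")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValidationError("hazard rates must be positive")
        if self.admin_horizon <= 0:
            raise ValidationError("admin_horizon must be positive")
        genes = set(self.gene_ids())
        extra = [g for g in self.prognostic_genes if g not in genes]
        if extra:
            raise ValidationError(f"prognostic genes outside the simulated panel: {extra}")
        missing_beta = [g for g in self.prognostic_genes if g not in self.effect_beta]
        if missing_beta:
            raise ValidationError(f"effect_beta missing for: {missing_beta}")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort (what a method should recover)."""

    prognostic_genes: list[str]
    beta: dict[str, float]
    carriers: dict[str, np.ndarray]  # per prognostic gene: tumor carries the shift
    high_risk: np.ndarray  # per-tumor: carrier of at least one prognostic gene
    linear_predictor: np.ndarray  # sum_g beta_g * z_gs per tumor


def simulate_cohort(cfg: CohortConfig):
    """Generate (ExpressionMatrix, ClinicalTable, CohortTruth).

    Reference samples are standard normal per gene; tumor samples are
    standard normal except prognostic genes in their latent high-risk
    carrier subsets, which get ``+alteration_shift``. Event times are
    exponential with hazard ``baseline_hazard * exp(lp)`` where ``lp`` is
    ``sum_g beta_g * z_gs`` under ``hazard_model="z"`` or
    ``sum_g beta_g * alteration_shift * carrier_gs`` (hazard multiplies per
    carried gene) under the default ``hazard_model="carrier"``. Censoring
    is exponential(``censor_rate``) truncated at ``admin_horizon``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids()
    n_t, n_r, G = cfg.n_tumor, cfg.n_reference, cfg.n_genes

    ref = rng.standard_normal((G, n_r))
    tum = rng.standard_normal((G, n_t))
    g_idx = {g: i for i, g in enumerate(genes)}
    carriers: dict[str, np.ndarray] = {}
    if cfg.carrier_mode == "shared":
        shared = rng.random(n_t) < cfg.risk_frac
        carriers = {g: shared.copy() for g in cfg.prognostic_genes}
    else:
        carriers = {g: rng.random(n_t) < cfg.risk_frac for g in cfg.prognostic_genes}
    for g in cfg.prognostic_genes:
        tum[g_idx[g], carriers[g]] += cfg.alteration_shift
    high_risk = (
        np.logical_or.reduce([carriers[g] for g in cfg.prognostic_genes])
        if cfg.prognostic_genes
        else np.zeros(n_t, dtype=bool)
    )

    # true z-scores: tumor values are already on the reference N(0,1) scale
    beta_vec = np.zeros(G)
    for g, b in cfg.effect_beta.items():
        if g in g_idx:
            beta_vec[g_idx[g]] = float(b)
    if cfg.hazard_model == "z":
        lp = beta_vec @ tum
    else:
        # discrete planting: each carried prognostic gene multiplies the
        # hazard by exp(beta * alteration_shift) (~2 at the defaults)
        lp = np.zeros(n_t)
        for g in cfg.prognostic_genes:
            lp += beta_vec[g_idx[g]] * cfg.alteration_shift * carriers[g]
    hazard = cfg.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = np.minimum(rng.exponential(1.0 / cfg.censor_rate, size=n_t), cfg.admin_horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    sample_ids = [f"T{i + 1:04d}" for i in range(n_t)] + [f"R{i + 1:04d}" for i in range(n_r)]
    values = np.concatenate([tum, ref], axis=1)
    is_ref = np.array([False] * n_t + [True] * n_r)
    expr = ExpressionMatrix(genes, sample_ids, values, is_ref)
    clin = ClinicalTable(sample_ids=sample_ids[:n_t], time=time, event=event)
    truth = CohortTruth(
        prognostic_genes=list(cfg.prognostic_genes),
        beta={g: float(cfg.effect_beta[g]) for g in cfg.prognostic_genes},
        carriers=carriers,
        high_risk=high_risk,
        linear_predictor=lp,
    )
    return expr, clin, truth


def simulate_two_class(
    cfg: CohortConfig,
    switched_pair: tuple[str, str] | None = None,
    fidelity: float = 1.0,
):
    """Two-class data for k-TSP: event before T vs event-free at T.

    Runs ``simulate_cohort``, labels tumors by outcome at the class horizon
    T (class 1 = event observed before T; class 0 = event-free follow-up of
    at least T) and drops tumors censored before T. Optionally injects a
    *switched pair*: per sample, with probability ``fidelity`` the pair is
    set to its class-typical order (first gene below the second in class 1,
    above it in class 0) and otherwise to the opposite order, so the pair's
    order-flip score delta is |2*fidelity - 1| in expectation.

    Returns ``(ExpressionMatrix, labels)`` for the retained tumor samples
    (reference samples are dropped).
    """
    cfg.validate()
    if not 0 <= fidelity <= 1:
        raise ValidationError("fidelity must be in [0,1]")
    T = cfg.class_horizon_T
    if T > cfg.admin_horizon:
        raise ValidationError("class_horizon_T must lie within admin_horizon")
    expr, clin, _ = simulate_cohort(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    time, event = clin.time, clin.event
    cls1 = (event == 1) & (time < T)
    cls0 = time >= T
    keep = cls1 | cls0
    if cls1.sum() == 0 or cls0.sum() == 0:
        raise ValidationError(
            "a class is empty after labelling; lengthen follow-up, move "
            "class_horizon_T or raise the baseline hazard"
        )
    labels = cls1[keep].astype(int)

    tumor_cols = np.flatnonzero(~expr.is_reference)[keep]
    values = expr.values[:, tumor_cols].copy()
    sample_ids = [expr.sample_ids[i] for i in tumor_cols]

    if switched_pair is not None:
        ia, ib = (expr.gene_ids.index(g) for g in switched_pair)
        typical = rng.random(values.shape[1]) < fidelity
        for s in range(values.shape[1]):
            lo, hi = sorted((values[ia, s], values[ib, s]))
            # class-typical order: gene a below gene b in class 1
            a_below_b = (labels[s] == 1) == typical[s]
            values[ia, s], values[ib, s] = (lo, hi) if a_below_b else (hi, lo)
    out = ExpressionMatrix(list(expr.gene_ids), sample_ids, values)
    return out, labels
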