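"""Hypergeometric over-representation analysis with BH FDR control.

The "compute overlap" flavour of gene-set enrichment: for a query gene list
and each gene set in a collection, the upper-tail hypergeometric probability
of seeing at least the observed overlap given the universe, corrected across
the collection by the Benjamini-Hochberg step-up procedure. The universe
(all assayable genes) must be supplied explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io import GeneSetCollection

__all__ = ["EnrichmentResult", "hypergeom_overlap", "bh_fdr", "enrich_collection"]

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    universe_size: int  # N
    set_size: int  # K (after intersection with the universe)
    query_size: int  # n (after intersection with the universe)
    overlap: int  # k
    p: float
    q: float | None
    overlap_genes: list[str]


def _dedup(genes) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    for g in genes:
        g = str(g).strip()
        if g and g not in seen:
            seen.add(g)
            out.append(g)
    return out


def hypergeom_overlap(query, gene_set, universe, set_name: str = "set") -> EnrichmentResult:
    """Upper-tail hypergeometric overlap test.

    ``p = P(overlap >= k)`` when drawing ``n`` query genes from a universe
    of ``N`` containing ``K`` set members. Query/set genes outside the
    universe are dropped (counts logged), mirroring portal behaviour.
    """
    uni = _dedup(universe)
    if not uni:
        raise ValidationError("empty universe")
    uni_set = set(uni)
    q_all, s_all = _dedup(query), _dedup(gene_set)
    q = [g for g in q_all if g in uni_set]
    s = [g for g in s_all if g in uni_set]
    dropped = (len(q_all) - len(q)) + (len(s_all) - len(s))
    if dropped:
        log.info("hypergeom_overlap: dropped %d genes outside the universe", dropped)
    if not q:
        raise ValidationError("query has no genes in the universe")
    N, K, n = len(uni), len(s), len(q)
    ov = sorted(set(q) & set(s))
    k = len(ov)
    # P(X >= k) = sf(k-1); exact 1.0 at k == 0
    p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    p = min(p, 1.0)
    return EnrichmentResult(set_name, N, K, n, k, p, None, ov)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_collection(
    query, coll: GeneSetCollection, universe, q_max: float | None = 0.05
) -> list[EnrichmentResult]:
    """Test a query list against every set in a collection.

    BH correction runs across the whole collection; results come back
    sorted by ascending p and, when ``q_max`` is not None, filtered to
    ``q <= q_max``.
    """
    if len(coll) == 0:
        raise ValidationError("empty gene-set collection")
    results = [
        hypergeom_overlap(query, members, universe, set_name=name)
        for name, _, members in coll
    ]
    qs = bh_fdr([r.p for r in results])
    for r, qv in zip(results, qs):
        r.q = float(qv)
    results.sort(key=lambda r: (r.p, r.set_name))
    if q_max is not None:
        results = [r for r in results if r.q <= q_max]
    return results
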