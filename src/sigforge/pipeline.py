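"""End-to-end orchestration of the signature-discovery workflow.

Stage order mirrors the analysis the package implements: z-scoring against
the reference panel, alteration calling, gene-set over-representation of the
starting signature, SGR and k-TSP refinement plus single-marker screening,
the combination rule, prognostic-index scoring with risk-group maximization,
and per-subgroup survival testing. A pipeline run is a pure function of the
config and input files: rerunning the same config reproduces the report
byte-for-byte. Plots are side artifacts; nothing downstream parses them.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sfio
from .enrich import enrich_collection
from .exceptions import SigforgeError, ValidationError
from .io import ClinicalTable
from .risk import maximize_risk_groups, prognostic_index
from .search import (
    combine_candidates,
    ktsp_score_pairs,
    ktsp_select,
    sgr_refine,
    single_gene_significance,
)
from .survival import cox_fit, km_fit, logrank_test

__all__ = ["PipelineConfig", "run_pipeline", "subgroup_survival"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All inputs and knobs of one pipeline run (loadable from YAML)."""

    expression: str
    clinical: str
    signature: str
    out_dir: str
    reference_samples: list[str] = field(default_factory=list)
    reference_file: str | None = None
    gmt: str | None = None
    universe: str | None = None
    # stage toggles
    run_enrichment: bool = True
    run_sgr: bool = True
    run_ktsp: bool = True
    run_stratify: bool = True
    # parameters
    threshold: float = 2.0
    target_size: int | None = None
    sgr_stop_rule: str = "size"
    k: int = 3
    groups: int = 2
    min_frac: float = 0.1
    q_max: float = 0.05
    class_horizon_T: float = 120.0
    singles_alpha: float = 0.05
    seed: int = 0
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for p in (self.expression, self.clinical, self.signature, self.gmt,
                  self.universe, self.reference_file):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")
        if self.groups not in (2, 3):
            raise ValidationError("groups must be 2 or 3")
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")


@contextmanager
def _stage(name: str):
    try:
        yield
    except SigforgeError as e:
        raise type(e)(f"[stage {name}] {e}") from e


def subgroup_survival(status, clin: ClinicalTable) -> dict:
    """Altered-vs-unaltered survival within each clinical subgroup.

    ``status`` is a per-sample 0/1 vector aligned with ``clin``. Subgroup
    levels in which only one status label occurs (or no events) are reported
    as untestable rather than dropped.
    """
    if clin.subgroup is None:
        raise ValidationError("clinical table has no subgroup column")
    status = np.asarray(status)
    if status.shape != (clin.n_samples,):
        raise ValidationError("status vector must align with the clinical table")
    out: dict = {}
    for level in sorted(set(clin.subgroup)):
        mask = np.array([s == level for s in clin.subgroup])
        st, t, ev = status[mask], clin.time[mask], clin.event[mask]
        if st.min() == st.max() or ev.sum() == 0:
            out[level] = {"testable": False, "n": int(mask.sum())}
            continue
        lr = logrank_test(t, ev, st)
        cox = cox_fit(st.astype(float), t, ev, names=["altered"])
        out[level] = {
            "testable": True,
            "n": int(mask.sum()),
            "n_altered": int(st.sum()),
            "logrank": vars(lr),
            "cox": cox.as_dict(),
        }
    return out


def _km_plot(path, time, event, groups) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g in sorted(set(groups)):
        mask = np.array([x == g for x in groups])
        curve = km_fit(time[mask], event[mask])
        if curve.event_times.size:
            ax.step(
                np.concatenate([[0], curve.event_times]),
                np.concatenate([[1.0], curve.survival]),
                where="post",
                label=f"{g} (n={int(mask.sum())})",
            )
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; write report.json + TSV tables.

    Returns the report dict (also written to ``<out_dir>/report.json``).
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": SCHEMA_VERSION, "config": asdict(cfg), "stages": {}}

    with _stage("load"):
        ref_ids = list(cfg.reference_samples)
        if cfg.reference_file:
            ref_ids += [
                ln.strip() for ln in Path(cfg.reference_file).read_text().splitlines()
                if ln.strip()
            ]
        expr = sfio.read_expression(cfg.expression, reference_ids=ref_ids or None)
        clin_all = sfio.read_clinical(cfg.clinical)
        start = sfio.read_signature(cfg.signature)
        report["stages"]["load"] = {
            "n_genes": expr.n_genes,
            "n_samples": expr.n_samples,
            "n_reference": int(expr.is_reference.sum()),
            "signature": start.genes,
        }

    with _stage("zscore"):
        z = sfio.zscore_vs_reference(expr)
        clin = clin_all.subset(z.sample_ids)

    with _stage("alteration"):
        alt = sfio.call_alterations(z, cfg.threshold)
        report["stages"]["alteration"] = {
            "threshold": cfg.threshold,
            "altered_fraction": float(alt.calls.mean()),
        }

    if cfg.run_enrichment and cfg.gmt:
        with _stage("enrichment"):
            coll = sfio.read_gmt(cfg.gmt)
            universe = (
                [ln.strip() for ln in Path(cfg.universe).read_text().splitlines() if ln.strip()]
                if cfg.universe
                else list(expr.gene_ids)
            )
            results = enrich_collection(start.genes, coll, universe, q_max=None)
            table = pd.DataFrame(
                [
                    {
                        "set_name": r.set_name, "N": r.universe_size, "K": r.set_size,
                        "n": r.query_size, "k": r.overlap, "p": r.p, "q": r.q,
                        "overlap_genes": ";".join(r.overlap_genes),
                    }
                    for r in results
                ]
            )
            table.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
            sig_hits = table[table["q"] <= cfg.q_max]
            report["stages"]["enrichment"] = {
                "n_sets": len(table),
                "n_significant": int(len(sig_hits)),
                "top": table.head(10).to_dict(orient="records"),
            }

    with _stage("single_gene"):
        singles_table = single_gene_significance(alt, clin, start.genes)
        singles_table.to_csv(out_dir / "single_genes.tsv", sep="\t", index=False)
        singles = list(
            singles_table.loc[
                singles_table["testable"] & (singles_table["logrank_p"] < cfg.singles_alpha),
                "gene",
            ]
        )
        report["stages"]["single_gene"] = {
            "singles_alpha": cfg.singles_alpha,
            "single_markers": singles,
        }

    sgr_trace = None
    if cfg.run_sgr:
        with _stage("sgr"):
            target = cfg.target_size
            if cfg.sgr_stop_rule == "size" and target is None:
                target = max(1, len(start) // 2)
            sgr_trace = sgr_refine(alt, clin, start, target, stop_rule=cfg.sgr_stop_rule)
            report["stages"]["sgr"] = sgr_trace.as_dict()

    tsp = None
    if cfg.run_ktsp:
        with _stage("ktsp"):
            T = cfg.class_horizon_T
            cls1 = (clin.event == 1) & (clin.time < T)
            cls0 = clin.time >= T
            keep = np.flatnonzero(cls1 | cls0)
            if cls1.sum() == 0 or cls0.sum() == 0:
                raise ValidationError(
                    f"empty outcome class at horizon T={T}; adjust class_horizon_T"
                )
            idx = z.gene_index(start.genes)
            zc = sfio.ExpressionMatrix(
                start.genes,
                [z.sample_ids[i] for i in keep],
                z.values[np.ix_(idx, keep)],
            )
            labels = cls1[keep].astype(int)
            pairs = ktsp_score_pairs(zc, labels)
            tsp = ktsp_select(pairs, cfg.k)
            report["stages"]["ktsp"] = {
                "T": T,
                "n_class1": int(labels.sum()),
                "n_class0": int(len(labels) - labels.sum()),
                **tsp.as_dict(),
            }

    with _stage("combine"):
        base = sgr_trace if sgr_trace is not None else start
        combined = combine_candidates(base, tsp, singles)
        sfio.write_signature(combined, out_dir / "combined_signature.txt")
        report["stages"]["combine"] = {"signature": combined.genes}

    if cfg.run_stratify:
        with _stage("stratify"):
            idx = z.gene_index(combined.genes)
            cox = cox_fit(z.values[idx].T, clin.time, clin.event, names=combined.genes)
            beta = dict(zip(combined.genes, cox.beta))
            scores = prognostic_index(beta, z, combined)
            pd.DataFrame(
                {"sample_id": scores.sample_ids, "score": scores.score}
            ).to_csv(out_dir / "scores.tsv", sep="\t", index=False, float_format="%.10g")
            part = maximize_risk_groups(scores, clin, cfg.groups, cfg.min_frac)
            report["stages"]["stratify"] = {
                "beta": {g: float(b) for g, b in beta.items()},
                "cox_converged": cox.converged,
                "partition": part.as_dict(),
            }
            if cfg.make_plots:
                _km_plot(out_dir / "km_risk_groups.png", clin.time, clin.event, part.group)

    if clin.subgroup is not None:
        with _stage("subgroups"):
            status = sfio.signature_status(alt, combined)
            report["stages"]["subgroups"] = subgroup_survival(status, clin)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
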