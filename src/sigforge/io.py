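"""Data containers and file formats.

Expression matrices travel as genes x samples TSV (first column ``gene_id``,
remaining columns sample identifiers). Clinical tables are per-sample TSV
with ``sample_id``, ``time_months`` (follow-up in months), ``event``
(1 = death/relapse observed, 0 = censored) and an optional ``subgroup``
column. Gene sets use the standard GMT format; signatures are one gene
symbol per line.

The reference ("diploid") sample panel anchors the z-scoring convention:
each gene's tumor expression is standardised by the mean and SD of the
reference samples, and a gene is called *altered* in a sample when its
z-score falls strictly outside ``[-threshold, threshold]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateDataError,
    FormatError,
    GeneLookupError,
    ValidationError,
)

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "AlterationMatrix",
    "GeneSignature",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "read_signature",
    "write_signature",
    "zscore_vs_reference",
    "call_alterations",
    "signature_status",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups = sorted({i for i in ids if i in seen or seen.add(i)})
    if dups:
        raise FormatError(f"duplicate {what} identifiers: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Continuous gene-by-sample values plus reference-panel flags.

    ``values`` has shape (n_genes, n_samples); ``is_reference`` flags the
    diploid/normal panel used for z-scoring.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    is_reference: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise FormatError("expression matrix contains missing values")
        if self.is_reference is None:
            self.is_reference = np.zeros(len(self.sample_ids), dtype=bool)
        self.is_reference = np.asarray(self.is_reference, dtype=bool)
        if self.is_reference.shape != (len(self.sample_ids),):
            raise FormatError("is_reference length does not match sample count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise GeneLookupError(f"genes absent from matrix: {missing}")
        return np.array([pos[g] for g in genes], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ClinicalTable:
    """Per-sample follow-up time (months), event indicator and optional subgroup."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    subgroup: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise FormatError("time/event length does not match sample count")
        if np.isnan(self.time).any() or (self.time < 0).any():
            raise ValidationError("follow-up times must be non-negative and complete")
        if not np.isin(self.event, [0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")
        self.event = self.event.astype(int)
        if self.subgroup is not None:
            self.subgroup = [str(s) for s in self.subgroup]
            if len(self.subgroup) != n:
                raise FormatError("subgroup length does not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise GeneLookupError(f"samples absent from clinical table: {missing[:10]}")
        idx = [pos[s] for s in sample_ids]
        return ClinicalTable(
            sample_ids=list(sample_ids),
            time=self.time[idx],
            event=self.event[idx],
            subgroup=[self.subgroup[i] for i in idx] if self.subgroup else None,
        )


@dataclass
class AlterationMatrix:
    """Binary gene-by-sample calls: 1 when |z| exceeds the threshold."""

    gene_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray
    threshold: float = 2.0

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.calls = np.asarray(self.calls)
        if not np.isin(self.calls, [0, 1]).all():
            raise ValidationError("alteration calls must be 0/1")
        self.calls = self.calls.astype(np.int8)
        if self.calls.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("calls shape does not match identifier lists")
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise GeneLookupError(f"genes absent from alteration matrix: {missing}")
        return np.array([pos[g] for g in genes], dtype=int)


@dataclass
class GeneSignature:
    """Named, ordered, duplicate-free gene list."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = [str(g).strip() for g in self.genes]
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        _check_unique(self.genes, "signature gene")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def without(self, gene: str) -> "GeneSignature":
        if gene not in self.genes:
            raise GeneLookupError(f"gene {gene!r} not in signature {self.name!r}")
        return GeneSignature(self.name, [g for g in self.genes if g != gene])


@dataclass
class GeneSetCollection:
    """Ordered collection of (name, description, members) gene sets."""

    sets: list[tuple[str, str, list[str]]]

    def __post_init__(self) -> None:
        _check_unique([s[0] for s in self.sets], "gene-set")
        for name, _, members in self.sets:
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, reference_ids: Sequence[str] | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV; flag ``reference_ids`` as the diploid panel."""
    with open(path) as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split("\t")[1:]]
    if len(set(header)) != len(header):
        raise FormatError(f"{path}: duplicate sample identifiers in header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = header
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene identifiers")
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = body.isna().any(axis=1)
        raise FormatError(
            f"{path}: non-numeric or missing values in genes "
            f"{list(df.index[bad][:5])}"
        )
    is_ref = np.zeros(df.shape[1], dtype=bool)
    if reference_ids is not None:
        pos = {s: i for i, s in enumerate(df.columns)}
        missing = [s for s in reference_ids if s not in pos]
        if missing:
            raise GeneLookupError(f"reference samples absent from header: {missing}")
        is_ref[[pos[s] for s in reference_ids]] = True
    return ExpressionMatrix(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        values=body.to_numpy(float),
        is_reference=is_ref,
    )


def write_expression(m: ExpressionMatrix, path) -> None:
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time_months", "event"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: clinical table needs columns {sorted(required)}")
    return ClinicalTable(
        sample_ids=list(df["sample_id"]),
        time=df["time_months"].to_numpy(float),
        event=df["event"].to_numpy(),
        subgroup=list(df["subgroup"]) if "subgroup" in df.columns else None,
    )


def write_clinical(clin: ClinicalTable, path) -> None:
    data = {
        "sample_id": clin.sample_ids,
        "time_months": clin.time,
        "event": clin.event,
    }
    if clin.subgroup is not None:
        data["subgroup"] = clin.subgroup
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene [<tab> gene ...]."""
    sets: list[tuple[str, str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc = fields[0].strip(), fields[1]
            members: list[str] = []
            for g in fields[2:]:
                g = g.strip()
                if g and g not in members:
                    members.append(g)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append((name, desc, members))
    return GeneSetCollection(sets)


def read_signature(path, name: str | None = None) -> GeneSignature:
    """Read a one-gene-per-line signature file (blank lines ignored)."""
    p = Path(path)
    genes = [ln.strip() for ln in p.read_text().splitlines() if ln.strip()]
    return GeneSignature(name or p.stem, genes)


def write_signature(sig: GeneSignature, path) -> None:
    Path(path).write_text("\n".join(sig.genes) + "\n")


# ---------------------------------------------------------------------------
# z-scoring and alteration calling


def zscore_vs_reference(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise every gene against the reference (diploid) panel.

    For gene g and non-reference sample s:
    ``z_gs = (x_gs - mean_ref(g)) / sd_ref(g)`` with the n-1 SD denominator.
    Reference samples are dropped from the output.
    """
    ref = m.is_reference
    n_ref = int(ref.sum())
    if n_ref < 2:
        raise ValidationError(f"need >=2 reference samples for z-scoring, got {n_ref}")
    ref_vals = m.values[:, ref]
    mu = ref_vals.mean(axis=1)
    sd = ref_vals.std(axis=1, ddof=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        names = [m.gene_ids[i] for i in degenerate[:10]]
        raise DegenerateDataError(
            f"zero reference variance for gene(s) {names}; cannot z-score"
        )
    tumor = ~ref
    z = (m.values[:, tumor] - mu[:, None]) / sd[:, None]
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=[s for s, r in zip(m.sample_ids, ref) if not r],
        values=z,
        is_reference=np.zeros(int(tumor.sum()), dtype=bool),
    )


def call_alterations(z: ExpressionMatrix, threshold: float = 2.0) -> AlterationMatrix:
    """Binarize z-scores: altered iff |z| > threshold (strict).

    Values inside [-threshold, threshold], endpoints included, are
    non-altered.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    calls = (np.abs(z.values) > threshold).astype(np.int8)
    return AlterationMatrix(
        gene_ids=list(z.gene_ids),
        sample_ids=list(z.sample_ids),
        calls=calls,
        threshold=float(threshold),
    )


def signature_status(a: AlterationMatrix, sig: GeneSignature) -> np.ndarray:
    """Per-sample signature status: 1 iff any signature gene is altered."""
    idx = a.gene_index(list(sig))
    return (a.calls[idx].any(axis=0)).astype(int)
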