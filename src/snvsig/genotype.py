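"""Build 0/1 gene-by-patient matrices from MAF-like somatic mutation records.

The reader is a minimal MAF-dialect parser: only the three columns needed for
a binary genotype matrix are interpreted (``Hugo_Symbol``,
``Tumor_Sample_Barcode``, ``Variant_Classification``); everything else in the
file is ignored, which keeps it robust to column drift across GDC releases.
A patient/gene entry is 1 when the patient carries at least one mutation
record for that gene (multiplicity is collapsed), 0 for wild type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "BinaryGenotypeMatrix",
    "SurvivalData",
    "MafFormatError",
    "read_maf",
    "filter_variant_class",
    "build_binary_matrix",
    "merge_survival",
    "mutation_summary",
]

REQUIRED_MAF_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

#: Variant classes removed by default before building the matrix.
DEFAULT_EXCLUDED_CLASSES = frozenset({"Nonsense_Mutation"})


class MafFormatError(ValueError):
    """Raised when a mutation file does not follow the expected MAF dialect."""


class MutationRecord(NamedTuple):
    gene: str
    sample: str
    variant_class: str


@dataclass
class BinaryGenotypeMatrix:
    """Samples x genes matrix over {0, 1} with aligned identifiers."""

    values: np.ndarray
    sample_ids: Sequence[str]
    gene_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.gene_ids):
            raise ValueError("matrix dimensions do not match id lists")
        if len(set(self.sample_ids)) != n or len(set(self.gene_ids)) != p:
            raise ValueError("sample and gene ids must be unique")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.gene_ids))

    def select_columns(self, idx) -> "BinaryGenotypeMatrix":
        idx = np.asarray(idx)
        return BinaryGenotypeMatrix(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            gene_ids=[self.gene_ids[j] for j in idx],
        )


@dataclass
class SurvivalData:
    """Per-sample right-censored follow-up: time (days) and event (1 = death)."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.shape != self.event.shape or len(self.time) != len(self.sample_ids):
            raise ValueError("time, event and sample_ids must be aligned")
        if np.any(self.time < 0) or np.any(np.isnan(self.time)):
            raise ValueError("times must be non-negative and non-missing")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        self.event = self.event.astype(np.int8)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event}, index=list(self.sample_ids)
        )

    def subset(self, idx) -> "SurvivalData":
        idx = np.asarray(idx)
        return SurvivalData(
            time=self.time[idx],
            event=self.event[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


def read_maf(path) -> list[MutationRecord]:
    """Read mutation records from a tab-delimited MAF-dialect file.

    Header-driven: column order is free; lines starting with ``#`` are
    skipped.  Raises :class:`MafFormatError` when a required column is
    missing or the file holds no data lines.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise MafFormatError(f"{path}: empty MAF file") from None
    missing = [c for c in REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise MafFormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise MafFormatError(f"{path}: no data lines")
    return [
        MutationRecord(gene=g, sample=s, variant_class=v)
        for g, s, v in zip(
            df["Hugo_Symbol"], df["Tumor_Sample_Barcode"], df["Variant_Classification"]
        )
    ]


def filter_variant_class(
    records: Iterable[MutationRecord],
    excluded: Iterable[str] = DEFAULT_EXCLUDED_CLASSES,
) -> list[MutationRecord]:
    """Drop records whose variant classification is in ``excluded``.

    By default nonsense mutations are eliminated.  The number of removed
    records is logged.
    """
    excluded = frozenset(excluded)
    records = list(records)
    kept = [r for r in records if r.variant_class not in excluded]
    logger.info("filter_variant_class: removed %d of %d records", len(records) - len(kept), len(records))
    return kept


def build_binary_matrix(
    records: Iterable[MutationRecord], barcode_prefix: int | None = None
) -> BinaryGenotypeMatrix:
    """Collapse mutation records to a samples x genes 0/1 matrix.

    A cell is 1 iff at least one record exists for the (sample, gene) pair;
    genes mutated several times in one patient still code 1.  Samples and
    genes are ordered lexicographically so the result is independent of
    record order.  ``barcode_prefix`` optionally truncates sample barcodes to
    their first N characters before grouping (TCGA patient vs aliquot ids).
    """
    records = list(records)
    if not records:
        raise ValueError("no mutation records supplied")
    samples = sorted(
        {r.sample[:barcode_prefix] if barcode_prefix else r.sample for r in records}
    )
    genes = sorted({r.gene for r in records})
    srow = {s: i for i, s in enumerate(samples)}
    gcol = {g: j for j, g in enumerate(genes)}
    values = np.zeros((len(samples), len(genes)), dtype=np.int8)
    for r in records:
        s = r.sample[:barcode_prefix] if barcode_prefix else r.sample
        values[srow[s], gcol[r.gene]] = 1
    return BinaryGenotypeMatrix(values=values, sample_ids=samples, gene_ids=genes)


def merge_survival(
    X: BinaryGenotypeMatrix,
    phenotype: pd.DataFrame,
    sample_col: str = "sample",
    time_col: str = "OS.time",
    event_col: str = "OS",
) -> tuple[BinaryGenotypeMatrix, SurvivalData]:
    """Intersect the genotype matrix with a phenotype table on sample barcode.

    Rows with missing time or event are dropped and the drop count logged;
    both returned objects share the same sample order.
    """
    if sample_col in phenotype.columns:
        pheno = phenotype.set_index(sample_col)
    else:
        pheno = phenotype
    for col in (time_col, event_col):
        if col not in pheno.columns:
            raise MafFormatError(f"phenotype table lacks column {col!r}")
    pheno = pheno[~pheno.index.duplicated(keep="first")]
    common = [s for s in X.sample_ids if s in pheno.index]
    if not common:
        raise ValueError("no overlapping samples between genotype matrix and phenotype table")
    sub = pheno.loc[common, [time_col, event_col]].apply(pd.to_numeric, errors="coerce")
    ok = sub.notna().all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("merge_survival: dropped %d samples with missing survival", dropped)
    keep = [s for s, good in zip(common, ok) if good]
    idx = [list(X.sample_ids).index(s) for s in keep]
    X2 = BinaryGenotypeMatrix(
        values=X.values[idx, :], sample_ids=keep, gene_ids=list(X.gene_ids)
    )
    surv = SurvivalData(
        time=sub.loc[keep, time_col].to_numpy(dtype=float),
        event=sub.loc[keep, event_col].to_numpy(dtype=float).astype(int),
        sample_ids=keep,
    )
    return X2, surv


def mutation_summary(
    X: BinaryGenotypeMatrix, groups: Mapping[str, Sequence[int]] | np.ndarray, top_n: int = 10
) -> dict:
    """Per-group mutation burden and gene frequencies.

    ``groups`` is either a mapping group-name -> row indices or a per-sample
    label array.  For each group the median number of mutated genes per
    sample and the per-gene mutated fraction are reported, plus the top-N
    genes by fraction (ties broken alphabetically).
    """
    if not isinstance(groups, Mapping):
        labels = np.asarray(groups)
        if len(labels) != X.shape[0]:
            raise ValueError("group labels must align with samples")
        groups = {str(g): np.flatnonzero(labels == g) for g in np.unique(labels)}
    total = sum(len(v) for v in groups.values())
    if total != X.shape[0]:
        raise ValueError("groups must partition the samples")
    out = {}
    for name, idx in groups.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError(f"group {name!r} is empty")
        sub = X.values[idx, :]
        freqs = pd.Series(sub.mean(axis=0), index=list(X.gene_ids))
        top = freqs.sort_index().sort_values(ascending=False, kind="stable").head(top_n)
        out[name] = {
            "n": int(idx.size),
            "median_variants_per_sample": float(np.median(sub.sum(axis=1))),
            "gene_frequency": freqs,
            "top_genes": top,
        }
    return out
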