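"""Data model and file I/O for TMT abundance tables, sample annotations,
gene sets and differential-expression result tables.

The central container is :class:`AbundanceMatrix`: a proteins x samples
table of reporter abundances plus a sample annotation (group, batch, TMT
channel) and a protein -> gene-symbol map.  Missing measurements are NaN;
zero is a valid measured abundance, distinct from missing.

File formats are plain TSV (UTF-8, "." decimals, "NA" written for missing;
"", "NA" and "NaN" all accepted as missing on read) and standard GMT for
gene-set collections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUPS = ("PSP", "PD", "HC", "QC", "MP")
SUBJECT_GROUPS = ("PSP", "PD", "HC")

#: Legal order of normalization states for an AbundanceMatrix.
SCALE_ORDER = ("raw", "mp_ratio", "median_ratio", "log2", "zscore", "batch_corrected")

NA_VALUES = ["", "NA", "NaN"]

RESULT_COLUMNS = (
    "accession", "gene", "log2fc", "tstat", "pvalue", "q_sam",
    "auc_mean", "auc_sd", "q_broc", "sig_sam", "sig_broc", "sig_consensus",
)


class AnnotationError(ValueError):
    """Sample annotation violates a design invariant."""


def validate_annotation(annotation: pd.DataFrame, require_mp: bool = True) -> None:
    """Check the design invariants of a sample-annotation table.

    Requires columns sample_id, group, batch, channel; unique sample ids,
    exactly one MP per batch (only when ``require_mp``: MP channels are
    consumed by the MP normalization, so later stages have none), at most
    one QC per batch, and unique channels within each batch.
    """
    required = {"sample_id", "group", "batch", "channel"}
    missing = required - set(annotation.columns)
    if missing:
        raise AnnotationError(f"annotation missing columns: {sorted(missing)}")
    if annotation["sample_id"].duplicated().any():
        dups = annotation.loc[annotation["sample_id"].duplicated(), "sample_id"]
        raise AnnotationError(f"duplicate sample ids: {sorted(set(dups))}")
    bad = set(annotation["group"]) - set(GROUPS)
    if bad:
        raise AnnotationError(f"unknown groups: {sorted(bad)}")
    for batch, sub in annotation.groupby("batch"):
        n_mp = int((sub["group"] == "MP").sum())
        if require_mp and n_mp == 0:
            raise AnnotationError(f"batch {batch} without MP")
        if n_mp > 1:
            raise AnnotationError(f"batch {batch} has {n_mp} MP samples (expected one)")
        if int((sub["group"] == "QC").sum()) > 1:
            raise AnnotationError(f"batch {batch} has more than one QC")
        if sub["channel"].duplicated().any():
            raise AnnotationError(f"batch {batch} has duplicate channels")


@dataclass
class AbundanceMatrix:
    """Proteins x samples reporter abundances with sample annotations.

    Attributes
    ----------
    data:
        DataFrame indexed by protein accession, one column per sample_id,
        float values with NaN for missing.
    annotation:
        DataFrame with columns sample_id, group, batch, channel; row order
        defines sample (column) order.
    genes:
        Series mapping accession -> gene symbol.
    scale:
        Current normalization state, one of :data:`SCALE_ORDER`.
    """

    data: pd.DataFrame
    annotation: pd.DataFrame
    genes: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALE_ORDER:
            raise ValueError(f"unknown scale {self.scale!r}")
        validate_annotation(self.annotation, require_mp=(self.scale == "raw"))
        ann_ids = list(self.annotation["sample_id"])
        if list(self.data.columns) != ann_ids:
            raise ValueError("data columns do not match annotation sample order")
        if not self.data.index.equals(self.genes.index):
            raise ValueError("protein index of data and genes disagree")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()]
            raise ValueError(f"duplicate accession(s): {sorted(set(dups))}")

    # -- convenience accessors -------------------------------------------
    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_ids(self, groups=None) -> list[str]:
        ann = self.annotation
        if groups is None:
            return list(ann["sample_id"])
        return list(ann.loc[ann["group"].isin(groups), "sample_id"])

    @property
    def subject_ids(self) -> list[str]:
        return self.sample_ids(SUBJECT_GROUPS)

    @property
    def qc_ids(self) -> list[str]:
        return self.sample_ids(("QC",))

    @property
    def mp_ids(self) -> list[str]:
        return self.sample_ids(("MP",))

    def group_of(self, sample_id: str) -> str:
        ann = self.annotation.set_index("sample_id")
        return str(ann.loc[sample_id, "group"])

    def batches(self) -> list[int]:
        return sorted(set(int(b) for b in self.annotation["batch"]))

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.data.copy(), self.annotation.copy(), self.genes.copy(), self.scale
        )

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "AbundanceMatrix":
        """New matrix with replaced values (and optionally a new scale);
        annotation is subset to the columns of ``data``."""
        ann = self.annotation[self.annotation["sample_id"].isin(data.columns)]
        ann = ann.set_index("sample_id").loc[list(data.columns)].reset_index()
        genes = self.genes.loc[data.index]
        return AbundanceMatrix(data, ann, genes, scale or self.scale)

    def require_scale(self, *scales: str) -> None:
        if self.scale not in scales:
            raise ValueError(
                f"operation requires scale in {scales}, matrix is {self.scale!r}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT) with an optional background universe."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def terms(self) -> list[str]:
        return list(self.sets)

    def genes_of(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def with_universe(self, universe) -> "GeneSetCollection":
        return GeneSetCollection(dict(self.sets), frozenset(g.upper() for g in universe))


# -- readers / writers ----------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "channel": str})
    ann["batch"] = ann["batch"].astype(int)
    validate_annotation(ann)
    return ann


def read_abundance_table(path, annotation_path) -> AbundanceMatrix:
    """Read a Proteome-Discoverer-like abundance TSV plus its annotation.

    The abundance file has columns ``accession``, ``gene`` and one column
    per sample; blank/NA cells become missing.  Sample order is taken from
    the annotation file.
    """
    ann = read_annotation(annotation_path)
    tab = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False,
                      dtype={"accession": str, "gene": str})
    if "accession" not in tab.columns or "gene" not in tab.columns:
        raise ValueError("abundance table must have 'accession' and 'gene' columns")
    if tab["accession"].duplicated().any():
        dups = tab.loc[tab["accession"].duplicated(), "accession"]
        raise ValueError(f"duplicate accession(s): {sorted(set(dups))}")
    sample_cols = [c for c in tab.columns if c not in ("accession", "gene")]
    unannotated = set(sample_cols) - set(ann["sample_id"])
    if unannotated:
        raise ValueError(f"abundance column(s) without annotation: {sorted(unannotated)}")
    missing_cols = set(ann["sample_id"]) - set(sample_cols)
    if missing_cols:
        raise ValueError(f"annotated sample(s) absent from table: {sorted(missing_cols)}")
    tab = tab.set_index("accession")
    genes = tab["gene"]
    data = tab[list(ann["sample_id"])].astype(float)
    return AbundanceMatrix(data, ann, genes, scale="raw")


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: "NA" if (isinstance(v, float) and math.isnan(v)) else f"{v:.12g}")
        elif out[c].dtype.kind == "b":
            out[c] = out[c].map(lambda v: "TRUE" if v else "FALSE")
    return out


def write_abundance_table(matrix: AbundanceMatrix, path) -> None:
    """Write the matrix as TSV (accession, gene, one column per sample)."""
    out = matrix.data.copy()
    out.insert(0, "gene", matrix.genes)
    out = out.reset_index().rename(columns={"index": "accession"})
    if out.columns[0] != "accession":
        out = out.rename(columns={out.columns[0]: "accession"})
    _format_frame(out).to_csv(path, sep="\t", index=False)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, ``term<TAB>desc<TAB>genes...``.

    Duplicate genes within a line are deduplicated; gene symbols are
    upper-cased; empty lines are skipped; a line with fewer than 3 fields is
    a parse error reported with its line number.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT parse error at line {lineno}: expected >=3 fields, got {len(fields)}")
            term, desc = fields[0], fields[1]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"GMT parse error at line {lineno}: gene set {term!r} is empty")
            sets[term] = (desc, genes)
    return GeneSetCollection(sets)


def write_results(results: pd.DataFrame, path) -> None:
    """Write a per-protein DE result table as TSV with a fixed column order.

    Missing statistics are written as "NA".  Columns not present in
    ``results`` are filled with NA.
    """
    out = pd.DataFrame(index=results.index)
    for col in RESULT_COLUMNS:
        if col in results.columns:
            out[col] = results[col]
        elif col == "accession":
            out[col] = results.index
        else:
            out[col] = np.nan
    _format_frame(out).to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False,
                      dtype={"accession": str, "gene": str})
    for col in ("sig_sam", "sig_broc", "sig_consensus"):
        if col in tab.columns and tab[col].dtype == object:
            tab[col] = tab[col].map({"TRUE": True, "FALSE": False})
    return tab.set_index("accession", drop=False)
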