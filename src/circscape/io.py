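"""Readers and writers for the tabular and annotation formats used by the pipeline.

Conventions
-----------
* All matrices are TSV: first column the feature id, header row the sample ids.
* Genomic coordinates are 1-based inclusive everywhere inside the package;
  conversion to BED's 0-based half-open scheme happens only in :func:`write_bed`.
* Missing clinical values are real missing values (``NaN``/``pd.NA``), never zeros.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError, FormatError, ReferenceIntegrityError

MISSING_TOKENS = ("", "NA", "NaN", "nan", "None")

# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (sample_id, library_size, cohort_tag).

    Returns a DataFrame indexed by ``sample_id``. ``library_size`` is the total
    number of sequenced fragments of the sample and must be a positive integer:
    it is the denominator of the fragments-per-million normalization.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "library_size"):
        if col not in df.columns:
            raise FormatError(f"sample metadata is missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r} in sample metadata")
    if (df["library_size"] <= 0).any() or not np.issubdtype(
        df["library_size"].dtype, np.integer
    ):
        raise FormatError("library_size must be a positive integer for every sample")
    if "cohort_tag" not in df.columns:
        df["cohort_tag"] = "default"
    return df.set_index("sample_id")


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read an integer feature x sample matrix.

    Cells must be non-negative integers; a violation is reported with the
    offending feature/sample coordinate. When ``meta`` is given, every header
    sample id must resolve against it.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    values = df.to_numpy()
    if values.size:
        bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"cell at feature {df.index[i]!r}, sample {df.columns[j]!r} "
                f"is not a non-negative integer: {values[i, j]!r}"
            )
    if meta is not None:
        unknown = [s for s in df.columns if s not in meta.index]
        if unknown:
            raise ReferenceIntegrityError(
                f"sample ids not present in sample metadata: {unknown[:5]}"
            )
    return df.astype(np.int64)


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_real_matrix(path: str | Path) -> pd.DataFrame:
    """Read a real-valued feature x sample matrix (e.g. FPM); NA preserved."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_real_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

CLINICAL_NUMERIC = ("os_time", "os_event", "cr_status", "age")


def read_clinical_table(path: str | Path, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read the per-patient clinical table.

    Expected columns: ``sample_id``, ``os_time``, ``os_event``, ``risk_group``,
    ``molecular_subtype``, ``cr_status``, ``age``, ``sex`` plus any number of
    binary mutation flags (``mut_*``). Unknown extra columns are carried along
    as categorical features. Empty/"NA" tokens become missing values.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str}, na_values=list(MISSING_TOKENS),
        keep_default_na=True,
    )
    if "sample_id" not in df.columns:
        raise FormatError("clinical table is missing required column 'sample_id'")
    df = df.set_index("sample_id")
    for col in CLINICAL_NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return validate_clinical(df, meta)


def validate_clinical(df: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    for col in ("os_event", "cr_status"):
        if col in df.columns:
            vals = df[col].dropna().unique()
            bad = [v for v in vals if v not in (0, 1)]
            if bad:
                raise FormatError(f"{col} must be 0/1/missing; found {bad[:3]}")
    if "os_time" in df.columns and "os_event" in df.columns:
        if (df["os_time"].isna() != df["os_event"].isna()).any():
            raise FormatError("os_time and os_event must be missing together")
        if (df["os_time"].dropna() < 0).any():
            raise FormatError("os_time must be non-negative")
    mut_cols = [c for c in df.columns if c.startswith("mut_")]
    for col in mut_cols:
        vals = df[col].dropna().unique()
        bad = [v for v in vals if v not in (0, 1)]
        if bad:
            raise FormatError(f"mutation flag {col} must be 0/1; found {bad[:3]}")
    if meta is not None:
        unknown = [s for s in df.index if s not in meta.index]
        if unknown:
            raise ReferenceIntegrityError(
                f"clinical sample ids not present in sample metadata: {unknown[:5]}"
            )
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# drug response matrix
# ---------------------------------------------------------------------------

ORIENTATIONS = ("higher_better", "lower_better")


@dataclass
class DrugResponseMatrix:
    """Patients x drugs response matrix plus its orientation contract.

    ``higher_better`` suits DSS-type scores (higher score = better response);
    ``lower_better`` suits dose-response AUC (lower area = better response).
    Orientation is mandatory: downstream association and validation logic maps
    effect signs through it and refuses to guess.
    """

    values: pd.DataFrame
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(
                f"drug response orientation must be one of {ORIENTATIONS}, "
                f"got {self.orientation!r}"
            )

    @property
    def patients(self) -> pd.Index:
        return self.values.index

    @property
    def drugs(self) -> pd.Index:
        return self.values.columns


def read_drug_matrix(path: str | Path, orientation: str | None) -> DrugResponseMatrix:
    if orientation is None:
        raise ConfigurationError(
            "drug response orientation (higher_better/lower_better) must be supplied"
        )
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS))
    df.index = df.index.astype(str)
    return DrugResponseMatrix(df.astype(float), orientation)


def write_drug_matrix(drm: DrugResponseMatrix, path: str | Path) -> None:
    drm.values.to_csv(path, sep="\t", index_label="patient_id")


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


@dataclass
class AnnotationIndex:
    """Per-chromosome interval index of genes and exons (1-based inclusive).

    ``gene_trees[chrom]`` and ``exon_trees[chrom]`` are interval trees whose
    payload is the gene id; ``gene_spans`` maps gene id -> (chrom, start, end,
    strand). Intervals are stored half-open internally (the interval-tree
    convention) as [start, end+1).
    """

    gene_trees: dict[str, IntervalTree] = field(default_factory=dict)
    exon_trees: dict[str, IntervalTree] = field(default_factory=dict)
    gene_spans: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        tree = self.gene_trees.get(chrom)
        return {iv.data for iv in tree[pos]} if tree is not None else set()

    def exon_genes_at(self, chrom: str, pos: int) -> set[str]:
        tree = self.exon_trees.get(chrom)
        return {iv.data for iv in tree[pos]} if tree is not None else set()


def read_annotation_gtf(path: str | Path, chrom_lengths: dict[str, int] | None = None) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from Ensembl-style GTF ``gene``/``exon`` records.

    Exons whose gene has no ``gene`` record get a synthetic gene body spanning
    the union of that gene's exons (with a warning via ``warnings``).
    """
    import warnings

    idx = AnnotationIndex(chrom_lengths=dict(chrom_lengths or {}))
    exon_records: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated GTF fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "exon"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise FormatError(f"{path}: line {lineno}: missing gene_id attribute")
            gene_id = m.group(1)
            if feature == "gene":
                idx.gene_spans[gene_id] = (chrom, start, end, strand)
                idx.gene_trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, gene_id)
            else:
                exon_records.append((chrom, start, end, gene_id))
    orphans: dict[str, list[tuple[str, int, int]]] = {}
    for chrom, start, end, gene_id in exon_records:
        idx.exon_trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, gene_id)
        if gene_id not in idx.gene_spans:
            orphans.setdefault(gene_id, []).append((chrom, start, end))
    for gene_id, exons in orphans.items():
        chrom = exons[0][0]
        start = min(e[1] for e in exons)
        end = max(e[2] for e in exons)
        warnings.warn(
            f"exon(s) of {gene_id} have no enclosing gene record; "
            "attaching a synthetic gene body",
            stacklevel=2,
        )
        idx.gene_spans[gene_id] = (chrom, start, end, ".")
        idx.gene_trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, gene_id)
    return idx


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------


def write_bed(catalog: pd.DataFrame, path: str | Path) -> None:
    """Export a circRNA catalog as BED (0-based half-open; strand reported '.').

    Expects a catalog frame with columns chrom, start, end, locus_class and the
    normID as index.
    """
    bed = pd.DataFrame(
        {
            "chrom": catalog["chrom"],
            "start": catalog["start"].astype(int) - 1,
            "end": catalog["end"].astype(int),
            "name": catalog.index,
            "score": catalog["locus_class"],
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
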