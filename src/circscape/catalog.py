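"""Build the filtered, annotated circRNA catalog.

A circRNA is identified by its back-splicing junction (BSJ): the chromosome
plus the 1-based inclusive start and end of the circularized locus, rendered
as the normID string ``chrom__start__end``. The catalog pipeline is

    consensus over detection tools -> prevalence filter -> true-negative
    exclusion -> FPM normalization -> locus classification -> summaries

where the true-negative set is derived from a poly-A-selected cohort: poly-A
libraries cannot capture circRNAs (no poly-A tail), so any id called there
with high support is a detection artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ReferenceIntegrityError
from .io import AnnotationIndex

# ---------------------------------------------------------------------------
# normID codec
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class CircId:
    """A back-splicing junction locus, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"circRNA start > end: {self.chrom}:{self.start}-{self.end}")
        if self.start < 1:
            raise FormatError(f"circRNA coordinates are 1-based; got start={self.start}")

    @property
    def span(self) -> int:
        """Genomic span in bases (end - start + 1)."""
        return self.end - self.start + 1

    @property
    def norm_id(self) -> str:
        return f"{self.chrom}__{self.start}__{self.end}"


def format_norm_id(circ: CircId) -> str:
    return circ.norm_id


def parse_norm_id(norm_id: str) -> CircId:
    """Parse ``chrom__start__end``; chromosome names may themselves contain '_'."""
    parts = norm_id.rsplit("__", 2)
    if len(parts) != 3:
        raise FormatError(f"malformed normID {norm_id!r}: expected chrom__start__end")
    chrom, start_s, end_s = parts
    if not chrom:
        raise FormatError(f"malformed normID {norm_id!r}: empty chromosome")
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"malformed normID {norm_id!r}: non-integer coordinates") from exc
    return CircId(chrom, start, end)


# ---------------------------------------------------------------------------
# consensus and filters
# ---------------------------------------------------------------------------


def consensus_calls(callsets: Iterable[Iterable[str] | Mapping[str, object]]) -> set[str]:
    """Ids called by every detection tool (exact set intersection).

    Accepts each tool's call set as an iterable of normIDs or a mapping keyed
    by normID; order and duplicates are irrelevant.
    """
    sets = [set(cs) for cs in callsets]
    if len(sets) < 2:
        raise ValueError("consensus requires at least two tool call sets")
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def min_patients(n_samples: int, frac: float) -> int:
    """Minimum patient count for the prevalence rule: max(1, floor(frac * n)).

    The floor-with-clamp reading is the one consistent with a 1% rule giving
    3 patients in a 315-patient cohort (0.01 * 315 = 3.15 -> 3).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0 <= frac <= 1:
        raise ValueError("frac must be in [0, 1]")
    return max(1, math.floor(frac * n_samples))


def prevalence_filter(
    counts: pd.DataFrame, min_reads: int = 4, frac: float = 0.01
) -> pd.DataFrame:
    """Keep circRNAs with more than ``min_reads`` BSJ reads in enough patients.

    'More than' is strict: a count of exactly ``min_reads`` does not qualify.
    The patient threshold is :func:`min_patients` of the sample count.
    """
    thresh = min_patients(counts.shape[1], frac)
    n_supported = (counts.to_numpy() > min_reads).sum(axis=1)
    return counts.loc[n_supported >= thresh]


def build_true_negative_set(
    polya_counts: pd.DataFrame, min_reads: int = 4, frac: float = 0.25
) -> set[str]:
    """Artifact ids from a poly-A cohort: support > min_reads in > frac of samples.

    Both inequalities are strict: count 4 does not count as support, and
    exactly 25% of samples does not qualify.
    """
    if polya_counts.shape[1] == 0:
        return set()
    supported_frac = (polya_counts.to_numpy() > min_reads).mean(axis=1)
    return set(polya_counts.index[supported_frac > frac])


def exclude_true_negatives(catalog_ids: set[str], tn: set[str]) -> set[str]:
    return set(catalog_ids) - set(tn)


# ---------------------------------------------------------------------------
# FPM normalization
# ---------------------------------------------------------------------------


def fpm_normalize(counts: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Junction fragments per million: count / library_size * 1e6.

    The denominator is the sample's total sequenced fragments from the sample
    metadata (read-depth normalization), not the circRNA column sum.
    """
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ReferenceIntegrityError(f"samples with no library size: {missing[:5]}")
    lib = meta.loc[counts.columns, "library_size"].to_numpy(dtype=float)
    return counts / lib * 1e6


# ---------------------------------------------------------------------------
# locus classification
# ---------------------------------------------------------------------------


def classify_locus_type(circ: CircId, ann: AnnotationIndex) -> tuple[str, str | None]:
    """Classify a circRNA locus as exonic / intronic / intergenic.

    exonic: both BSJ ends fall inside exons of one common gene; intronic: both
    ends inside one gene body but not exonic; intergenic otherwise. Strand is
    ignored. When several genes qualify the tie breaks by smallest gene span,
    then lexicographic gene id.
    """

    def _pick(genes: set[str]) -> str:
        return min(
            genes,
            key=lambda g: (
                ann.gene_spans[g][2] - ann.gene_spans[g][1],
                g,
            ),
        )

    exonic = ann.exon_genes_at(circ.chrom, circ.start) & ann.exon_genes_at(circ.chrom, circ.end)
    if exonic:
        return "exonic", _pick(exonic)
    genic = ann.genes_at(circ.chrom, circ.start) & ann.genes_at(circ.chrom, circ.end)
    if genic:
        return "intronic", _pick(genic)
    return "intergenic", None


def build_catalog(ids: Iterable[str], ann: AnnotationIndex) -> pd.DataFrame:
    """Annotated catalog frame indexed by normID.

    Columns: chrom, start, end, span, locus_class, host_gene.
    """
    rows = []
    for norm_id in sorted(set(ids)):
        circ = parse_norm_id(norm_id)
        locus_class, host = classify_locus_type(circ, ann)
        rows.append(
            {
                "norm_id": norm_id,
                "chrom": circ.chrom,
                "start": circ.start,
                "end": circ.end,
                "span": circ.span,
                "locus_class": locus_class,
                "host_gene": host if host is not None else pd.NA,
            }
        )
    cols = ["norm_id", "chrom", "start", "end", "span", "locus_class", "host_gene"]
    df = pd.DataFrame(rows, columns=cols)
    return df.set_index("norm_id")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def catalog_summaries(
    catalog: pd.DataFrame,
    counts: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    expressed_min_reads: int = 1,
) -> dict[str, pd.DataFrame]:
    """Landscape summary tables.

    Returns per-chromosome circ counts with the Pearson correlation against
    chromosome length, the host-gene multiplicity histogram, per-patient
    distinct-circRNA counts and per-circRNA patient prevalence. A circRNA
    counts as expressed in a patient when its read count exceeds
    ``expressed_min_reads`` (strict).
    """
    per_chrom = (
        catalog.groupby("chrom").size().rename("n_circ").to_frame().reset_index()
    )
    per_chrom["chrom_length"] = per_chrom["chrom"].map(chrom_lengths)
    if per_chrom["chrom_length"].notna().sum() >= 3 and per_chrom["n_circ"].nunique() > 1:
        r, p = stats.pearsonr(
            per_chrom.dropna(subset=["chrom_length"])["n_circ"],
            per_chrom.dropna(subset=["chrom_length"])["chrom_length"],
        )
    else:
        r, p = np.nan, np.nan
    per_chrom.attrs["pearson_r"] = float(r)
    per_chrom.attrs["pearson_p"] = float(p)

    hosts = catalog["host_gene"].dropna()
    multiplicity = hosts.value_counts()
    mult_hist = (
        multiplicity.value_counts().sort_index().rename("n_genes").to_frame()
    )
    mult_hist.index.name = "n_circ_per_gene"

    common = counts.index.intersection(catalog.index)
    expressed = counts.loc[common].to_numpy() > expressed_min_reads
    per_patient = pd.DataFrame(
        {"n_distinct_circ": expressed.sum(axis=0)}, index=counts.columns
    )
    per_circ = pd.DataFrame({"n_patients": expressed.sum(axis=1)}, index=common)

    return {
        "per_chromosome": per_chrom,
        "host_multiplicity": mult_hist.reset_index(),
        "per_patient": per_patient.reset_index(names="sample_id"),
        "per_circ_prevalence": per_circ.reset_index(names="norm_id"),
    }
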