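"""Two-statistic subgroup-specific circRNA discovery.

A circRNA is specific to a risk group g when it is significantly up-regulated
in g versus all remaining samples (T1, a Welch-type t with a variance floor —
the robust element), the remaining groups are mutually homogeneous (T2, a
score-type chi-square on the group means), and its host gene is *not*
differentially expressed in g (the veto that separates genuine circRNA
regulation from plain host-gene transcription). Defaults: T1 FDR < 0.01
(Benjamini-Hochberg within each group's screen), T2 p > 0.05, host p > 0.05.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import adjust_bh
from .errors import AnalysisError

VAR_FLOOR = 1e-6


def _group_moments(x: np.ndarray) -> tuple[float, float, int]:
    n = x.shape[-1]
    mean = x.mean(axis=-1)
    var = x.var(axis=-1, ddof=1) if n > 1 else np.zeros_like(mean)
    return mean, np.maximum(var, VAR_FLOOR), n


def t1_up_statistic(
    expr: np.ndarray | Sequence[float],
    groups: Sequence[str] | np.ndarray,
    g: str,
) -> tuple[float, float]:
    """Welch t of group g versus the rest with floored variances; one-sided up p.

    ``expr`` is on the log2(FPM + 1) scale. Returns (T1, p) where p is the
    upper-tail probability for up-regulation in g (large positive T1 = small p).
    """
    expr = np.asarray(expr, dtype=float)
    groups = np.asarray(groups)
    in_g = groups == g
    if in_g.sum() == 0:
        raise AnalysisError(f"group {g!r} absent from labels")
    if in_g.sum() < 2 or (~in_g).sum() < 2:
        raise AnalysisError("need at least 2 samples in the group and in the rest")
    m1, v1, n1 = _group_moments(expr[in_g])
    m2, v2, n2 = _group_moments(expr[~in_g])
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = stats.t.sf(t, df)
    return float(t), float(p)


def t2_homogeneity(
    expr: np.ndarray | Sequence[float],
    groups: Sequence[str] | np.ndarray,
    g: str,
) -> tuple[float, float]:
    """Homogeneity chi-square of the remaining groups after excluding g.

    T2 = sum_j n_j (xbar_j - xbar_w)^2 / s2_pool over remaining groups j, with
    xbar_w the pooled mean and s2_pool the pooled within-group variance
    (floored); p from chi-square with (#remaining - 1) df. Small T2 = the
    remaining groups look alike.
    """
    expr = np.asarray(expr, dtype=float)
    groups = np.asarray(groups)
    rest_labels = [lab for lab in pd.unique(groups) if lab != g and not pd.isna(lab)]
    if len(rest_labels) < 2:
        raise AnalysisError("need at least 2 remaining groups for the homogeneity test")
    means, ns, ss = [], [], []
    for lab in rest_labels:
        x = expr[groups == lab]
        if x.shape[0] < 2:
            raise AnalysisError(f"remaining group {lab!r} has fewer than 2 samples")
        means.append(x.mean())
        ns.append(x.shape[0])
        ss.append(x.var(ddof=1) * (x.shape[0] - 1))
    means = np.asarray(means)
    ns = np.asarray(ns, dtype=float)
    pooled_mean = np.sum(ns * means) / ns.sum()
    s2_pool = max(np.sum(ss) / (ns.sum() - len(rest_labels)), VAR_FLOOR)
    t2 = float(np.sum(ns * (means - pooled_mean) ** 2) / s2_pool)
    p = float(stats.chi2.sf(t2, df=len(rest_labels) - 1))
    return t2, p


# ---------------------------------------------------------------------------
# vectorized screen internals
# ---------------------------------------------------------------------------


def _welch_up_matrix(
    x: np.ndarray, in_g: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch up-test of columns in_g vs the rest; floored variances."""
    a, b = x[:, in_g], x[:, ~in_g]
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = np.maximum(a.var(axis=1, ddof=1), VAR_FLOOR)
    v2 = np.maximum(b.var(axis=1, ddof=1), VAR_FLOOR)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, stats.t.sf(t, df)


def _t2_matrix(x: np.ndarray, groups: np.ndarray, rest_labels: list) -> tuple[np.ndarray, np.ndarray]:
    means, ns, ss = [], [], []
    for lab in rest_labels:
        sub = x[:, groups == lab]
        means.append(sub.mean(axis=1))
        ns.append(sub.shape[1])
        ss.append(sub.var(axis=1, ddof=1) * (sub.shape[1] - 1))
    means = np.stack(means, axis=1)
    ns = np.asarray(ns, dtype=float)
    pooled_mean = (means * ns).sum(axis=1) / ns.sum()
    s2_pool = np.maximum(np.stack(ss, axis=1).sum(axis=1) / (ns.sum() - len(rest_labels)), VAR_FLOOR)
    t2 = ((ns * (means - pooled_mean[:, None]) ** 2).sum(axis=1)) / s2_pool
    return t2, stats.chi2.sf(t2, df=len(rest_labels) - 1)


def find_subgroup_specific(
    circ_fpm: pd.DataFrame,
    gene_counts: pd.DataFrame,
    groups: pd.Series,
    host_gene: Mapping[str, str | None] | pd.Series,
    t1_fdr_cut: float = 0.01,
    t2_p_cut: float = 0.05,
    host_p_cut: float = 0.05,
) -> pd.DataFrame:
    """Screen every (circRNA, group) pair for subgroup-specific up-regulation.

    ``circ_fpm``: circ x sample FPM matrix (log2(FPM+1) is taken internally);
    ``gene_counts``: gene x sample counts for the host-gene veto (log2(CPM+1)
    Welch two-sided); ``groups``: per-sample group labels (missing labels are
    dropped); ``host_gene``: circ id -> host gene id or missing (intergenic
    circRNAs have no host gene and pass the veto vacuously).

    Verdict = (T1 FDR < cut) & (T1 > 0) & (T2 p > cut) & (host p > cut).
    """
    import warnings

    groups = pd.Series(groups)
    keep = groups.dropna().index.intersection(circ_fpm.columns)
    labels = groups.loc[keep].to_numpy()
    x = np.log2(circ_fpm.loc[:, keep].to_numpy(dtype=float) + 1.0)

    if gene_counts is not None and len(gene_counts) and keep.isin(gene_counts.columns).all():
        from .diffexp import estimate_size_factors

        sub_genes = gene_counts.loc[:, keep]
        # robust (median-of-ratios) library normalization: immune to the
        # composition bias a handful of strongly shifted genes induces in
        # plain total-count CPM
        sf = estimate_size_factors(sub_genes, pseudo_reference=True).to_numpy()
        gc = sub_genes.to_numpy(dtype=float) / sf
        scale = 1e6 / max(gc.sum(axis=0).mean(), 1.0)
        log_cpm = np.log2(gc * scale + 1.0)
        gene_index = {g: i for i, g in enumerate(gene_counts.index)}
    else:
        log_cpm, gene_index = None, {}

    host_gene = pd.Series(host_gene)
    unique_groups = sorted(lab for lab in pd.unique(labels))
    records = []
    for g in unique_groups:
        in_g = labels == g
        if in_g.sum() < 2:
            warnings.warn(f"group {g!r} has fewer than 2 samples; skipped", stacklevel=2)
            continue
        rest_labels = [lab for lab in unique_groups if lab != g]
        t1, p1 = _welch_up_matrix(x, in_g)
        fdr1 = adjust_bh(p1)
        t2, p2 = _t2_matrix(x, labels, rest_labels)
        if log_cpm is not None:
            # two-sided host-gene DE p from the same Welch machinery
            _, host_p_one = _welch_up_matrix(log_cpm, in_g)
            host_p_two = 2.0 * np.minimum(host_p_one, 1.0 - host_p_one)
        for i, circ in enumerate(circ_fpm.index):
            host = host_gene.get(circ, None)
            if host is None or pd.isna(host) or log_cpm is None or host not in gene_index:
                hp = np.nan  # no host gene: veto passes vacuously
            else:
                hp = float(host_p_two[gene_index[host]])
            verdict = (
                fdr1[i] < t1_fdr_cut
                and t1[i] > 0
                and p2[i] > t2_p_cut
                and (np.isnan(hp) or hp > host_p_cut)
            )
            records.append(
                {
                    "norm_id": circ,
                    "group": g,
                    "T1": t1[i],
                    "T1_p": p1[i],
                    "T1_FDR": fdr1[i],
                    "T2": t2[i],
                    "T2_p": p2[i],
                    "host_gene": host if host is not None and not pd.isna(host) else pd.NA,
                    "host_p": hp,
                    "verdict": bool(verdict),
                }
            )
    return pd.DataFrame.from_records(records)
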