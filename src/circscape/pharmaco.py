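"""Drug-sensitivity association and cross-cohort signature transfer.

Discovery: ex vivo drug responses of patients stratified high/low on a
circRNA are compared per drug by Welch's t; a drug is significant when
p < 0.05 AND the absolute high-low median difference exceeds 1 (response
units). The favored group maps the sign of the difference through the
response orientation (DSS: higher = better; AUC: lower = better).

Validation: a signature of strongly differential genes (FDR < 0.05,
|log2FC| > 1, mean expression above the median of gene means) transfers the
high/low grouping to an external cohort by per-gene majority vote — each
gene votes a patient high-like or low-like according to the side of the
*validation cohort's own* per-gene median, which makes the labels invariant
to any additive per-gene batch shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import nb_wald_de
from .errors import AnalysisError, ConfigurationError
from .io import DrugResponseMatrix


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Unequal-variance t-test: returns (t, Welch-Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 2 or y.shape[0] < 2:
        raise AnalysisError("Welch's t needs at least 2 observations per group")
    n1, n2 = x.shape[0], y.shape[0]
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return 0.0, float(n1 + n2 - 2), 1.0
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# drug association
# ---------------------------------------------------------------------------


def drug_group_association(
    responses: DrugResponseMatrix,
    labels: pd.Series,
    p_cut: float = 0.05,
    median_diff_cut: float = 1.0,
) -> pd.DataFrame:
    """Per-drug association of responses with high/low patient groups.

    ``labels``: per-patient {"low","high"}. A drug is skipped (with a note)
    when either group has fewer than 2 non-missing responses. Significance is
    conjunctive: p < p_cut and |median(high) - median(low)| > median_diff_cut.
    ``favored`` is the group with the better response after mapping the sign
    of the difference through the orientation.
    """
    labels = pd.Series(labels)
    ids = labels.index.intersection(responses.patients)
    labels = labels.loc[ids]
    records = []
    for drug in responses.drugs:
        vals = responses.values.loc[ids, drug]
        hi = vals[labels == "high"].dropna()
        lo = vals[labels == "low"].dropna()
        if len(hi) < 2 or len(lo) < 2:
            records.append({"drug": drug, "n_low": len(lo), "n_high": len(hi),
                            "t": np.nan, "p": np.nan, "median_diff": np.nan,
                            "significant": False, "favored": pd.NA,
                            "note": "too few responders"})
            continue
        t, _, p = welch_t(lo.to_numpy(), hi.to_numpy())
        mdiff = float(np.median(hi) - np.median(lo))
        sig = (p < p_cut) and (abs(mdiff) > median_diff_cut)
        if mdiff == 0:
            favored = pd.NA
        elif responses.orientation == "higher_better":
            favored = "high" if mdiff > 0 else "low"
        else:
            favored = "low" if mdiff > 0 else "high"
        records.append({"drug": drug, "n_low": len(lo), "n_high": len(hi),
                        "t": t, "p": p, "median_diff": mdiff,
                        "significant": bool(sig), "favored": favored, "note": ""})
    return pd.DataFrame.from_records(records).set_index("drug")


# ---------------------------------------------------------------------------
# signature transfer
# ---------------------------------------------------------------------------


@dataclass
class TransferSignature:
    """Signed gene signature for cross-cohort group transfer.

    ``directions``: gene id -> +1/-1, the sign of the discovery log2FC
    (high vs low). The thresholds used to select the genes are echoed for the
    run manifest.
    """

    directions: pd.Series
    fdr_cut: float
    lfc_cut: float

    def __len__(self) -> int:
        return len(self.directions)


def build_transfer_signature(
    gene_counts: pd.DataFrame,
    labels: pd.Series,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.0,
    de_result: pd.DataFrame | None = None,
) -> TransferSignature:
    """Select signature genes from a discovery high/low DE analysis.

    Criteria (all required): FDR < fdr_cut, |log2FC| > lfc_cut, and mean
    normalized expression above the median of all genes' mean expression.
    ``de_result`` may supply a precomputed DE table (index = gene ids with
    baseMean/log2FC/FDR columns); otherwise the NB Wald engine is run on
    ``gene_counts`` with condition = (labels == "high").
    """
    labels = pd.Series(labels)
    ids = labels.index.intersection(gene_counts.columns)
    cond = (labels.loc[ids] == "high").astype(int).to_numpy()
    if de_result is None:
        de_result = nb_wald_de(gene_counts.loc[:, ids], cond)
    mean_cut = de_result["baseMean"].median()
    mask = (
        (de_result["FDR"] < fdr_cut)
        & (de_result["log2FC"].abs() > lfc_cut)
        & (de_result["baseMean"] > mean_cut)
    )
    mask = mask.fillna(False)
    if not mask.any():
        raise AnalysisError(
            "empty transfer signature: no gene passed FDR/log2FC/mean-expression "
            "criteria; consider relaxing the thresholds"
        )
    directions = np.sign(de_result.loc[mask, "log2FC"]).astype(int)
    return TransferSignature(directions=directions, fdr_cut=fdr_cut, lfc_cut=lfc_cut)


def assign_transfer_labels(
    signature: TransferSignature, validation_expr: pd.DataFrame
) -> pd.DataFrame:
    """Majority-vote low-like/high-like labels for validation-cohort patients.

    ``validation_expr``: gene x patient expression (log2 CPM or any per-gene
    monotone transform — the vote only uses the side of the per-gene median
    computed in the validation cohort itself). Each signature gene g with
    direction d_g casts, for patient p, a high vote when
    d_g * sign(expr[g,p] - median_g) > 0, a low vote when < 0, and abstains on
    exact equality. Label = strict majority of cast votes; ties or all-abstain
    leave the patient unassigned.
    """
    present = signature.directions.index.intersection(validation_expr.index)
    if len(present) == 0:
        raise AnalysisError("no signature gene present in the validation matrix")
    if len(present) < len(signature.directions):
        import warnings

        warnings.warn(
            f"{len(signature.directions) - len(present)} signature gene(s) absent "
            "from the validation matrix; dropped",
            stacklevel=2,
        )
    x = validation_expr.loc[present].to_numpy(dtype=float)
    d = signature.directions.loc[present].to_numpy()[:, None]
    med = np.median(x, axis=1, keepdims=True)
    vote = d * np.sign(x - med)  # genes x patients in {-1, 0, +1}
    votes_high = (vote > 0).sum(axis=0)
    votes_low = (vote < 0).sum(axis=0)
    abstain = (vote == 0).sum(axis=0)
    label = np.where(
        votes_high > votes_low, "high-like",
        np.where(votes_low > votes_high, "low-like", "unassigned"),
    )
    cast = votes_high + votes_low
    label = np.where(cast == 0, "unassigned", label)
    return pd.DataFrame(
        {
            "votes_high": votes_high,
            "votes_low": votes_low,
            "abstain": abstain,
            "label": label,
        },
        index=validation_expr.columns,
    )


def validate_drug_association(
    labels: pd.DataFrame,
    responses: DrugResponseMatrix,
    drug: str,
    expected_direction: str,
    p_cut: float = 0.05,
) -> dict[str, object]:
    """Check a discovery drug finding in an external cohort.

    ``labels``: the frame from :func:`assign_transfer_labels`;
    ``expected_direction``: "high" or "low" — the group the discovery cohort
    found to respond better. Verdict "validated" requires Welch p < p_cut AND
    the better-responding group (after orientation mapping) to match.
    """
    if expected_direction not in ("high", "low"):
        raise ConfigurationError(
            "expected_direction must be 'high' or 'low' (the discovery claim)"
        )
    assigned = labels[labels["label"] != "unassigned"]
    ids = assigned.index.intersection(responses.patients)
    vals = responses.values.loc[ids, drug]
    hi = vals[assigned.loc[ids, "label"] == "high-like"].dropna()
    lo = vals[assigned.loc[ids, "label"] == "low-like"].dropna()
    if len(hi) < 2 or len(lo) < 2:
        raise AnalysisError("both label groups need >= 2 responders for validation")
    t, _, p = welch_t(lo.to_numpy(), hi.to_numpy())
    diff = float(np.median(hi) - np.median(lo))
    if diff == 0:
        favored = None
    elif responses.orientation == "higher_better":
        favored = "high" if diff > 0 else "low"
    else:
        favored = "low" if diff > 0 else "high"
    verdict = "validated" if (p < p_cut and favored == expected_direction) else "not validated"
    return {
        "drug": drug,
        "n_low": int(len(lo)),
        "n_high": int(len(hi)),
        "t": t,
        "p": p,
        "median_diff": diff,
        "favored": favored,
        "expected": expected_direction,
        "verdict": verdict,
    }
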