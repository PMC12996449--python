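"""Synthetic AML-like cohort generator with a planted-effect truth ledger.

The generator emulates the statistical structure the downstream stages
assume, so the whole pipeline runs and is testable without any external
download:

* circRNA back-splicing-junction counts are negative binomial
  (Var = mu + alpha mu^2) with log-normal library sizes, so the FPM and
  size-factor code paths are exercised;
* three overlapping detection-tool call sets with per-tool detection
  probabilities and disjoint tool-specific false positives;
* a poly-A-selected cohort whose designated artifact ids exceed the
  true-negative thresholds while genuine circRNAs stay near zero;
* planted differential, subgroup-specific, prognostic and drug-associated
  effects, all recorded in the truth ledger (`SimTruth`);
* clinical survival times from an exponential proportional-hazards model on
  the planted prognostic circRNA's high/low indicator;
* a validation cohort whose gene expression shares the planted signature
  directions but carries an additive per-gene batch shift, with responses in
  the opposite (AUC, lower-better) orientation.

Every component draws from its own child stream of the master seed, so
changing one block's parameters never perturbs another block's sample.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnnotationIndex, DrugResponseMatrix
from intervaltree import IntervalTree

# hg38 primary-assembly chromosome lengths (1..22), used so the per-chromosome
# circRNA counts correlate with chromosome length as in real catalogs
CHROM_LENGTHS = {
    "1": 248956422, "2": 242193529, "3": 198295559, "4": 190214555,
    "5": 181538259, "6": 170805979, "7": 159345973, "8": 145138636,
    "9": 138394717, "10": 133797422, "11": 135086622, "12": 133275309,
    "13": 114364328, "14": 107043718, "15": 101991189, "16": 90338345,
    "17": 83257441, "18": 80373285, "19": 58617616, "20": 64444167,
    "21": 46709983, "22": 50818468,
}

GROUPS = ("Adverse", "Intermediate", "Favorable")


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; defaults are the desk-scale study conditions."""

    n_patients: int = 300
    n_controls: int = 100
    n_circ: int = 5000
    n_genes: int = 2000
    group_proportions: dict = field(
        default_factory=lambda: {"Adverse": 0.35, "Intermediate": 0.35, "Favorable": 0.30}
    )
    # NB count model (Var = mu + alpha mu^2)
    baseline_log_mean: float = float(np.log(2.0))
    baseline_log_sd: float = 1.2
    dispersion_log_mean: float = float(np.log(0.4))
    dispersion_log_sd: float = 0.5
    zero_inflation: float = 0.0
    # library sizes, log-normal
    libsize_log_mean: float = float(np.log(3.0e7))
    libsize_log_sd: float = 0.3
    # planted effects
    n_de: int = 100
    de_log2fc: float = 2.0
    n_prognostic: int = 1
    prognostic_log_hr: float = float(np.log(2.5))
    subgroup_group: str = "Adverse"
    n_subgroup: int = 50
    subgroup_log2_shift: float = 1.5
    n_subgroup_vetoed: int = 10
    # locus-class mixture for circ placement
    frac_exonic: float = 0.90
    frac_intronic: float = 0.05
    # tools
    tool_names: tuple = ("circall", "ciri2", "findcirc2")
    tool_detect_probs: tuple = (0.95, 0.90, 0.90)
    tool_fp_counts: tuple = (150, 150, 150)
    # poly-A cohort
    polya_n_samples: int = 40
    n_artifacts: int = 50
    artifact_mean: float = 20.0
    polya_background_mean: float = 0.05
    # survival
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.3
    # genes
    gene_log_mean: float = float(np.log(50.0))
    gene_log_sd: float = 1.0
    gene_dispersion: float = 0.2
    # drugs
    n_drugs: int = 100
    n_drug_hits: int = 10
    n_drug_patients: int = 45
    drug_effect: float = 3.0
    drug_noise_sd: float = 1.5
    drug_baseline_mean: float = 10.0
    drug_baseline_sd: float = 3.0
    # transfer validation
    n_signature_genes: int = 30
    signature_log2fc: float = 2.0
    batch_shift_sd: float = 1.0
    n_validation_patients: int = 150
    validation_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        props = self.group_proportions
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if set(props) != set(GROUPS):
            raise ValueError(f"group proportions must cover {GROUPS}")
        min_group = min(props.values()) * self.n_patients
        if min_group < 2:
            raise ValueError("need at least 2 patients per risk group")
        planted = self.n_de + self.n_prognostic + self.n_subgroup + self.n_subgroup_vetoed + self.n_artifacts
        if planted > self.n_circ:
            raise ValueError("planted sets exceed the circRNA universe")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")


@dataclass
class SimTruth:
    """Planted-effect ledger: what was planted where, for recovery testing."""

    features: pd.DataFrame      # norm_id, role, effect, group; one row per planted circ
    patients: pd.DataFrame      # sample_id, group, high_prognostic
    validation_patients: pd.DataFrame  # latent high/low labels of the validation cohort
    signature_genes: pd.DataFrame  # gene_id, direction, log2fc
    drug_hits: pd.DataFrame     # drug, effect, favored
    artifact_ids: list
    prognostic_id: str | None
    baseline_mean: pd.Series
    dispersion: pd.Series


@dataclass
class CohortBundle:
    """Everything one simulated study produces."""

    config: SimConfig
    meta: pd.DataFrame                 # AML + control samples
    circ_counts: pd.DataFrame          # circ x (AML + control)
    condition: pd.Series               # per-sample cohort tag (AML / HSPC)
    tool_callsets: dict                # tool -> circ x sample counts
    polya_counts: pd.DataFrame
    polya_meta: pd.DataFrame
    gene_counts: pd.DataFrame          # gene x AML samples
    clinical: pd.DataFrame
    annotation: AnnotationIndex
    gtf_lines: list
    host_gene: pd.Series               # circ -> host gene (NA for intergenic)
    drugs: DrugResponseMatrix
    validation_expr: pd.DataFrame
    validation_drugs: DrugResponseMatrix
    truth: SimTruth


# ---------------------------------------------------------------------------
# annotation and circRNA universe
# ---------------------------------------------------------------------------


def _simulate_annotation(cfg: SimConfig, rng: np.random.Generator):
    """Place non-overlapping genes (with exons) along hg38-length chromosomes."""
    chroms = list(CHROM_LENGTHS)
    lengths = np.array([CHROM_LENGTHS[c] for c in chroms], dtype=float)
    genes_per_chrom = rng.multinomial(cfg.n_genes, lengths / lengths.sum())
    gtf_lines: list[str] = []
    idx = AnnotationIndex(chrom_lengths=dict(CHROM_LENGTHS))
    gene_records = []  # (gene_id, chrom, start, end, exons)
    g = 0
    for chrom, k in zip(chroms, genes_per_chrom):
        if k == 0:
            continue
        slot = CHROM_LENGTHS[chrom] // (k + 1)
        for i in range(k):
            gene_id = f"G{g:05d}"
            g += 1
            start = slot * (i + 1) + 1
            span = int(min(slot * 0.6, np.exp(rng.normal(np.log(2.0e4), 0.8))))
            span = max(span, 1000)
            end = start + span - 1
            n_ex = int(rng.integers(3, 9))
            seg = span // n_ex
            exons = []
            for e in range(n_ex):
                ex_start = start + e * seg
                ex_len = max(int(seg * rng.uniform(0.2, 0.5)), 50)
                exons.append((ex_start, min(ex_start + ex_len - 1, end)))
            gene_records.append((gene_id, chrom, start, end, exons))
            idx.gene_spans[gene_id] = (chrom, start, end, "+")
            idx.gene_trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, gene_id)
            gtf_lines.append(
                f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t+\t.\tgene_id \"{gene_id}\";"
            )
            for ex_start, ex_end in exons:
                idx.exon_trees.setdefault(chrom, IntervalTree()).addi(ex_start, ex_end + 1, gene_id)
                gtf_lines.append(
                    f"{chrom}\tsim\texon\t{ex_start}\t{ex_end}\t.\t+\t.\tgene_id \"{gene_id}\";"
                )
    return idx, gtf_lines, gene_records


def _simulate_circ_universe(cfg: SimConfig, gene_records, rng: np.random.Generator):
    """Draw circRNA loci: mostly exonic, some intronic, some intergenic."""
    ids: list[str] = []
    hosts: list[object] = []
    seen: set[str] = set()
    gene_weights = rng.exponential(1.0, size=len(gene_records))
    gene_weights /= gene_weights.sum()
    while len(ids) < cfg.n_circ:
        u = rng.uniform()
        if u < cfg.frac_exonic:
            gi = rng.choice(len(gene_records), p=gene_weights)
            gene_id, chrom, _gs, _ge, exons = gene_records[gi]
            i = int(rng.integers(0, len(exons)))
            j = int(rng.integers(i, len(exons)))
            s = int(rng.integers(exons[i][0], exons[i][1] + 1))
            e = int(rng.integers(exons[j][0], exons[j][1] + 1))
            if s > e:
                s, e = e, s
            host = gene_id
        elif u < cfg.frac_exonic + cfg.frac_intronic:
            gi = rng.choice(len(gene_records), p=gene_weights)
            gene_id, chrom, _gs, _ge, exons = gene_records[gi]
            if len(exons) < 2:
                continue
            i = int(rng.integers(0, len(exons) - 1))
            lo, hi = exons[i][1] + 1, exons[i + 1][0] - 1
            if hi - lo < 10:
                continue
            s = int(rng.integers(lo, hi - 5))
            e = int(rng.integers(s + 1, hi + 1))
            host = gene_id
        else:
            chrom = str(rng.choice(list(CHROM_LENGTHS)))
            gi_recs = [r for r in gene_records if r[1] == chrom]
            # a gap after the last gene always exists by construction
            last_end = max((r[3] for r in gi_recs), default=0)
            lo = last_end + 1000
            hi = min(lo + 500000, CHROM_LENGTHS[chrom] - 1)
            if hi - lo < 100:
                continue
            s = int(rng.integers(lo, hi - 50))
            e = int(s + rng.integers(100, 20000))
            host = None
        norm_id = f"{chrom}__{s}__{e}"
        if norm_id in seen or s >= e:
            continue
        seen.add(norm_id)
        ids.append(norm_id)
        hosts.append(host)
    return ids, pd.Series(hosts, index=ids, name="host_gene", dtype=object)


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + alpha mu^2; alpha ~ 0 degrades to Poisson."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson_like = alpha < 1e-8
    if poisson_like.any():
        out[poisson_like] = rng.poisson(mean[poisson_like])
    nb = ~poisson_like
    if nb.any():
        shape = 1.0 / alpha[nb]
        lam = rng.gamma(shape, alpha[nb] * mean[nb])
        out[nb] = rng.poisson(lam)
    return out


def simulate_circ_counts(
    cfg: SimConfig,
    rng: np.random.Generator,
    fold: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
    library_sizes: np.ndarray | None = None,
    baseline_mean: np.ndarray | None = None,
    dispersion: np.ndarray | None = None,
    feature_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB count matrix: c_is ~ NB(mu_i * L_s / median(L) * fold_is, alpha_i).

    All structural arguments are optional; defaults draw fresh baselines,
    library sizes and ids from ``cfg``. Returns (counts, meta).
    """
    n_feat = cfg.n_circ if baseline_mean is None else len(baseline_mean)
    if sample_ids is None:
        sample_ids = [f"P{i:04d}" for i in range(cfg.n_patients)]
    n_s = len(sample_ids)
    if library_sizes is None:
        library_sizes = np.exp(rng.normal(cfg.libsize_log_mean, cfg.libsize_log_sd, n_s))
    library_sizes = np.asarray(library_sizes, dtype=float)
    if baseline_mean is None:
        baseline_mean = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, n_feat))
    if dispersion is None:
        dispersion = np.exp(rng.normal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, n_feat))
    if feature_ids is None:
        feature_ids = [f"circ{i:05d}" for i in range(n_feat)]
    depth = library_sizes / np.median(library_sizes)
    mean = baseline_mean[:, None] * depth[None, :]
    if fold is not None:
        mean = mean * fold
    counts = _nb_sample(rng, mean, np.asarray(dispersion)[:, None])
    if cfg.zero_inflation > 0:
        counts = counts * (rng.uniform(size=counts.shape) >= cfg.zero_inflation)
    meta = pd.DataFrame(
        {"library_size": np.round(library_sizes).astype(np.int64), "cohort_tag": "AML"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return pd.DataFrame(counts, index=feature_ids, columns=sample_ids), meta


def simulate_tool_callsets(
    counts: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator,
    always_detect: set | None = None,
) -> tuple[dict, dict]:
    """Per-tool call sets: independent detection + disjoint tool-specific FPs.

    Returns (callsets, fp_ids) where callsets maps tool name -> circ x sample
    count frame and fp_ids maps tool name -> its private false-positive ids.
    ``always_detect`` ids bypass the detection coin flip (used to keep planted
    markers identifiable through the consensus step).
    """
    callsets: dict[str, pd.DataFrame] = {}
    fp_ids: dict[str, list[str]] = {}
    used: set[str] = set(counts.index)
    n_s = counts.shape[1]
    forced = np.isin(counts.index.to_numpy(), sorted(always_detect)) if always_detect else None
    for tool, p_det, n_fp in zip(cfg.tool_names, cfg.tool_detect_probs, cfg.tool_fp_counts):
        detected = rng.uniform(size=counts.shape[0]) < p_det
        if forced is not None:
            detected |= forced
        frame = counts.loc[counts.index[detected]]
        fps = []
        while len(fps) < n_fp:
            chrom = str(rng.choice(list(CHROM_LENGTHS)))
            s = int(rng.integers(1, CHROM_LENGTHS[chrom] - 100000))
            e = s + int(rng.integers(100, 50000))
            nid = f"{chrom}__{s}__{e}"
            if nid not in used:
                used.add(nid)
                fps.append(nid)
        fp_counts = rng.poisson(0.5, size=(n_fp, n_s)) + (
            rng.uniform(size=(n_fp, n_s)) < 0.2
        ).astype(np.int64)
        frame = pd.concat(
            [frame, pd.DataFrame(fp_counts, index=fps, columns=counts.columns)]
        )
        callsets[tool] = frame
        fp_ids[tool] = fps
    return callsets, fp_ids


def simulate_polya_cohort(
    cfg: SimConfig, circ_ids: list[str], artifact_ids: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poly-A-library cohort: genuine circRNAs near zero, artifacts high.

    Artifact ids receive NB counts whose support exceeds the true-negative
    thresholds (reads > 4 in > 25% of samples); everything else is sparse
    Poisson background.
    """
    samples = [f"PA{i:03d}" for i in range(cfg.polya_n_samples)]
    counts = rng.poisson(cfg.polya_background_mean, size=(len(circ_ids), len(samples)))
    frame = pd.DataFrame(counts, index=circ_ids, columns=samples)
    if artifact_ids:
        art = _nb_sample(
            rng,
            np.full((len(artifact_ids), len(samples)), cfg.artifact_mean),
            np.full((len(artifact_ids), 1), 0.3),
        )
        frame.loc[artifact_ids] = art
    lib = np.exp(rng.normal(cfg.libsize_log_mean, cfg.libsize_log_sd, len(samples)))
    meta = pd.DataFrame(
        {"library_size": np.round(lib).astype(np.int64), "cohort_tag": "polyA"},
        index=pd.Index(samples, name="sample_id"),
    )
    return frame, meta


# ---------------------------------------------------------------------------
# clinical and drugs
# ---------------------------------------------------------------------------

CR_RATE = {"Favorable": 0.75, "Intermediate": 0.60, "Adverse": 0.45}
MUTATION_RATE = {"mut_FLT3": 0.25, "mut_NPM1": 0.30, "mut_TP53": 0.10}


def simulate_clinical(
    cfg: SimConfig,
    groups: pd.Series,
    high_indicator: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clinical table with exponential proportional-hazards survival.

    hazard = h0 * exp(beta * high); independent exponential censoring tuned to
    the configured censoring fraction (rate 0 = none, rate 1 = everyone
    censored at their drawn time).
    """
    ids = groups.index
    n = len(ids)
    beta = cfg.prognostic_log_hr
    high = high_indicator.reindex(ids).fillna(0).to_numpy(dtype=float)
    hazard = cfg.baseline_hazard * np.exp(beta * high)
    t_event = rng.exponential(1.0 / hazard)
    c = cfg.censoring_rate
    if c >= 1.0:
        os_time, os_event = t_event, np.zeros(n, dtype=int)
    elif c <= 0.0:
        os_time, os_event = t_event, np.ones(n, dtype=int)
    else:
        cens_rate = cfg.baseline_hazard * c / (1.0 - c)
        t_cens = rng.exponential(1.0 / cens_rate, size=n)
        os_event = (t_event <= t_cens).astype(int)
        os_time = np.minimum(t_event, t_cens)
    cr_p = groups.map(CR_RATE).to_numpy(dtype=float)
    clinical = pd.DataFrame(
        {
            "os_time": np.round(os_time, 3),
            "os_event": os_event,
            "risk_group": groups.to_numpy(),
            "molecular_subtype": rng.choice(
                ["NPM1", "p53C", "Splice", "Other"], size=n, p=[0.25, 0.23, 0.18, 0.34]
            ),
            "cr_status": (rng.uniform(size=n) < cr_p).astype(int),
            "age": np.clip(np.round(rng.normal(65, 12, n), 1), 18, 95),
            "sex": rng.choice(["M", "F"], size=n, p=[0.55, 0.45]),
        },
        index=ids,
    )
    for mut, rate in MUTATION_RATE.items():
        clinical[mut] = (rng.uniform(size=n) < rate).astype(int)
    return clinical


def simulate_drug_and_validation(
    cfg: SimConfig,
    high_indicator: pd.Series,
    signature_genes: pd.DataFrame,
    gene_ids: list[str],
    rng: np.random.Generator,
):
    """Discovery DSS matrix plus a validation bundle (expression + AUC responses).

    Discovery: DSS = baseline + effect * high + noise for planted hit drugs
    (higher DSS = better response, so hits favor the high group). Validation:
    latent high labels are redrawn; gene expression (log2 CPM scale) shares the
    planted signature directions plus an additive per-gene batch shift; AUC
    responses carry the sign-flipped effect (lower AUC = better response).
    """
    drug_names = [f"drug{i:03d}" for i in range(cfg.n_drugs)]
    hit_drugs = drug_names[: cfg.n_drug_hits]
    patients = list(high_indicator.index[: cfg.n_drug_patients])
    high = high_indicator.loc[patients].to_numpy(dtype=float)
    base = rng.normal(cfg.drug_baseline_mean, cfg.drug_baseline_sd, cfg.n_drugs)
    dss = base[None, :] + rng.normal(0, cfg.drug_noise_sd, (len(patients), cfg.n_drugs))
    for j, d in enumerate(drug_names):
        if d in hit_drugs:
            dss[:, j] += cfg.drug_effect * high
    drugs = DrugResponseMatrix(
        pd.DataFrame(dss, index=patients, columns=drug_names), "higher_better"
    )

    v_ids = [f"V{i:04d}" for i in range(cfg.n_validation_patients)]
    v_high = (rng.uniform(size=len(v_ids)) < 0.5).astype(float)
    base_expr = rng.normal(5.0, 1.5, len(gene_ids))
    batch = rng.normal(0.0, cfg.batch_shift_sd, len(gene_ids))
    expr = (
        base_expr[:, None]
        + batch[:, None]
        + rng.normal(0, cfg.validation_noise_sd, (len(gene_ids), len(v_ids)))
    )
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for _, row in signature_genes.iterrows():
        gi = gene_pos[row["gene_id"]]
        expr[gi] += row["direction"] * cfg.signature_log2fc * v_high
    validation_expr = pd.DataFrame(expr, index=gene_ids, columns=v_ids)

    auc_base = rng.normal(100.0, 10.0, cfg.n_drugs)
    auc = auc_base[None, :] + rng.normal(0, cfg.drug_noise_sd * 2, (len(v_ids), cfg.n_drugs))
    for j, d in enumerate(drug_names):
        if d in hit_drugs:
            auc[:, j] -= 2.0 * cfg.drug_effect * v_high  # better (lower) AUC when high
    validation_drugs = DrugResponseMatrix(
        pd.DataFrame(auc, index=v_ids, columns=drug_names), "lower_better"
    )
    truth_patients = pd.DataFrame(
        {"high_latent": v_high.astype(int)}, index=pd.Index(v_ids, name="sample_id")
    )
    hit_table = pd.DataFrame(
        {"drug": hit_drugs, "effect": cfg.drug_effect, "favored": "high"}
    )
    return drugs, validation_expr, validation_drugs, truth_patients, hit_table


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate_cohort(cfg: SimConfig | None = None, seed: int | None = None) -> CohortBundle:
    """Generate a full synthetic study from a master seed.

    Independent child RNG streams per component: annotation, circ counts,
    tools, poly-A, clinical, genes, drugs.
    """
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_ann, rng_counts, rng_tools, rng_polya, rng_clin, rng_genes, rng_drugs, rng_misc = (
        np.random.default_rng(s) for s in streams
    )

    annotation, gtf_lines, gene_records = _simulate_annotation(cfg, rng_ann)
    circ_ids, host_gene = _simulate_circ_universe(cfg, gene_records, rng_ann)

    # patient structure
    aml_ids = [f"P{i:04d}" for i in range(cfg.n_patients)]
    ctrl_ids = [f"C{i:04d}" for i in range(cfg.n_controls)]
    props = [cfg.group_proportions[g] for g in GROUPS]
    groups = pd.Series(
        rng_clin.choice(GROUPS, size=cfg.n_patients, p=props), index=aml_ids, name="risk_group"
    )

    # planted feature sets (disjoint by construction)
    order = rng_misc.permutation(cfg.n_circ)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        sel = [circ_ids[i] for i in order[cursor : cursor + n]]
        cursor += n
        return sel

    de_ids = take(cfg.n_de)
    subgroup_ids = take(cfg.n_subgroup)
    veto_ids = take(cfg.n_subgroup_vetoed)
    artifact_ids = take(cfg.n_artifacts)

    baseline = np.exp(rng_counts.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_circ))
    dispersion = np.exp(
        rng_counts.normal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, cfg.n_circ)
    )
    base_s = pd.Series(baseline, index=circ_ids)
    disp_s = pd.Series(dispersion, index=circ_ids)

    # prognostic circ: needs a workable median split, so pick among mid-expressed
    candidates = base_s[(base_s > 2.0) & (base_s < 20.0)].index
    candidates = [c for c in candidates if c not in set(de_ids + subgroup_ids + veto_ids + artifact_ids)]
    prognostic_id = candidates[0] if cfg.n_prognostic > 0 and candidates else None

    # fold matrix over AML + control samples
    all_ids = aml_ids + ctrl_ids
    fold = np.ones((cfg.n_circ, len(all_ids)))
    pos = {c: i for i, c in enumerate(circ_ids)}
    is_aml = np.array([s in set(aml_ids) for s in all_ids])
    half = cfg.n_de // 2
    for k, cid in enumerate(de_ids):
        lfc = cfg.de_log2fc if k < half else -cfg.de_log2fc
        fold[pos[cid], is_aml] = 2.0 ** lfc
    in_sub = np.array([s in set(groups.index[groups == cfg.subgroup_group]) for s in all_ids])
    for cid in subgroup_ids + veto_ids:
        fold[pos[cid], in_sub] = 2.0 ** cfg.subgroup_log2_shift

    lib = np.exp(rng_counts.normal(cfg.libsize_log_mean, cfg.libsize_log_sd, len(all_ids)))
    circ_counts, meta = simulate_circ_counts(
        cfg,
        rng_counts,
        fold=fold,
        sample_ids=all_ids,
        library_sizes=lib,
        baseline_mean=baseline,
        dispersion=dispersion,
        feature_ids=circ_ids,
    )
    meta.loc[ctrl_ids, "cohort_tag"] = "HSPC"
    condition = meta["cohort_tag"].rename("condition")

    # tools and poly-A act on the AML side of the matrix
    aml_counts = circ_counts[aml_ids]
    forced = {prognostic_id} if prognostic_id is not None else set()
    tool_callsets, fp_ids = simulate_tool_callsets(aml_counts, cfg, rng_tools, always_detect=forced)
    polya_counts, polya_meta = simulate_polya_cohort(cfg, circ_ids, artifact_ids, rng_polya)

    # prognostic stratification on FPM over AML patients
    if prognostic_id is not None:
        fpm_prog = aml_counts.loc[prognostic_id] / meta.loc[aml_ids, "library_size"] * 1e6
        med = fpm_prog.median()
        high_indicator = (fpm_prog > med).astype(int)
    else:
        high_indicator = pd.Series(0, index=aml_ids)

    clinical = simulate_clinical(cfg, groups, high_indicator, rng_clin)

    # gene counts for AML patients: signature genes follow high/low, veto hosts co-shift
    gene_ids = [r[0] for r in gene_records]
    gene_base = np.exp(rng_genes.normal(cfg.gene_log_mean, cfg.gene_log_sd, len(gene_ids)))
    gene_fold = np.ones((len(gene_ids), cfg.n_patients))
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    veto_hosts = sorted({host_gene[c] for c in veto_ids if pd.notna(host_gene[c])})
    in_sub_aml = groups.to_numpy() == cfg.subgroup_group
    for gid in veto_hosts:
        gene_fold[gene_pos[gid], in_sub_aml] = 2.0 ** cfg.subgroup_log2_shift
    excluded = set(veto_hosts)
    sig_pool = [g for g in gene_ids if g not in excluded]
    sig_sel = list(rng_genes.choice(sig_pool, size=cfg.n_signature_genes, replace=False))
    sig_dirs = np.where(rng_genes.uniform(size=cfg.n_signature_genes) < 0.5, 1, -1)
    hi = high_indicator.to_numpy(dtype=float)
    for gid, d in zip(sig_sel, sig_dirs):
        gene_fold[gene_pos[gid]] *= 2.0 ** (d * cfg.signature_log2fc * hi)
    gene_mean = gene_base[:, None] * (lib[: cfg.n_patients] / np.median(lib))[None, :] * gene_fold
    gene_counts = pd.DataFrame(
        _nb_sample(rng_genes, gene_mean, np.full((len(gene_ids), 1), cfg.gene_dispersion)),
        index=gene_ids,
        columns=aml_ids,
    )
    signature_genes = pd.DataFrame(
        {"gene_id": sig_sel, "direction": sig_dirs, "log2fc": sig_dirs * cfg.signature_log2fc}
    )

    drugs, validation_expr, validation_drugs, v_truth, hit_table = simulate_drug_and_validation(
        cfg, high_indicator, signature_genes, gene_ids, rng_drugs
    )

    feature_rows = (
        [{"norm_id": c, "role": "de",
          "effect": cfg.de_log2fc if k < half else -cfg.de_log2fc,
          "group": ""} for k, c in enumerate(de_ids)]
        + [{"norm_id": c, "role": "subgroup", "effect": cfg.subgroup_log2_shift,
            "group": cfg.subgroup_group} for c in subgroup_ids]
        + [{"norm_id": c, "role": "subgroup_vetoed", "effect": cfg.subgroup_log2_shift,
            "group": cfg.subgroup_group} for c in veto_ids]
        + [{"norm_id": c, "role": "artifact", "effect": np.nan, "group": ""} for c in artifact_ids]
    )
    if prognostic_id is not None:
        feature_rows.append(
            {"norm_id": prognostic_id, "role": "prognostic",
             "effect": cfg.prognostic_log_hr, "group": ""}
        )
    for tool, fps in fp_ids.items():
        feature_rows += [
            {"norm_id": c, "role": f"tool_fp_{tool}", "effect": np.nan, "group": ""} for c in fps
        ]
    truth = SimTruth(
        features=pd.DataFrame(feature_rows),
        patients=pd.DataFrame(
            {"risk_group": groups, "high_prognostic": high_indicator}
        ).rename_axis("sample_id"),
        validation_patients=v_truth,
        signature_genes=signature_genes,
        drug_hits=hit_table,
        artifact_ids=artifact_ids,
        prognostic_id=prognostic_id,
        baseline_mean=base_s,
        dispersion=disp_s,
    )
    return CohortBundle(
        config=cfg,
        meta=meta,
        circ_counts=circ_counts,
        condition=condition,
        tool_callsets=tool_callsets,
        polya_counts=polya_counts,
        polya_meta=polya_meta,
        gene_counts=gene_counts,
        clinical=clinical,
        annotation=annotation,
        gtf_lines=gtf_lines,
        host_gene=host_gene,
        drugs=drugs,
        validation_expr=validation_expr,
        validation_drugs=validation_drugs,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> dict:
    """Write every simulated table in the formats the readers expect; returns a manifest."""
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_sample_meta(bundle.meta, outdir / "meta.tsv")
    cio.write_count_matrix(bundle.circ_counts, outdir / "circ_counts.tsv")
    for tool, frame in bundle.tool_callsets.items():
        cio.write_count_matrix(frame, outdir / f"tool_{tool}.tsv")
    cio.write_count_matrix(bundle.polya_counts, outdir / "polya_counts.tsv")
    cio.write_sample_meta(bundle.polya_meta, outdir / "polya_meta.tsv")
    cio.write_count_matrix(bundle.gene_counts, outdir / "gene_counts.tsv")
    cio.write_clinical_table(bundle.clinical, outdir / "clinical.tsv")
    (outdir / "annotation.gtf").write_text("\n".join(bundle.gtf_lines) + "\n")
    bundle.host_gene.rename_axis("norm_id").to_frame().reset_index().to_csv(
        outdir / "host_gene.tsv", sep="\t", index=False
    )
    cio.write_drug_matrix(bundle.drugs, outdir / "drug_dss.tsv")
    cio.write_real_matrix(bundle.validation_expr, outdir / "validation_expr.tsv")
    cio.write_drug_matrix(bundle.validation_drugs, outdir / "validation_auc.tsv")
    bundle.truth.features.to_csv(outdir / "truth_features.tsv", sep="\t", index=False)
    bundle.truth.patients.reset_index().to_csv(outdir / "truth_patients.tsv", sep="\t", index=False)
    bundle.truth.validation_patients.reset_index().to_csv(
        outdir / "truth_validation_patients.tsv", sep="\t", index=False
    )
    bundle.truth.signature_genes.to_csv(outdir / "truth_signature_genes.tsv", sep="\t", index=False)
    bundle.truth.drug_hits.to_csv(outdir / "truth_drug_hits.tsv", sep="\t", index=False)
    pd.Series(bundle.annotation.chrom_lengths, name="length").rename_axis("chrom").reset_index().to_csv(
        outdir / "chrom_lengths.tsv", sep="\t", index=False
    )
    cfg_json = dataclasses.asdict(bundle.config)
    cfg_json = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg_json.items()}
    (outdir / "simconfig.json").write_text(json.dumps(cfg_json, indent=2, default=float))
    return {"outdir": str(outdir), "n_circ": int(bundle.circ_counts.shape[0]),
            "n_samples": int(bundle.circ_counts.shape[1])}
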