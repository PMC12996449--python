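"""Stage orchestration: simulate -> catalog -> de -> subgroup -> survive -> drugs -> transfer.

Each stage is a function that reads its inputs from the run directory, writes
its result tables as TSV and returns a summary dict; :func:`run_pipeline`
chains them and writes a machine-readable manifest (thresholds, seed, record
counts, stage status). Results are deterministic given (config, seed) and
independent of input row/column order (inputs are canonicalized by sorting).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from . import diffexp, io, pharmaco, subgroup, survival
from .config import load_config, require
from .errors import AnalysisError, ConfigurationError
from .simulate import SimConfig, simulate_cohort, write_bundle

log = logging.getLogger("circscape")


def _stage_logger(stage: str, n_in: int, n_out: int, t0: float) -> None:
    log.info("stage=%s records_in=%d records_out=%d elapsed=%.2fs", stage, n_in, n_out, time.time() - t0)


def _read_inputs(outdir: Path):
    meta = io.read_sample_meta(outdir / "meta.tsv")
    counts = io.read_count_matrix(outdir / "circ_counts.tsv", meta)
    # canonical order: sorted features and samples
    counts = counts.sort_index().sort_index(axis=1)
    return meta, counts


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: dict, outdir: Path) -> dict:
    t0 = time.time()
    sim_overrides = dict(cfg.get("simulate") or {})
    sim_cfg = SimConfig(**{**sim_overrides, "seed": int(cfg["seed"])})
    bundle = simulate_cohort(sim_cfg)
    write_bundle(bundle, outdir)
    _stage_logger("simulate", 0, bundle.circ_counts.shape[0], t0)
    return {"n_circ": int(bundle.circ_counts.shape[0]),
            "n_samples": int(bundle.circ_counts.shape[1])}


def stage_catalog(cfg: dict, outdir: Path) -> dict:
    t0 = time.time()
    th = cfg["thresholds"]
    meta, counts = _read_inputs(outdir)
    aml = sorted(meta.index[meta["cohort_tag"] == "AML"])
    aml_counts = counts[aml]
    callsets = {}
    for path in sorted(outdir.glob("tool_*.tsv")):
        callsets[path.stem] = io.read_count_matrix(path)
    consensus = cat.consensus_calls([frame.index for frame in callsets.values()])
    kept = cat.prevalence_filter(
        aml_counts.loc[sorted(consensus & set(aml_counts.index))],
        min_reads=th["min_reads"], frac=th["prevalence_frac"],
    )
    polya = io.read_count_matrix(outdir / "polya_counts.tsv")
    tn = cat.build_true_negative_set(polya, min_reads=th["min_reads"], frac=th["tn_frac"])
    final_ids = cat.exclude_true_negatives(set(kept.index), tn)
    chrom_lengths = pd.read_csv(outdir / "chrom_lengths.tsv", sep="\t").set_index("chrom")
    chrom_lengths.index = chrom_lengths.index.astype(str)
    ann = io.read_annotation_gtf(outdir / "annotation.gtf", chrom_lengths["length"].to_dict())
    catalog = cat.build_catalog(final_ids, ann)
    fpm = cat.fpm_normalize(counts.loc[catalog.index], meta)
    summaries = cat.catalog_summaries(
        catalog, aml_counts, chrom_lengths["length"].to_dict(),
        expressed_min_reads=th["expressed_min_reads"],
    )
    catalog.reset_index().to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    io.write_bed(catalog, outdir / "catalog.bed")
    io.write_real_matrix(fpm, outdir / "fpm.tsv")
    pd.Series(sorted(tn), name="norm_id").to_csv(outdir / "true_negatives.tsv", sep="\t", index=False)
    for name, frame in summaries.items():
        frame.to_csv(outdir / f"summary_{name}.tsv", sep="\t", index=False)
    _stage_logger("catalog", counts.shape[0], catalog.shape[0], t0)
    return {
        "n_consensus": len(consensus),
        "n_prevalence": int(kept.shape[0]),
        "n_true_negative": len(tn),
        "n_catalog": int(catalog.shape[0]),
        "chrom_length_pearson_r": summaries["per_chromosome"].attrs.get("pearson_r"),
    }


def stage_de(cfg: dict, outdir: Path) -> dict:
    t0 = time.time()
    th = cfg["thresholds"]
    meta, counts = _read_inputs(outdir)
    catalog = pd.read_csv(outdir / "catalog.tsv", sep="\t", index_col="norm_id")
    sub = counts.loc[catalog.index.sort_values()]
    condition = (meta.loc[sub.columns, "cohort_tag"] == "AML").astype(int)
    de = diffexp.nb_wald_de(sub, condition.to_numpy(),
                            fdr_cut=th["de_fdr"], lfc_cut=th["de_lfc"])
    de.reset_index(names="norm_id").to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    # ranked-recall against the planted differential set when truth is available
    recall_summary = {}
    truth_path = outdir / "truth_features.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        reference = set(truth.loc[truth["role"] == "de", "norm_id"]) & set(de.index)
        if reference:
            curve = diffexp.recall_enrichment_curve(
                diffexp.rank_de_results(de), reference, set(de.index)
            )
            curve.to_csv(outdir / "recall_curve.tsv", sep="\t", index=False)
            k = min(500, len(de))
            recall_summary = {"recall_at_500": float(curve.loc[curve["k"] == k, "recall"].iloc[0]),
                              "recall_p_at_500": float(curve.loc[curve["k"] == k, "p"].iloc[0])}
    n_sig = int((de["category"] == "FDR & Log2FC").sum())
    _stage_logger("de", sub.shape[0], n_sig, t0)
    return {"n_tested": int(de["p"].notna().sum()), "n_de": n_sig, **recall_summary}


def stage_subgroup(cfg: dict, outdir: Path) -> dict:
    t0 = time.time()
    th = cfg["thresholds"]
    meta, _ = _read_inputs(outdir)
    fpm = io.read_real_matrix(outdir / "fpm.tsv").sort_index()
    clinical = io.read_clinical_table(outdir / "clinical.tsv", meta)
    gene_counts = io.read_count_matrix(outdir / "gene_counts.tsv")
    catalog = pd.read_csv(outdir / "catalog.tsv", sep="\t", index_col="norm_id")
    aml = clinical.index.intersection(fpm.columns)
    res = subgroup.find_subgroup_specific(
        fpm[sorted(aml)], gene_counts, clinical.loc[sorted(aml), "risk_group"],
        catalog["host_gene"],
        t1_fdr_cut=th["t1_fdr"], t2_p_cut=th["t2_p"], host_p_cut=th["host_p"],
    )
    res.to_csv(outdir / "subgroup_specific.tsv", sep="\t", index=False)
    per_group = res[res["verdict"]].groupby("group").size().to_dict()
    _stage_logger("subgroup", fpm.shape[0], int(res["verdict"].sum()), t0)
    return {"n_flagged": int(res["verdict"].sum()),
            "per_group": {str(k): int(v) for k, v in per_group.items()}}


def stage_survive(cfg: dict, outdir: Path) -> dict:
    t0 = time.time()
    th = cfg["thresholds"]
    meta, _ = _read_inputs(outdir)
    fpm = io.read_real_matrix(outdir / "fpm.tsv").sort_index()
    clinical = io.read_clinical_table(outdir / "clinical.tsv", meta)
    aml = sorted(clinical.index.intersection(fpm.columns))
    clinical = clinical.loc[aml]
    screens = []
    main = survival.survival_screen(fpm[aml], clinical, min_subset=th["screen_min_subset"])
    screens.append(main.reset_index())
    for col, tag in (("risk_group", "risk"), ("molecular_subtype", "subtype")):
        for level in sorted(clinical[col].dropna().unique()):
            ids = clinical.index[clinical[col] == level]
            try:
                scr = survival.survival_screen(
                    fpm[aml], clinical, subset_filter=list(ids),
                    min_subset=th["screen_min_subset"], subset_name=f"{tag}:{level}",
                )
                screens.append(scr.reset_index())
            except AnalysisError as exc:
                log.warning("screen skipped: %s", exc)
    all_screens = pd.concat(screens, ignore_index=True)
    all_screens.to_csv(outdir / "survival_screens.tsv", sep="\t", index=False)
    # multivariable adjustment of the top cohort-wide hit
    top = main.sort_values("p").head(1)
    cox_summary = {}
    if len(top):
        top_id = top.index[0]
        labels = survival.stratify_by_median(fpm.loc[top_id, aml])
        covs = [c for c in cfg["cox_covariates"] if c in clinical.columns]
        cox = survival.cox_ph_fit(clinical, labels, covs)
        cox.reset_index().to_csv(outdir / "cox_top_hit.tsv", sep="\t", index=False)
        assoc = survival.group_clinical_association(
            pd.Series(labels, index=aml), clinical
        )
        assoc.to_csv(outdir / "top_hit_clinical_association.tsv", sep="\t", index=False)
        cox_summary = {"top_circ": str(top_id), "top_p": float(top["p"].iloc[0]),
                       "cox_circ_p": float(cox.loc["circ_high", "p"])}
    _stage_logger("survive", fpm.shape[0], len(all_screens), t0)
    return {"n_screens": int(all_screens["subset"].nunique()),
            "n_risk_hits": int(((all_screens["subset"].str.startswith("risk")) &
                                (all_screens["FDR"] < th["screen_fdr_risk"])).sum()),
            **cox_summary}


def stage_drugs(cfg: dict, outdir: Path) -> dict:
    t0 = time.time()
    th = cfg["thresholds"]
    meta, _ = _read_inputs(outdir)
    fpm = io.read_real_matrix(outdir / "fpm.tsv")
    drugs = io.read_drug_matrix(outdir / "drug_dss.tsv", "higher_better")
    screens = pd.read_csv(outdir / "survival_screens.tsv", sep="\t")
    top = screens[screens["subset"] == "all"].sort_values("p").iloc[0]
    # stratify on the cohort-wide median, then restrict to patients with drug data
    aml = sorted(set(meta.index[meta["cohort_tag"] == "AML"]) & set(fpm.columns))
    cohort_labels = pd.Series(
        survival.stratify_by_median(fpm.loc[top["norm_id"], aml]), index=aml
    )
    ids = sorted(set(drugs.patients) & set(fpm.columns))
    label_s = cohort_labels.loc[ids]
    assoc = pharmaco.drug_group_association(
        drugs, label_s, p_cut=th["drug_p"], median_diff_cut=th["drug_median_diff"]
    )
    assoc.reset_index().to_csv(outdir / "drug_associations.tsv", sep="\t", index=False)
    _stage_logger("drugs", len(drugs.drugs), int(assoc["significant"].sum()), t0)
    return {"top_circ": str(top["norm_id"]),
            "n_drugs": int(len(drugs.drugs)),
            "n_significant": int(assoc["significant"].sum())}


def stage_transfer(cfg: dict, outdir: Path) -> dict:
    t0 = time.time()
    th = cfg["thresholds"]
    meta, _ = _read_inputs(outdir)
    fpm = io.read_real_matrix(outdir / "fpm.tsv")
    gene_counts = io.read_count_matrix(outdir / "gene_counts.tsv")
    screens = pd.read_csv(outdir / "survival_screens.tsv", sep="\t")
    top_id = screens[screens["subset"] == "all"].sort_values("p")["norm_id"].iloc[0]
    aml = sorted(set(gene_counts.columns) & set(fpm.columns))
    labels = pd.Series(survival.stratify_by_median(fpm.loc[top_id, aml]), index=aml)
    try:
        signature = pharmaco.build_transfer_signature(
            gene_counts[aml], labels, fdr_cut=th["signature_fdr"], lfc_cut=th["signature_lfc"]
        )
    except AnalysisError as exc:
        # no transferable signature for this stratification: flag and emit empty tables
        log.warning("transfer stage: %s", exc)
        for name, cols in (
            ("transfer_signature.tsv", ["gene_id", "direction"]),
            ("transfer_labels.tsv", ["patient_id", "votes_high", "votes_low", "abstain", "label"]),
            ("drug_validation.tsv", ["drug", "cohort", "p", "direction", "verdict"]),
        ):
            pd.DataFrame(columns=cols).to_csv(outdir / name, sep="\t", index=False)
        return {"n_signature_genes": 0, "n_assigned": 0, "n_validated": 0,
                "n_candidates": 0, "note": "empty signature"}
    validation_expr = io.read_real_matrix(outdir / "validation_expr.tsv")
    assigned = pharmaco.assign_transfer_labels(signature, validation_expr)
    assigned.reset_index(names="patient_id").to_csv(outdir / "transfer_labels.tsv", sep="\t", index=False)
    signature.directions.rename("direction").rename_axis("gene_id").reset_index().to_csv(
        outdir / "transfer_signature.tsv", sep="\t", index=False
    )
    validation_auc = io.read_drug_matrix(outdir / "validation_auc.tsv", "lower_better")
    assoc = pd.read_csv(outdir / "drug_associations.tsv", sep="\t", index_col="drug")
    verdicts = []
    for drug, row in assoc[assoc["significant"].fillna(False)].iterrows():
        try:
            verdicts.append(
                pharmaco.validate_drug_association(
                    assigned, validation_auc, drug, str(row["favored"]), p_cut=th["drug_p"]
                )
            )
        except AnalysisError as exc:
            log.warning("validation skipped for %s: %s", drug, exc)
    verdict_df = pd.DataFrame(verdicts)
    verdict_df.to_csv(outdir / "drug_validation.tsv", sep="\t", index=False)
    n_validated = int((verdict_df["verdict"] == "validated").sum()) if len(verdict_df) else 0
    _stage_logger("transfer", len(signature), n_validated, t0)
    return {"n_signature_genes": len(signature),
            "n_assigned": int((assigned["label"] != "unassigned").sum()),
            "n_validated": n_validated,
            "n_candidates": int(len(verdict_df))}


def stage_report(cfg: dict, outdir: Path, manifest: dict) -> dict:
    rows = []
    for stage, info in manifest.get("stages", {}).items():
        for key, val in info.items():
            if isinstance(val, (int, float, str)):
                rows.append({"stage": stage, "metric": key, "value": val})
    pd.DataFrame(rows).to_csv(outdir / "report.tsv", sep="\t", index=False)
    return {"n_metrics": len(rows)}


STAGES = ("simulate", "catalog", "de", "subgroup", "survive", "drugs", "transfer")


def run_pipeline(config: dict | str | Path | None = None, seed: int | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run every stage on a config (path or dict); returns the manifest.

    The run is deterministic given (config, seed): all randomness flows from
    the seed through the simulator's child streams, and all stage inputs are
    canonicalized by sorting before analysis.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = load_config(None, overrides=config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    out = Path(require(cfg, "outdir"))
    out.mkdir(parents=True, exist_ok=True)
    if cfg.get("simulate") is None and not cfg.get("inputs"):
        raise ConfigurationError("config needs a 'simulate' block or an 'inputs' block")
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)
    manifest: dict = {
        "seed": int(cfg["seed"]),
        "thresholds": cfg["thresholds"],
        "stages": {},
        "status": "ok",
    }
    stage_funcs = {
        "simulate": stage_simulate, "catalog": stage_catalog, "de": stage_de,
        "subgroup": stage_subgroup, "survive": stage_survive,
        "drugs": stage_drugs, "transfer": stage_transfer,
    }
    try:
        for stage in STAGES:
            if stage == "simulate" and cfg.get("inputs"):
                continue
            manifest["stages"][stage] = stage_funcs[stage](cfg, out)
    except Exception as exc:
        manifest["status"] = f"failed at {stage}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest["stages"]["report"] = stage_report(cfg, out, manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
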