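"""Pipeline configuration: YAML file with documented defaults for every threshold."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: Every analysis threshold, named, with its default. The catalog thresholds
#: implement the strict "more than" readings (support > min_reads; poly-A
#: artifact support in > tn_frac of samples).
DEFAULT_THRESHOLDS = {
    "min_reads": 4,              # BSJ read support, strict 'more than'
    "prevalence_frac": 0.01,     # fraction of patients for the catalog filter
    "tn_frac": 0.25,             # poly-A artifact prevalence, strict 'more than'
    "expressed_min_reads": 1,    # per-patient 'expressed' rule in summaries
    "de_fdr": 0.05,
    "de_lfc": 1.0,
    "t1_fdr": 0.01,
    "t2_p": 0.05,
    "host_p": 0.05,
    "screen_min_subset": 20,
    "screen_fdr_risk": 0.2,      # reporting threshold for risk-group screens
    "screen_fdr_subtype": 0.1,   # reporting threshold for subtype screens
    "drug_p": 0.05,
    "drug_median_diff": 1.0,
    "signature_fdr": 0.05,
    "signature_lfc": 1.0,
}

DEFAULT_CONFIG = {
    "outdir": None,
    "seed": 0,
    "simulate": {},          # SimConfig overrides; presence triggers simulation
    "inputs": None,          # alternatively: paths to pre-existing tables
    "thresholds": DEFAULT_THRESHOLDS,
    "cox_covariates": ["age", "sex", "mut_FLT3", "mut_NPM1", "mut_TP53", "risk_group"],
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config and merge it over the defaults (two levels deep)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    loaded = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
    for source in (loaded, overrides or {}):
        for key, value in source.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def require(cfg: dict, key: str):
    value = cfg.get(key)
    if value is None:
        raise ConfigurationError(f"missing required configuration key: {key!r}")
    return value
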