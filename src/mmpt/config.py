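"""Pipeline configuration: defaults, validation, normalization."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "validate_config", "load_config"]

# Defaults mirror the published analysis parameters.
DEFAULTS: dict = {
    "seed": 0,
    "phenotype": {
        "min_confidence": 0.6,
        "big_small_diameter_cutoff_um": 11.0,
        "contact_radius_um": 15.0,
    },
    "score": {
        "reporting_concentration": "middle",
        "qc_concordance_threshold": 0.5,
        "lasso_training_correlation_cutoff": 0.8,
        "lasso_min_training_samples": 10,
        "elasticnet_l1_ratio": 0.5,
        "n_lambdas": 100,
        "cv_folds": 10,
    },
    "phenogroup": {
        "n_features": 100,
        "k": 15,
        "knn_k": 15,
        "n_groups": 3,
        "similarity": "pearson",
        "per_sample_training_cells": 1200,
    },
    "proteome": {
        "low_abundance_quantile": 0.05,
        "p_cut": 0.05,
        "fc_cut": 0.3,
        "network_rho_cut": 0.585,
        "network_p_cut": 0.05,
        "min_pairs": 10,
        "fdr": "storey",
    },
    "scrna": {
        "min_umi": 300,
        "max_mito_fraction": 0.5,
        "big_like_rule": "median",
        "fixed_ratio": 5.0,
    },
    "outcome": {
        "anova_p_cut": 0.01,
        "n_cv": 100,
        "holdout_frac": 0.2,
        "ipcy_match_mode": "subset",
    },
    "stages": {
        "simulate": True, "phenotype": True, "score": True,
        "phenogroup": True, "proteome": True, "network": True,
        "scrna": True, "cytokines": True, "outcome": True,
    },
}

_RANGES = {
    ("phenotype", "min_confidence"): (0.0, 1.0),
    ("phenotype", "contact_radius_um"): (0.0, float("inf")),
    ("phenogroup", "k"): (2, 10_000),
    ("phenogroup", "n_groups"): (2, 10_000),
    ("proteome", "p_cut"): (0.0, 1.0),
    ("proteome", "network_p_cut"): (0.0, 1.0),
    ("outcome", "anova_p_cut"): (0.0, 1.0),
    ("score", "lasso_training_correlation_cutoff"): (-1.0, 1.0),
}


def validate_config(raw: dict | None) -> tuple[dict, list[str], list[str]]:
    """Fill defaults and range-check; returns (config, errors, warnings).

    Unknown keys are preserved under ``extras`` with a warning.
    """
    cfg = copy.deepcopy(DEFAULTS)
    errors: list[str] = []
    warns: list[str] = []
    extras: dict = {}
    for section, value in (raw or {}).items():
        if section not in cfg:
            warns.append(f"unknown key: {section}")
            extras[section] = value
            continue
        if not isinstance(value, dict):
            cfg[section] = value
            continue
        for key, v in value.items():
            if key not in cfg[section]:
                warns.append(f"unknown key: {section}.{key}")
                extras.setdefault(section, {})[key] = v
            else:
                cfg[section][key] = v
    for (section, key), (lo, hi) in _RANGES.items():
        v = cfg[section][key]
        if not isinstance(v, (int, float)) or not (lo <= v <= hi):
            errors.append(f"{section}.{key}={v!r} outside [{lo}, {hi}]")
    for key in ("p_cut", "network_p_cut"):
        v = cfg["proteome"][key]
        if isinstance(v, (int, float)) and not (0 < v < 1):
            errors.append(f"proteome.{key}={v!r} must be in (0, 1)")
    if extras:
        cfg["extras"] = extras
    return cfg, errors, warns


def load_config(path: str | Path | None) -> dict:
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    cfg, errors, warns = validate_config(raw)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))
    return cfg
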