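"""RCF / PCY drug-response scoring, replicate QC, imputation, predictors.

The relative cell fraction (RCF) of a target population in a treated
well is its fraction of all cells divided by the mean fraction in the
matched control wells (isotype controls for antibody-containing
treatments, DMSO otherwise). The PCY score is the zero-centered
replicate mean, 1 - mean(RCF): positive means on-target depletion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import ElasticNetCV, LassoCV
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

__all__ = [
    "well_fractions",
    "compute_rcf",
    "rcf_table",
    "pcy_scores",
    "replicate_qc",
    "lasso_impute",
    "elasticnet_predictors",
    "PredictorRanking",
]

ANTIBODY_KINDS = {"antibody"}


def _target_mask(cells: pd.DataFrame, target_class: str) -> pd.Series:
    if target_class == "myeloma":
        return (cells["cell_class"] == "plasma") & (
            cells["plasma_subtype"] == "myeloma")
    if target_class == "small":
        return (cells["cell_class"] == "plasma") & (
            cells["plasma_subtype"] == "small")
    return cells["cell_class"] == target_class


def well_fractions(cells: pd.DataFrame, target_class: str = "myeloma",
                   ) -> pd.DataFrame:
    """Per (sample, well): target-class fraction and total cell count."""
    cells = cells.copy()
    cells["_is_target"] = _target_mask(cells, target_class)
    out = (cells.groupby(["sample_id", "well_id"], sort=True)
           .agg(n_cells=("_is_target", "size"), n_target=("_is_target", "sum"))
           .reset_index())
    out["fraction"] = out["n_target"] / out["n_cells"]
    return out


def compute_rcf(well_fraction: float, control_fractions) -> float:
    """RCF = well fraction / mean control fraction (NaN if that mean is 0)."""
    ctrl = np.asarray(control_fractions, dtype=float)
    ctrl = ctrl[np.isfinite(ctrl)]
    if ctrl.size == 0:
        raise ValueError("no matched control wells")
    m = ctrl.mean()
    if m == 0:
        return float("nan")
    return float(well_fraction / m)


def _control_type_for(drug_class: str) -> str:
    return "isotype" if drug_class in ANTIBODY_KINDS else "dmso"


def rcf_table(cells: pd.DataFrame, layout: pd.DataFrame,
              target_class: str = "myeloma") -> pd.DataFrame:
    """Long table of per-well RCFs for every treated well of every sample."""
    frac = well_fractions(cells, target_class)
    merged = layout.merge(frac, on=["sample_id", "well_id"], how="inner")
    rows = []
    for sid, grp in merged.groupby("sample_id", sort=True):
        ctrl_means = {
            ct: grp.loc[grp["control_type"] == ct, "fraction"].mean()
            for ct in ("dmso", "isotype")}
        for rec in grp.itertuples(index=False):
            ct = (rec.control_type if rec.control_type != "none"
                  else _control_type_for(rec.drug_class))
            cm = ctrl_means.get(ct, np.nan)
            rcf = rec.fraction / cm if cm and np.isfinite(cm) and cm > 0 else np.nan
            rows.append({
                "sample_id": sid, "well_id": rec.well_id,
                "treatment": rec.treatment, "drug_class": rec.drug_class,
                "concentration_um": rec.concentration_um,
                "replicate": rec.replicate, "control_type": rec.control_type,
                "fraction": rec.fraction, "rcf": rcf,
            })
    return pd.DataFrame(rows)


def pcy_scores(cells: pd.DataFrame, layout: pd.DataFrame,
               target_class: str = "myeloma",
               reporting_concentration: str | float = "middle",
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Samples x treatments PCY matrix plus the long per-concentration table.

    PCY = 1 - mean(RCF over technical replicates), per concentration; the
    wide matrix reports the designated concentration (the middle tested
    one by default).
    """
    rcfs = rcf_table(cells, layout, target_class)
    treated = rcfs[rcfs["control_type"] == "none"]
    per_conc = (treated.groupby(["sample_id", "treatment", "concentration_um"])
                ["rcf"].agg(["mean", "count"]).reset_index())
    per_conc["pcy"] = 1.0 - per_conc["mean"]
    per_conc = per_conc.rename(columns={"count": "n_replicates"})

    def _report_conc(sub: pd.DataFrame) -> float:
        concs = np.sort(sub["concentration_um"].unique())
        if reporting_concentration == "middle":
            return concs[len(concs) // 2]
        if reporting_concentration == "mean":
            return np.nan  # sentinel: average over concentrations
        return float(reporting_concentration)

    rows = []
    for (sid, trt), sub in per_conc.groupby(["sample_id", "treatment"]):
        rc = _report_conc(sub)
        if np.isnan(rc):
            val = sub["pcy"].mean()
        else:
            sel = sub.loc[sub["concentration_um"] == rc, "pcy"]
            val = sel.iloc[0] if len(sel) else np.nan
        rows.append({"sample_id": sid, "treatment": trt, "pcy": val})
    wide = (pd.DataFrame(rows)
            .pivot(index="sample_id", columns="treatment", values="pcy"))
    wide.columns.name = None
    return wide, per_conc


def replicate_qc(cells: pd.DataFrame, layout: pd.DataFrame,
                 target_class: str = "myeloma",
                 concordance_threshold: float = 0.5) -> pd.DataFrame:
    """Per-sample replicate concordance of 1-RCF vectors.

    Replicate-wise response vectors (over treatment x concentration) are
    correlated pairwise (Pearson); the report carries the mean pairwise
    correlation and a flag for samples below threshold.
    """
    rcfs = rcf_table(cells, layout, target_class)
    treated = rcfs[rcfs["control_type"] == "none"].copy()
    treated["response"] = 1.0 - treated["rcf"]
    rows = []
    for sid, grp in treated.groupby("sample_id", sort=True):
        mat = grp.pivot_table(index=["treatment", "concentration_um"],
                              columns="replicate", values="response")
        reps = mat.columns
        if len(reps) < 2:
            warnings.warn(f"sample {sid}: single-replicate design, QC skipped")
            rows.append({"sample_id": sid, "concordance": np.nan,
                         "flagged": False, "n_replicates": len(reps)})
            continue
        cors = []
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                sub = mat.iloc[:, [i, j]].dropna()
                if len(sub) >= 3 and sub.std().min() > 0:
                    cors.append(float(sub.corr().iloc[0, 1]))
        conc = float(np.mean(cors)) if cors else np.nan
        rows.append({"sample_id": sid, "concordance": conc,
                     "flagged": bool(np.isfinite(conc)
                                     and conc < concordance_threshold),
                     "n_replicates": len(reps)})
    return pd.DataFrame(rows)


def _cv_lasso(X: np.ndarray, y: np.ndarray, seed: int, n_lambdas: int = 100,
              n_folds: int = 10, l1_ratio: float | None = None):
    n = len(y)
    folds = min(n_folds, n)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    if l1_ratio is None:
        model = LassoCV(alphas=n_lambdas, cv=cv, max_iter=50_000)
    else:
        model = ElasticNetCV(l1_ratio=l1_ratio, alphas=n_lambdas, cv=cv,
                             max_iter=50_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def lasso_impute(drug_matrix: pd.DataFrame,
                 predictors: pd.DataFrame | None = None, *,
                 min_training_samples: int = 10,
                 training_correlation_cutoff: float = 0.8,
                 seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute missing PCY entries by cross-validated LASSO.

    Per target treatment: a 100-point lambda scan in 10-fold CV on samples
    with measured responses, predictors being the other measured drug
    columns (or a supplied samples x features table, e.g. a proteome).
    Models whose training-set Pearson correlation between fitted and
    measured values falls below the cutoff impute nothing. Returns the
    filled matrix and a boolean mask of imputed entries; imputed values
    are for visualization/export only.
    """
    filled = drug_matrix.copy()
    mask = pd.DataFrame(False, index=drug_matrix.index,
                        columns=drug_matrix.columns)
    for col in drug_matrix.columns:
        missing = drug_matrix[col].isna()
        if not missing.any():
            continue
        if predictors is not None:
            X_all = predictors.reindex(drug_matrix.index)
        else:
            X_all = drug_matrix.drop(columns=[col])
        X_all = X_all.apply(lambda s: s.fillna(s.mean()))
        X_all = X_all.loc[:, X_all.std(ddof=0) > 0]
        if X_all.shape[1] == 0:
            continue
        train = ~missing
        n_train = int(train.sum())
        if n_train < min_training_samples:
            log.info("treatment %s: only %d measured samples, skipped",
                     col, n_train)
            continue
        X = X_all.loc[train].to_numpy(dtype=float)
        y = drug_matrix.loc[train, col].to_numpy(dtype=float)
        model = _cv_lasso(X, y, seed)
        fitted = model.predict(X)
        if np.std(fitted) == 0 or np.std(y) == 0:
            continue
        r = float(np.corrcoef(fitted, y)[0, 1])
        if not np.isfinite(r) or r < training_correlation_cutoff:
            log.info("treatment %s: training r=%.3f below cutoff, not imputed",
                     col, r if np.isfinite(r) else float("nan"))
            continue
        pred = model.predict(X_all.loc[missing].to_numpy(dtype=float))
        filled.loc[missing, col] = pred
        mask.loc[missing, col] = True
    return filled, mask


@dataclass
class PredictorRanking:
    treatment: str
    coefficients: pd.Series
    top3_positive: list[str] = field(default_factory=list)
    top3_negative: list[str] = field(default_factory=list)
    cv_lambda: float = float("nan")
    n_samples: int = 0


def elasticnet_predictors(proteome: pd.DataFrame, response: pd.Series, *,
                          l1_ratio: float = 0.5, min_samples: int = 15,
                          seed: int = 0) -> PredictorRanking:
    """Rank protein predictors of one drug response by elastic net.

    ``proteome`` is proteins x samples; missing protein values are mean-
    imputed per protein, constant rows dropped. The top-3 positive and
    negative coefficients at the deviance-minimizing lambda are reported.
    """
    name = str(response.name or "response")
    common = [s for s in response.index if s in proteome.columns
              and np.isfinite(response[s])]
    if len(common) < min_samples:
        raise ValueError(
            f"need >= {min_samples} complete sample pairs, got {len(common)}")
    X_df = proteome[common].T  # samples x proteins
    X_df = X_df.apply(lambda s: s.fillna(s.mean()))
    keep = X_df.std(ddof=0) > 0
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} constant protein columns dropped")
    X_df = X_df.loc[:, keep]
    y = response[common].to_numpy(dtype=float)
    model = _cv_lasso(X_df.to_numpy(dtype=float), y, seed, l1_ratio=l1_ratio)
    coefs = pd.Series(model.coef_, index=X_df.columns)
    nz = coefs[coefs != 0]
    top_pos = nz[nz > 0].sort_values(ascending=False).index[:3].tolist()
    top_neg = nz[nz < 0].sort_values().index[:3].tolist()
    return PredictorRanking(name, coefs, top_pos, top_neg,
                            cv_lambda=float(model.alpha_), n_samples=len(common))


def spearman_check(x, y):
    """Convenience Pearson/Spearman pair used in QC reports."""
    r_p = float(sps.pearsonr(x, y)[0])
    r_s = float(sps.spearmanr(x, y)[0])
    return r_p, r_s
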