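"""scRNA-seq QC and big-like signature scoring; cytokine normalization."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "scrna_qc_filter",
    "normalize_counts",
    "big_like_scores",
    "fraction_big_like",
    "normalize_cytokines",
]


def scrna_qc_filter(counts: pd.DataFrame, gene_flags: pd.DataFrame, *,
                    min_umi: int = 300, max_mito_fraction: float = 0.5,
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter cells of a genes x cells UMI matrix.

    Keeps cells with >= ``min_umi`` non-immunoglobulin UMIs (strict
    "fewer than 300" removal), mitochondrial fraction <= 0.5, and zero
    counts on every exclusion marker. Returns the filtered matrix and the
    number of cells removed per rule (counted independently per rule).
    """
    flags = gene_flags.reindex(counts.index).fillna(False)
    ig = flags["is_immunoglobulin"].to_numpy(dtype=bool)
    mito = flags["is_mitochondrial"].to_numpy(dtype=bool)
    excl = flags["is_exclusion_marker"].to_numpy(dtype=bool)

    mat = counts.to_numpy()
    total = mat.sum(axis=0)
    non_ig = mat[~ig].sum(axis=0)
    low_umi = non_ig < min_umi
    if mito.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mat[mito].sum(axis=0) / total, 0.0)
        high_mito = mito_frac > max_mito_fraction
    else:
        warnings.warn("no mitochondrial flags: mito rule skipped")
        high_mito = np.zeros(mat.shape[1], dtype=bool)
    marker_pos = (mat[excl] > 0).any(axis=0) if excl.any() else np.zeros(
        mat.shape[1], dtype=bool)

    keep = ~(low_umi | high_mito | marker_pos)
    removed = {"low_umi": int(low_umi.sum()),
               "high_mito": int(high_mito.sum()),
               "marker_positive": int(marker_pos.sum()),
               "total_removed": int((~keep).sum())}
    return counts.loc[:, keep], removed


def normalize_counts(counts: pd.DataFrame, *, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalization to counts-per-``scale``, log1p."""
    total = counts.sum(axis=0).replace(0, np.nan)
    return np.log1p(counts.div(total, axis=1) * scale)


@dataclass
class BigLikeResult:
    scores: pd.Series
    big_like: pd.Series
    threshold_rule: str
    threshold: float
    genes_up: list[str]
    genes_down: list[str]


def big_like_scores(counts: pd.DataFrame, up_genes, down_genes,
                    gene_flags: pd.DataFrame | None = None, *,
                    rule: str = "median", fixed_ratio: float = 5.0,
                    normalized: bool = False) -> BigLikeResult:
    """Per-cell ratio of mean up-signature to mean down-signature expression.

    Genes undetected in every cell and immunoglobulin genes are dropped
    before scoring; expression is library-size-normalized (log1p CP10K)
    unless ``normalized=True``. A cell is big-like if its score exceeds
    the median of all scores (default) or ``fixed_ratio`` with
    ``rule='fixed_ratio'``.
    """
    if rule not in ("median", "fixed_ratio"):
        raise ValueError(f"unknown rule: {rule}")
    drop = set(counts.index[counts.sum(axis=1) == 0])
    if gene_flags is not None:
        ig = gene_flags.reindex(counts.index)["is_immunoglobulin"].fillna(False)
        drop |= set(counts.index[ig.to_numpy(dtype=bool)])
    up = [g for g in up_genes if g in counts.index and g not in drop]
    down = [g for g in down_genes if g in counts.index and g not in drop]
    if not up or not down:
        raise ValueError("empty signature gene list after filtering")
    expr = counts if normalized else normalize_counts(counts)
    up_mean = expr.loc[up].mean(axis=0)
    down_mean = expr.loc[down].mean(axis=0)
    pseudo = 1e-9 * float(expr.to_numpy().mean() or 1.0)
    scores = up_mean / (down_mean + pseudo)
    if rule == "median":
        thr = float(scores.median())
    else:
        thr = float(fixed_ratio)
    return BigLikeResult(scores, scores > thr, rule, thr, up, down)


def fraction_big_like(big_like: pd.Series, patient_ids: pd.Series,
                      group_labels: pd.Series | None = None):
    """Per-patient big-like fractions and an optional two-group Welch t-test.

    Returns ``(fractions, test)`` where ``test`` is None without two
    groups, else a dict with t, p and the group means (direction).
    """
    patient_ids = patient_ids.reindex(big_like.index)
    df = pd.DataFrame({"big": big_like.astype(float), "patient": patient_ids})
    fractions = df.groupby("patient")["big"].mean().rename("fraction_big_like")
    test = None
    if group_labels is not None:
        pg = group_labels.reindex(big_like.index).groupby(patient_ids).first()
        groups = [g for g in pg.dropna().unique()]
        if len(groups) == 2:
            a = fractions[pg == groups[0]].dropna()
            b = fractions[pg == groups[1]].dropna()
            if len(a) >= 2 and len(b) >= 2:
                t, p = sps.ttest_ind(a, b, equal_var=False)
                test = {"groups": groups, "t": float(t), "p": float(p),
                        "mean_" + str(groups[0]): float(a.mean()),
                        "mean_" + str(groups[1]): float(b.mean())}
        else:
            warnings.warn("need exactly 2 groups for the t-test; skipped")
    return fractions, test


def normalize_cytokines(panel: pd.DataFrame, status: pd.DataFrame,
                        ) -> pd.DataFrame:
    """Detection-limit handling plus two-stage z-scoring.

    Below-LOD entries become missing; above-max entries are replaced by
    the cohort maximum of that cytokine (among in-range values). Then:
    log10, z-score per cytokine across samples, z-score per sample across
    cytokines. Missing entries are ignored in all moments. Cytokines
    missing in every sample are dropped with a warning.
    """
    status = status.reindex_like(panel)
    vals = panel.to_numpy(dtype=float).copy()
    below = (status == "below_lod").to_numpy()
    above = (status == "above_max").to_numpy()
    vals[below] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ok_vals = np.where(below | above, np.nan, vals)
        row_max = np.nanmax(ok_vals, axis=1)
    for i in np.flatnonzero(above.any(axis=1)):
        vals[i, above[i]] = row_max[i]
    df = pd.DataFrame(vals, index=panel.index, columns=panel.columns)
    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} cytokines missing in all samples dropped")
        df = df[~all_missing]
    if (df <= 0).any().any():
        raise ValueError("non-positive concentrations cannot be log10-scaled")
    logged = np.log10(df)
    z1 = logged.sub(logged.mean(axis=1), axis=0).div(
        logged.std(axis=1, ddof=0), axis=0)
    z2 = z1.sub(z1.mean(axis=0), axis=1).div(z1.std(axis=0, ddof=0), axis=1)
    return z2
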