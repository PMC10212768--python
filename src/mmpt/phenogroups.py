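"""Bone-marrow composition modes from latent cell features.

Pipeline: standardize latent features, select the most informative 100
by PCA loading contribution, spectral-cluster a balanced training
subsample into k subclusters, k-NN-propagate labels to the remaining
cells, compute per-sample subcluster compositions from control wells,
correlate compositions into a sample similarity matrix and cut the
hierarchical dendrogram into PhenoGroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA

__all__ = [
    "SubclusterModel",
    "PhenoGroupAssignment",
    "select_latent_features",
    "balanced_training_sample",
    "fit_subclusters",
    "assign_subclusters",
    "sample_composition",
    "derive_phenogroups",
]


@dataclass
class SubclusterModel:
    selected_features: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    training_matrix: np.ndarray  # standardized, selected features only
    training_labels: np.ndarray  # 1..k
    k: int
    knn_k: int = 15
    variance_explained_pc12: float = float("nan")


@dataclass
class PhenoGroupAssignment:
    labels: pd.Series  # sample_id -> "PG1".."PGn"
    similarity: pd.DataFrame
    linkage: np.ndarray
    group_order: list[int] = field(default_factory=list)


def select_latent_features(features: pd.DataFrame, n_select: int = 100,
                           ) -> tuple[list[str], float]:
    """Top features by variance-weighted |PC1| + |PC2| loading contribution.

    Features are standardized first; returns (selected column names sorted
    by descending contribution, variance explained by PC1+PC2).
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features")
    X = features.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("zero-variance feature matrix")
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=2)
    pca.fit(Xs)
    lam = pca.explained_variance_ratio_
    contrib = lam[0] * np.abs(pca.components_[0]) + lam[1] * np.abs(pca.components_[1])
    order = np.argsort(-contrib)[:min(n_select, features.shape[1])]
    return [features.columns[i] for i in order], float(lam.sum())


def balanced_training_sample(cells: pd.DataFrame, *, per_sample: int = 1200,
                             class_column: str = "cell_class",
                             rng: np.random.Generator | int = 0) -> pd.DataFrame:
    """Subsample approximately ``per_sample`` cells per sample, balanced
    across the four cell classes (as far as availability allows)."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    picks = []
    classes = sorted(cells[class_column].unique())
    per_class = max(1, per_sample // max(len(classes), 1))
    for _, grp in cells.groupby("sample_id", sort=True):
        for _, sub in grp.groupby(class_column, sort=True):
            n = min(per_class, len(sub))
            picks.append(sub.sample(n=n, random_state=rng.integers(2**31)))
    return pd.concat(picks)


def fit_subclusters(training_cells: pd.DataFrame, feature_columns,
                    *, k: int = 15, knn_k: int = 15, n_neighbors: int = 15,
                    seed: int = 0,
                    selected: list[str] | None = None) -> SubclusterModel:
    """Spectral clustering of a training subsample into k subclusters.

    Affinity is a symmetrized k-nearest-neighbor graph; labels are 1..k.
    Standardization parameters are estimated on the training cells and
    reused for propagation.
    """
    feats = training_cells[list(feature_columns)]
    if selected is None:
        selected, var12 = select_latent_features(feats)
    else:
        var12 = float("nan")
    X = feats[selected].to_numpy(dtype=float)
    if k > len(X):
        raise ValueError(f"k={k} exceeds {len(X)} training cells")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd
    sc = SpectralClustering(n_clusters=k, affinity="nearest_neighbors",
                            n_neighbors=min(n_neighbors, len(X) - 1),
                            assign_labels="kmeans", random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = sc.fit_predict(Xs) + 1
    return SubclusterModel(selected, mu, sd, Xs, labels, k, knn_k, var12)


def assign_subclusters(model: SubclusterModel, cells: pd.DataFrame) -> np.ndarray:
    """k-NN propagation of subcluster labels (majority vote; ties go to
    the nearest neighbor's label)."""
    missing = [f for f in model.selected_features if f not in cells.columns]
    if missing:
        raise KeyError(f"cells lack selected features: {missing[:5]}")
    X = cells[model.selected_features].to_numpy(dtype=float)
    Xs = (X - model.feature_means) / model.feature_sds
    k = min(model.knn_k, len(model.training_matrix))
    tree = cKDTree(model.training_matrix)
    _, idx = tree.query(Xs, k=k)
    idx = np.asarray(idx).reshape(len(Xs), k)
    neigh = model.training_labels[idx]  # (n, k), nearest first
    out = np.empty(len(Xs), dtype=int)
    for i, row in enumerate(neigh):
        counts = np.bincount(row)
        best = counts.max()
        winners = np.flatnonzero(counts == best)
        if len(winners) == 1:
            out[i] = winners[0]
        else:
            # tie: first neighbor (the nearest) whose label is among winners
            out[i] = row[np.isin(row, winners)][0]
    return out


def sample_composition(cells: pd.DataFrame, labels: np.ndarray, k: int, *,
                       min_cells: int = 50) -> pd.DataFrame:
    """Per-sample fractions over subclusters 1..k (rows sum to 1).

    Pass control-well cells only; samples with fewer than ``min_cells``
    are dropped with a warning.
    """
    df = pd.DataFrame({"sample_id": cells["sample_id"].to_numpy(),
                       "label": labels})
    counts = (df.groupby(["sample_id", "label"]).size()
              .unstack(fill_value=0)
              .reindex(columns=range(1, k + 1), fill_value=0))
    totals = counts.sum(axis=1)
    low = totals < min_cells
    if low.any():
        warnings.warn(f"{int(low.sum())} samples below {min_cells} control "
                      "cells dropped from composition")
        counts = counts[~low]
        totals = totals[~low]
    comp = counts.div(totals, axis=0)
    comp.columns = [f"subcluster_{j}" for j in comp.columns]
    return comp


def derive_phenogroups(composition: pd.DataFrame, *, n_groups: int = 3,
                       method: str = "pearson", linkage_method: str = "average",
                       plasma_subclusters: list[int] | None = None,
                       ) -> PhenoGroupAssignment:
    """Correlate sample compositions, cluster hierarchically, cut into
    PhenoGroups.

    PG labels are ordered by descending mean plasma-subcluster abundance
    (PG1 = most myeloma-rich) when ``plasma_subclusters`` is given, else
    by descending abundance of the overall most variable subcluster.
    """
    if len(composition) < n_groups:
        raise ValueError("fewer samples than requested groups")
    comp = composition.to_numpy(dtype=float)
    const = comp.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = pd.DataFrame(
            np.corrcoef(comp) if method == "pearson"
            else pd.DataFrame(comp.T).corr(method=method).to_numpy(),
            index=composition.index, columns=composition.index)
    sim = sim.fillna(0.0)
    if const.any():
        warnings.warn("constant composition rows: correlations set to 0")
        sim.iloc[np.flatnonzero(const), :] = 0.0
        sim.iloc[:, np.flatnonzero(const)] = 0.0
    np.fill_diagonal(sim.values, 1.0)
    dist = 1.0 - sim.to_numpy()
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    raw = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")

    if plasma_subclusters:
        cols = [f"subcluster_{j}" for j in plasma_subclusters
                if f"subcluster_{j}" in composition.columns]
        score = composition[cols].sum(axis=1)
    else:
        var_col = composition.var(axis=0).idxmax()
        score = composition[var_col]
    means = {g: score[raw == g].mean() for g in np.unique(raw)}
    order = sorted(means, key=means.get, reverse=True)
    relabel = {g: i + 1 for i, g in enumerate(order)}
    labels = pd.Series([f"PG{relabel[g]}" for g in raw],
                       index=composition.index, name="phenogroup")
    return PhenoGroupAssignment(labels, sim, Z, order)
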