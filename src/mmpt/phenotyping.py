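"""Single-cell quality filtering, class gating and spatial scoring.

Implements the threshold-gating stand-in for the trained classifiers:
confidence filtering, marker-based class assignment, size-based splitting
of plasma-marker-positive cells into myeloma (big) and small subtypes,
density-valley marker-positivity thresholding, and drug-induced
cell-cell interaction scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import argrelextrema
from scipy.spatial import cKDTree

__all__ = [
    "GatingThresholds",
    "InteractionResult",
    "filter_cells",
    "gate_cell_class",
    "gate_cells",
    "split_plasma_by_size",
    "fraction_big",
    "marker_positive_fraction",
    "interaction_score",
]

GATED_CHANNELS = ("CD138", "CD319", "CD3", "CD14")


@dataclass
class GatingThresholds:
    """Per-channel positivity cutoffs and the big/small size split."""

    channel_cutoffs: dict[str, float] = field(default_factory=lambda: {
        "CD138": 10 ** 1.5, "CD319": 10 ** 1.5,
        "CD3": 10 ** 1.5, "CD14": 10 ** 1.5,
    })
    big_small_diameter_cutoff_um: float = 11.0
    min_confidence: float = 0.6

    def __post_init__(self):
        for ch, cut in self.channel_cutoffs.items():
            if not np.isfinite(cut) or cut <= 0:
                raise ValueError(f"cutoff for {ch} must be finite and positive")


@dataclass
class InteractionResult:
    sample_id: str
    treatment: str
    effector_class: str
    raw_contact_fraction: float | None
    normalized_score: float | None = None
    n_target: int = 0
    n_effector: int = 0


def filter_cells(cells: pd.DataFrame, min_confidence: float = 0.6) -> pd.DataFrame:
    """Keep cells with classification confidence strictly above the cutoff.

    Order is preserved and the input frame is untouched.
    """
    if cells.empty:
        return cells.copy()
    return cells.loc[cells["class_confidence"] > min_confidence].copy()


def gate_cell_class(markers, thresholds: GatingThresholds) -> str:
    """Assign one exclusive class from marker intensities.

    Precedence plasma > t_cell > monocyte > other, so a cell positive for
    both a plasma marker and CD3 is called plasma.
    """
    cuts = thresholds.channel_cutoffs
    for ch in GATED_CHANNELS:
        if ch not in markers or markers[ch] is None or (
                isinstance(markers[ch], float) and np.isnan(markers[ch])):
            raise KeyError(f"missing marker channel: {ch}")
    if markers["CD138"] > cuts["CD138"] or markers["CD319"] > cuts["CD319"]:
        return "plasma"
    if markers["CD3"] > cuts["CD3"]:
        return "t_cell"
    if markers["CD14"] > cuts["CD14"]:
        return "monocyte"
    return "other"


def gate_cells(cells: pd.DataFrame, thresholds: GatingThresholds) -> pd.Series:
    """Vectorized :func:`gate_cell_class` over a cell table."""
    for ch in GATED_CHANNELS:
        if ch not in cells.columns:
            raise KeyError(f"missing marker channel: {ch}")
        if cells[ch].isna().any():
            raise KeyError(f"missing marker channel: {ch} (NaN intensities)")
    cuts = thresholds.channel_cutoffs
    out = pd.Series("other", index=cells.index, dtype=object)
    mono = cells["CD14"] > cuts["CD14"]
    tc = cells["CD3"] > cuts["CD3"]
    plasma = (cells["CD138"] > cuts["CD138"]) | (cells["CD319"] > cuts["CD319"])
    out[mono] = "monocyte"
    out[tc] = "t_cell"
    out[plasma] = "plasma"
    return out


def split_plasma_by_size(cells: pd.DataFrame,
                         diameter_cutoff_um: float = 11.0) -> pd.Series:
    """Label plasma cells 'myeloma' (diameter >= cutoff) or 'small'.

    Non-plasma cells get 'none'.
    """
    out = pd.Series("none", index=cells.index, dtype=object)
    plasma = cells["cell_class"] == "plasma"
    big = plasma & (cells["diameter_um"] >= diameter_cutoff_um)
    out[plasma] = "small"
    out[big] = "myeloma"
    return out


def fraction_big(subtypes: pd.Series) -> float:
    """big / (big + small) among plasma cells; NaN when there are none."""
    n_big = int((subtypes == "myeloma").sum())
    n_small = int((subtypes == "small").sum())
    if n_big + n_small == 0:
        return float("nan")
    return n_big / (n_big + n_small)


def marker_positive_fraction(intensities, *, min_cells: int = 50,
                             bandwidth: str | float = "scott",
                             ) -> tuple[float, float, bool]:
    """Positivity threshold from the density valley of log-intensities.

    A Gaussian KDE of log10 intensity is evaluated on a grid; if two or
    more density modes exist, the threshold is the density minimum
    between the two most prominent modes. Unimodal distributions fall
    back to mean + 2 sd (flagged).

    Returns ``(threshold, fraction_above, unimodal_fallback)`` with the
    threshold on the original intensity scale.
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < min_cells:
        raise ValueError(f"need >= {min_cells} cells with finite intensity")
    logx = np.log10(x)
    if np.ptp(logx) < 1e-12:
        thr = float(10 ** (logx.mean() + 2 * logx.std()))
        return thr, float(np.mean(x > thr)), True
    kde = sps.gaussian_kde(logx, bw_method=bandwidth)
    grid = np.linspace(logx.min(), logx.max(), 512)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if grid.size and dens[0] > dens[1]:
        maxima = np.concatenate([[0], maxima])
    if dens[-1] > dens[-2]:
        maxima = np.concatenate([maxima, [grid.size - 1]])
    if maxima.size < 2:
        thr = float(10 ** (logx.mean() + 2 * logx.std()))
        return thr, float(np.mean(x > thr)), True
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    thr = float(10 ** grid[valley])
    return thr, float(np.mean(x > thr)), False


def interaction_score(cells: pd.DataFrame, *, effector_class: str = "activated_t",
                      contact_radius_um: float = 15.0,
                      control_fraction: float | None = None,
                      sample_id: str = "", treatment: str = "",
                      brute_force: bool = False) -> InteractionResult:
    """Fraction of myeloma cells with >= 1 effector within contact range.

    ``effector_class`` is 'activated_t' or 'monocyte'. If a matched mean
    control fraction is given, the normalized score (fold change vs
    control) is attached. ``brute_force=True`` uses the O(n^2) pairwise
    check instead of a KD-tree (for verification; results are identical).
    """
    targets = cells[(cells["cell_class"] == "plasma")
                    & (cells["plasma_subtype"] == "myeloma")]
    if effector_class == "activated_t":
        eff = cells[(cells["cell_class"] == "t_cell")
                    & (cells["t_subtype"] == "activated")]
    elif effector_class == "monocyte":
        eff = cells[cells["cell_class"] == "monocyte"]
    else:
        raise ValueError(f"unknown effector class: {effector_class}")

    res = InteractionResult(sample_id, treatment, effector_class, None,
                            n_target=len(targets), n_effector=len(eff))
    if len(targets) == 0:
        return res  # missing, not zero
    if len(eff) == 0:
        res.raw_contact_fraction = 0.0
    else:
        tp = targets[["x_um", "y_um"]].to_numpy()
        ep = eff[["x_um", "y_um"]].to_numpy()
        if brute_force:
            d2 = ((tp[:, None, :] - ep[None, :, :]) ** 2).sum(axis=2)
            in_contact = (d2 <= contact_radius_um ** 2).any(axis=1)
        else:
            tree = cKDTree(ep)
            dist, _ = tree.query(tp, k=1)
            in_contact = dist <= contact_radius_um
        res.raw_contact_fraction = float(in_contact.mean())
    if control_fraction is not None and control_fraction > 0:
        res.normalized_score = res.raw_contact_fraction / control_fraction
    return res


def phenotype_summary(cells: pd.DataFrame, thresholds: GatingThresholds,
                      *, gamma_channel: str | None = None) -> pd.DataFrame:
    """Per-sample class counts, fraction_big and optional marker positivity."""
    rows = []
    for sid, grp in cells.groupby("sample_id", sort=True):
        kept = filter_cells(grp, thresholds.min_confidence)
        counts = kept["cell_class"].value_counts()
        sub = split_plasma_by_size(kept, thresholds.big_small_diameter_cutoff_um)
        row = {"sample_id": sid,
               "n_cells": len(kept),
               **{f"n_{c}": int(counts.get(c, 0))
                  for c in ("plasma", "t_cell", "monocyte", "other")},
               "fraction_big": fraction_big(sub)}
        if gamma_channel and gamma_channel in kept.columns:
            myel = kept.loc[sub == "myeloma", gamma_channel]
            if len(myel) >= 50:
                thr, frac, fb = marker_positive_fraction(myel)
                row.update({f"{gamma_channel}_threshold": thr,
                            f"{gamma_channel}_positive_fraction": frac,
                            f"{gamma_channel}_unimodal_fallback": fb})
        rows.append(row)
    return pd.DataFrame(rows)
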