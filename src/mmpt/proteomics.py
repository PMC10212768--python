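"""Proteome normalization, myeloma-abundance associations, signatures,
gene-set enrichment and drug-protein correlation networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import signed_logp, spearman, storey_qvalues, bh_adjust

__all__ = [
    "normalize_proteome",
    "discovery_associations",
    "validation_foldchanges",
    "SignatureSet",
    "select_signature",
    "geneset_enrichment",
    "regress_out_covariate",
    "drug_protein_network",
]


def normalize_proteome(raw: pd.DataFrame, *, low_abundance_quantile: float = 0.05,
                       ) -> pd.DataFrame:
    """log10-transform, mask the low-abundance tail, double z-score.

    Entries below each protein's ``low_abundance_quantile`` quantile are
    set missing, then values are z-scored across proteins (per row) and
    across samples (per column); missing entries are ignored in moments.
    Constant rows become all-missing with a warning.
    """
    vals = raw.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] <= 0):
        bad = np.argwhere(np.isfinite(vals) & (vals <= 0))[:5]
        raise ValueError(f"non-positive abundances at (row, col): {bad.tolist()}")
    logged = np.log10(vals)
    if low_abundance_quantile > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            floor = np.nanquantile(logged, low_abundance_quantile, axis=1,
                                   keepdims=True)
        logged = np.where(logged < floor, np.nan, logged)
    df = pd.DataFrame(logged, index=raw.index, columns=raw.columns)

    row_sd = df.std(axis=1, ddof=0)
    const = (row_sd == 0) & df.notna().any(axis=1)
    if const.any():
        warnings.warn(f"{int(const.sum())} constant protein rows set missing")
        df.loc[const] = np.nan
    z1 = df.sub(df.mean(axis=1), axis=0).div(df.std(axis=1, ddof=0), axis=0)
    z2 = z1.sub(z1.mean(axis=0), axis=1).div(z1.std(axis=0, ddof=0), axis=1)
    return z2


def discovery_associations(proteome: pd.DataFrame, covariate: pd.Series, *,
                           partner: str = "myeloma_fraction",
                           min_pairs: int = 10,
                           fdr: str = "storey") -> pd.DataFrame:
    """Per-protein Spearman association with a per-sample covariate.

    Pairwise-complete; proteins with fewer than ``min_pairs`` complete
    pairs are omitted. Returns rho, two-sided p, signed -log10(p) and a
    Storey q-value (or BH with ``fdr='bh'``).
    """
    cov = covariate.reindex(proteome.columns)
    rows = []
    for prot, vals in proteome.iterrows():
        res = spearman(vals.to_numpy(dtype=float), cov.to_numpy(dtype=float))
        if res.n < min_pairs or not np.isfinite(res.rho):
            continue
        rows.append({"protein": prot, "partner": partner, "rho": res.rho,
                     "p": res.p, "signed_logp": signed_logp(res.rho, res.p),
                     "n": res.n})
    out = pd.DataFrame(rows)
    if len(out):
        adjust = storey_qvalues if fdr == "storey" else bh_adjust
        out["q"] = adjust(out["p"].to_numpy())
    return out


def validation_foldchanges(big: pd.DataFrame, small: pd.DataFrame, *,
                           min_pairs: int = 2) -> pd.DataFrame:
    """Per-protein paired big-vs-small log2 fold change and paired t-test.

    Inputs are proteins x pairs matrices on log2 scale. log2FC is the
    mean over complete pairs of (big - small); a degenerate t statistic
    (zero variance of differences) reports p = 1.
    """
    common = big.index.intersection(small.index)
    rows = []
    for prot in common:
        d = (big.loc[prot] - small.loc[prot]).to_numpy(dtype=float)
        d = d[np.isfinite(d)]
        if d.size < min_pairs:
            continue
        fc = float(d.mean())
        sd = d.std(ddof=1)
        if sd == 0:
            p = 1.0
        else:
            t = fc / (sd / np.sqrt(d.size))
            p = float(2 * sps.t.sf(abs(t), df=d.size - 1))
        rows.append({"protein": prot, "log2fc": fc, "p": p, "n_pairs": d.size})
    return pd.DataFrame(rows)


@dataclass
class SignatureSet:
    up: list[str]
    down: list[str]
    p_cut: float
    fc_cut: float
    fisher_p: float
    quadrant_counts: list[list[int]] = field(default_factory=list)


def select_signature(discovery: pd.DataFrame, validation: pd.DataFrame, *,
                     p_cut: float = 0.05, fc_cut: float = 0.3) -> SignatureSet:
    """Quadrant signature: up = discovery-positive (p < p_cut, rho > 0)
    AND validation log2FC > +fc_cut; down is the mirrored quadrant.

    The Fisher concordance test is a two-sided exact test on the 2x2 of
    discovery sign x validation sign among proteins passing both the
    discovery p and validation |FC| cutoffs.
    """
    if len(discovery) == 0 or len(validation) == 0:
        warnings.warn("empty discovery or validation table: empty signature")
        return SignatureSet([], [], p_cut, fc_cut, 1.0, [[0, 0], [0, 0]])
    merged = discovery.merge(validation, on="protein",
                             suffixes=("_disc", "_val"))
    sig = merged[(merged["p_disc"] < p_cut)
                 & (merged["log2fc"].abs() > fc_cut)]
    up = sig.loc[(sig["rho"] > 0) & (sig["log2fc"] > fc_cut),
                 "protein"].tolist()
    down = sig.loc[(sig["rho"] < 0) & (sig["log2fc"] < -fc_cut),
                   "protein"].tolist()
    a = len(up)  # disc+ val+
    b = int(((sig["rho"] > 0) & (sig["log2fc"] < -fc_cut)).sum())
    c = int(((sig["rho"] < 0) & (sig["log2fc"] > fc_cut)).sum())
    d = len(down)
    table = [[a, b], [c, d]]
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        if a + b + c + d == 0:
            warnings.warn("empty quadrant table; Fisher p set to 1")
        fisher_p = float(sps.fisher_exact(table)[1]) if a + b + c + d else 1.0
    else:
        fisher_p = float(sps.fisher_exact(table)[1])
    return SignatureSet(sorted(up), sorted(down), p_cut, fc_cut, fisher_p, table)


def geneset_enrichment(signature, gene_sets: dict[str, list], universe) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a signature in gene sets,
    BH-adjusted across sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    signature = set(signature) & universe
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        overlap = len(members & signature)
        # P(X >= overlap), X ~ Hypergeom(N, K=|set|, n=|signature|)
        p = float(sps.hypergeom.sf(overlap - 1, len(universe), len(members),
                                   len(signature)))
        rows.append({"gene_set": name, "set_size": len(members),
                     "overlap": overlap, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", ignore_index=True)


def regress_out_covariate(proteome: pd.DataFrame, covariate: pd.Series,
                          ) -> pd.DataFrame:
    """Replace abundances with OLS residuals after regressing on the
    covariate (with intercept), per protein over complete pairs."""
    cov = covariate.reindex(proteome.columns).to_numpy(dtype=float)
    if np.nanstd(cov) == 0:
        warnings.warn("constant covariate: residuals are centered abundances")
        return proteome.sub(proteome.mean(axis=1), axis=0)
    out = proteome.copy()
    vals = proteome.to_numpy(dtype=float)
    for i in range(vals.shape[0]):
        y = vals[i]
        ok = np.isfinite(y) & np.isfinite(cov)
        if ok.sum() < 3:
            continue
        x = cov[ok]
        beta, alpha = np.polyfit(x, y[ok], 1)
        res = np.full_like(y, np.nan)
        res[ok] = y[ok] - (alpha + beta * x)
        out.iloc[i] = res
    return out


def drug_protein_network(proteome: pd.DataFrame, drug_matrix: pd.DataFrame,
                         edges: pd.DataFrame, *,
                         imputed_mask: pd.DataFrame | None = None,
                         rho_cut: float = 0.585, p_cut: float = 0.05,
                         top_n: int = 2, min_pairs: int = 10,
                         ) -> tuple[nx.Graph, pd.DataFrame]:
    """Drug-protein Spearman association network.

    Associations use non-imputed responses only. Nodes are proteins with
    |rho| > rho_cut and p < p_cut for any drug, plus the top-``top_n``
    and bottom-``top_n`` strongest associations per drug; edges come from
    the user-supplied interaction pair list and isolated nodes are
    dropped. Returns the graph and the full association table.
    """
    drugs = drug_matrix.copy()
    if imputed_mask is not None:
        drugs = drugs.mask(imputed_mask.reindex_like(drugs).fillna(False))
    rows = []
    for drug in drugs.columns:
        resp = drugs[drug].reindex(proteome.columns)
        for prot, vals in proteome.iterrows():
            res = spearman(vals.to_numpy(dtype=float),
                           resp.to_numpy(dtype=float))
            if res.n < min_pairs or not np.isfinite(res.rho):
                continue
            rows.append({"protein": prot, "drug": drug,
                         "rho": res.rho, "p": res.p, "n": res.n})
    assoc = pd.DataFrame(rows)
    selected: set = set()
    if len(assoc):
        passing = assoc[(assoc["rho"].abs() > rho_cut) & (assoc["p"] < p_cut)]
        selected |= set(passing["protein"])
        for drug, sub in assoc.groupby("drug"):
            ranked = sub.sort_values("rho")
            selected |= set(ranked["protein"].tail(top_n))
            selected |= set(ranked["protein"].head(top_n))

    g = nx.Graph()
    if edges is None or len(edges) == 0:
        warnings.warn("empty interaction edge list: network has no edges")
        return g, assoc
    ecols = list(edges.columns[:2])
    for rec in edges.itertuples(index=False):
        a, b = getattr(rec, ecols[0]), getattr(rec, ecols[1])
        if a in selected and b in selected and a != b:
            g.add_edge(a, b)
    # attach per-drug rho node attributes
    if len(assoc):
        for prot in g.nodes:
            sub = assoc[assoc["protein"] == prot]
            g.nodes[prot].update(
                {f"rho_{r.drug}": r.rho for r in sub.itertuples(index=False)})
    return g, assoc
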