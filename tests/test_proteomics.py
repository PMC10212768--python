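"""Normalization, associations, signature, enrichment and network against
closed-form / brute-force oracles."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mmpt.proteomics import (
    discovery_associations,
    drug_protein_network,
    geneset_enrichment,
    normalize_proteome,
    regress_out_covariate,
    select_signature,
    validation_foldchanges,
)


def _raw(rng, p=30, s=20):
    return pd.DataFrame(10 ** rng.normal(3, 1, (p, s)),
                        index=[f"P{i}" for i in range(p)],
                        columns=[f"s{i}" for i in range(s)])


class TestNormalize:
    def test_nonpositive_rejected(self, rng):
        raw = _raw(rng)
        raw.iloc[0, 0] = -1.0
        with pytest.raises(ValueError):
            normalize_proteome(raw)

    def test_row_zscore_after_first_step(self, rng):
        raw = _raw(rng)
        # z across proteins only: disable the low-abundance floor and verify
        logged = np.log10(raw)
        z1 = logged.sub(logged.mean(axis=1), axis=0).div(
            logged.std(axis=1, ddof=0), axis=0)
        np.testing.assert_allclose(z1.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z1.std(axis=1, ddof=0), 1.0, atol=1e-9)
        out = normalize_proteome(raw, low_abundance_quantile=0.0)
        # column step runs after row step; columns of the result are z-scored
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_constant_row_set_missing(self, rng):
        raw = _raw(rng)
        raw.iloc[3] = 100.0
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_proteome(raw, low_abundance_quantile=0.0)
        assert out.iloc[3].isna().all()

    def test_low_abundance_tail_masked(self, rng):
        raw = _raw(rng, p=10, s=100)
        out = normalize_proteome(raw, low_abundance_quantile=0.05)
        # about 5% of each row masked
        frac = out.isna().mean(axis=1)
        assert ((frac >= 0.03) & (frac <= 0.08)).all()

    def test_missing_preserved(self, rng):
        raw = _raw(rng)
        raw.iloc[2, 5] = np.nan
        out = normalize_proteome(raw, low_abundance_quantile=0.0)
        assert np.isnan(out.iloc[2, 5])


class TestDiscovery:
    def test_perfect_monotone(self, rng):
        fb = pd.Series(np.linspace(0.1, 0.9, 20),
                       index=[f"s{i}" for i in range(20)])
        prot = pd.DataFrame([fb.to_numpy()], index=["P0"], columns=fb.index)
        out = discovery_associations(prot, fb)
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        assert out.loc[0, "signed_logp"] > 0

    def test_min_pairs_enforced(self, rng):
        fb = pd.Series(rng.uniform(size=8), index=[f"s{i}" for i in range(8)])
        prot = pd.DataFrame(rng.standard_normal((3, 8)), columns=fb.index)
        out = discovery_associations(prot, fb, min_pairs=10)
        assert len(out) == 0

    def test_planted_auroc(self, rng):
        from sklearn.metrics import roc_auc_score
        from mmpt.synthetic import generate_proteome
        fb = pd.Series(rng.uniform(0.1, 0.9, 77),
                       index=[f"s{i}" for i in range(77)])
        raw, up, down, *_ = generate_proteome(fb, n_proteins=400,
                                              n_signature=40, effect=0.8,
                                              missing_rate=0.0, rng=1)
        out = discovery_associations(normalize_proteome(raw), fb)
        planted = out["protein"].isin(up + down)
        auroc = roc_auc_score(planted, out["signed_logp"].abs())
        assert auroc >= 0.95


class TestValidation:
    def test_equal_pairs_fc_zero_p_one(self):
        big = pd.DataFrame(np.ones((3, 4)), index=list("abc"))
        out = validation_foldchanges(big, big.copy())
        assert (out["log2fc"] == 0).all()
        assert (out["p"] == 1.0).all()

    def test_exact_doubling(self):
        small = pd.DataFrame(np.full((2, 4), 3.0), index=list("ab"))
        big = small + 1.0  # log2 scale: 2x linear
        out = validation_foldchanges(big, small)
        np.testing.assert_allclose(out["log2fc"], 1.0, atol=1e-12)

    def test_t_statistic_closed_form(self):
        d = np.array([0.5, 0.6, 0.4, 0.5])
        big = pd.DataFrame([d], index=["P0"])
        small = pd.DataFrame([np.zeros(4)], index=["P0"])
        out = validation_foldchanges(big, small)
        t = d.mean() / (d.std(ddof=1) / 2.0)
        p = 2 * sps.t.sf(abs(t), df=3)
        assert out.loc[0, "log2fc"] == pytest.approx(d.mean(), abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(p, abs=1e-9)

    def test_insufficient_pairs_omitted(self):
        big = pd.DataFrame([[1.0, np.nan, np.nan, np.nan]], index=["P0"])
        small = pd.DataFrame([[0.5, 0.4, np.nan, np.nan]], index=["P0"])
        assert len(validation_foldchanges(big, small)) == 0


class TestSignature:
    def _tables(self, rhos, ps, fcs):
        disc = pd.DataFrame({"protein": [f"P{i}" for i in range(len(rhos))],
                             "rho": rhos, "p": ps,
                             "signed_logp": np.sign(rhos), "n": 20})
        val = pd.DataFrame({"protein": [f"P{i}" for i in range(len(fcs))],
                            "log2fc": fcs, "p": 0.01, "n_pairs": 4})
        return disc, val

    def test_boundary_strictness(self):
        disc, val = self._tables([0.9], [0.04], [0.29])
        sig = select_signature(disc, val)
        assert sig.up == []  # 0.29 fails the strict > 0.3 cutoff

    def test_quadrants(self):
        disc, val = self._tables([0.9, 0.9, -0.9, -0.9],
                                 [0.01] * 4, [1.0, -1.0, 1.0, -1.0])
        sig = select_signature(disc, val)
        assert sig.up == ["P0"]
        assert sig.down == ["P3"]
        assert sig.quadrant_counts == [[1, 1], [1, 1]]

    def test_fisher_oracle_10_0_0_10(self):
        # hypergeometric enumeration: P = 2 / C(20,10)
        rhos = [1.0] * 10 + [-1.0] * 10
        fcs = [1.0] * 10 + [-1.0] * 10
        disc, val = self._tables(rhos, [0.001] * 20, fcs)
        sig = select_signature(disc, val)
        assert sig.fisher_p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_random_signs_uniform_p(self, rng):
        ps = []
        for _ in range(200):
            n = 40
            rhos = rng.choice([1.0, -1.0], n)
            fcs = rng.choice([1.0, -1.0], n)
            disc, val = self._tables(rhos, [0.001] * n, fcs)
            ps.append(select_signature(disc, val).fisher_p)
        # discrete p-values are conservative; KS against sub-uniform
        assert np.mean(np.asarray(ps) <= 0.05) <= 0.07

    def test_order_invariance(self, rng):
        n = 30
        rhos = rng.choice([1.0, -1.0], n)
        fcs = rng.normal(0, 1, n)
        disc, val = self._tables(rhos, [0.01] * n, fcs)
        s1 = select_signature(disc, val)
        s2 = select_signature(disc.sample(frac=1, random_state=1),
                              val.sample(frac=1, random_state=2))
        assert s1.up == s2.up and s1.down == s2.down


class TestEnrichment:
    def test_closed_form_1_over_252(self):
        universe = [f"g{i}" for i in range(10)]
        out = geneset_enrichment(universe[:5], {"set": universe[:5]}, universe)
        assert out.loc[0, "p"] == pytest.approx(1 / 252, rel=1e-9)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(100)]
        out = geneset_enrichment(universe[:5], {"set": universe[90:]}, universe)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            geneset_enrichment(["a"], {"s": ["a"]}, [])

    def test_planted_set_ranks_first(self, rng):
        universe = [f"g{i}" for i in range(1000)]
        signature = universe[:50]
        planted = universe[:8] + universe[900:902]  # 8/10 in signature
        sets = {"planted": planted}
        for i in range(100):
            sets[f"rand{i}"] = list(rng.choice(universe, 10, replace=False))
        out = geneset_enrichment(signature, sets, universe)
        assert out.loc[0, "gene_set"] == "planted"


class TestResiduals:
    def test_perfect_linear_gives_zero(self):
        cov = pd.Series([1.0, 2, 3, 4, 5], index=[f"s{i}" for i in range(5)])
        prot = pd.DataFrame([2 * cov + 1], index=["P0"], columns=cov.index)
        out = regress_out_covariate(prot, cov)
        np.testing.assert_allclose(out.loc["P0"], 0.0, atol=1e-9)

    def test_orthogonal_gives_centered(self, rng):
        cov = pd.Series([-1.0, 1, -1, 1], index=[f"s{i}" for i in range(4)])
        y = np.array([5.0, 5, 7, 7])  # orthogonal to cov
        prot = pd.DataFrame([y], index=["P0"], columns=cov.index)
        out = regress_out_covariate(prot, cov)
        np.testing.assert_allclose(out.loc["P0"], y - y.mean(), atol=1e-9)

    def test_constant_covariate_warns(self, rng):
        cov = pd.Series(np.ones(5), index=[f"s{i}" for i in range(5)])
        prot = pd.DataFrame(rng.standard_normal((2, 5)), columns=cov.index)
        with pytest.warns(UserWarning, match="constant"):
            out = regress_out_covariate(prot, cov)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)

    def test_signal_survives(self, rng):
        n = 60
        cov = pd.Series(rng.standard_normal(n),
                        index=[f"s{i}" for i in range(n)])
        signal = rng.standard_normal(n)
        prot = pd.DataFrame([cov.to_numpy() + signal], index=["P0"],
                            columns=cov.index)
        out = regress_out_covariate(prot, cov)
        rho = np.corrcoef(out.loc["P0"], signal)[0, 1]
        assert rho >= 0.95


class TestNetwork:
    def _setup(self, rng, p=20, s=25, d=5):
        prot = pd.DataFrame(rng.standard_normal((p, s)),
                            index=[f"P{i}" for i in range(p)],
                            columns=[f"s{i}" for i in range(s)])
        drugs = pd.DataFrame(rng.standard_normal((s, d)),
                             index=prot.columns,
                             columns=[f"d{i}" for i in range(d)])
        drugs["d0"] = prot.loc["P0"] + 0.1 * rng.standard_normal(s)
        return prot, drugs

    def test_brute_force_node_selection(self, rng):
        prot, drugs = self._setup(rng)
        edges = pd.DataFrame({"a": [f"P{i}" for i in range(19)],
                              "b": [f"P{i+1}" for i in range(19)]})
        g, assoc = drug_protein_network(prot, drugs, edges,
                                        rho_cut=0.585, p_cut=0.05)
        # independent re-selection with scipy
        selected = set()
        for d in drugs.columns:
            rows = []
            for pr in prot.index:
                rho, p = sps.spearmanr(prot.loc[pr], drugs[d])
                rows.append((pr, rho, p))
                if abs(rho) > 0.585 and p < 0.05:
                    selected.add(pr)
            rows.sort(key=lambda r: r[1])
            selected |= {r[0] for r in rows[:2]} | {r[0] for r in rows[-2:]}
        expect_edges = {(a, b) for a, b in zip(edges["a"], edges["b"])
                        if a in selected and b in selected}
        assert set(map(tuple, map(sorted, g.edges))) == \
            set(map(tuple, map(sorted, expect_edges)))

    def test_top2_bottom2_always_contribute(self, rng):
        prot, drugs = self._setup(rng, d=1)
        drugs["d0"] = rng.standard_normal(len(drugs))  # all |rho| small
        g, assoc = drug_protein_network(prot, drugs[["d0"]],
                                        pd.DataFrame({"a": [], "b": []}),
                                        rho_cut=0.99)
        # selection before edge filtering: 4 nodes per drug
        ranked = assoc.sort_values("rho")
        sel = set(ranked["protein"].head(2)) | set(ranked["protein"].tail(2))
        assert len(sel) == 4

    def test_isolated_nodes_dropped(self, rng):
        prot, drugs = self._setup(rng)
        # edge to a protein that is never selected
        edges = pd.DataFrame({"a": ["P0"], "b": ["NOT_A_PROTEIN"]})
        g, assoc = drug_protein_network(prot, drugs, edges)
        assert "P0" not in g.nodes

    def test_empty_edges_warn(self, rng):
        prot, drugs = self._setup(rng)
        with pytest.warns(UserWarning, match="empty"):
            g, _ = drug_protein_network(prot, drugs,
                                        pd.DataFrame({"a": [], "b": []}))
        assert g.number_of_nodes() == 0
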