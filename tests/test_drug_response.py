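"""RCF/PCY scoring against the closed-form composition oracle; QC,
imputation and predictor ranking contracts."""

import numpy as np
import pandas as pd
import pytest

from mmpt.drug_response import (
    compute_rcf,
    elasticnet_predictors,
    lasso_impute,
    pcy_scores,
    rcf_table,
    replicate_qc,
    well_fractions,
)


def oracle_pcy(class_weights: dict, kills: dict, target="myeloma") -> float:
    """Independent closed-form PCY: killed cells also shrink the denominator."""
    ctrl = {k: v / sum(class_weights.values()) for k, v in class_weights.items()}
    surv = {k: v * (1 - kills.get(k, 0.0)) for k, v in class_weights.items()}
    treated = {k: v / sum(surv.values()) for k, v in surv.items()}
    return 1.0 - treated[target] / ctrl[target]


class TestRCF:
    def test_formula(self):
        assert compute_rcf(50 / 500, [0.2]) == pytest.approx(0.5)

    def test_three_controls(self):
        assert compute_rcf(0.10, [0.18, 0.20, 0.22]) == pytest.approx(0.5)

    def test_zero_control_mean_is_nan(self):
        assert np.isnan(compute_rcf(0.1, [0.0, 0.0]))

    def test_no_controls_is_error(self):
        with pytest.raises(ValueError):
            compute_rcf(0.1, [])

    def test_control_wells_average_to_one(self, scored_cohort):
        rcfs = rcf_table(scored_cohort.cells, scored_cohort.layout)
        for _, grp in rcfs.groupby("sample_id"):
            for ct in ("dmso", "isotype"):
                sub = grp.loc[grp["control_type"] == ct, "rcf"]
                assert sub.mean() == pytest.approx(1.0, abs=1e-9)

    def test_antibody_normalized_to_isotype(self, scored_cohort):
        rcfs = rcf_table(scored_cohort.cells, scored_cohort.layout)
        frac = well_fractions(scored_cohort.cells)
        merged = scored_cohort.layout.merge(frac, on=["sample_id", "well_id"])
        sid = rcfs["sample_id"].iloc[0]
        sub = merged[merged["sample_id"] == sid]
        iso_mean = sub.loc[sub["control_type"] == "isotype", "fraction"].mean()
        row = rcfs[(rcfs["sample_id"] == sid) & (rcfs["treatment"] == "mab")].iloc[0]
        assert row["rcf"] == pytest.approx(row["fraction"] / iso_mean)


class TestPCY:
    def test_replicate_mean(self):
        # PCY = 1 - mean(RCF): direct arithmetic on a hand-built table
        layout = pd.DataFrame({
            "sample_id": "s", "well_id": ["W1", "W2", "W3", "C1", "C2"],
            "treatment": ["drug"] * 3 + ["DMSO"] * 2,
            "drug_class": ["compound"] * 3 + ["control"] * 2,
            "concentration_um": [1.0] * 3 + [0.0] * 2,
            "replicate": [1, 2, 3, 1, 2],
            "control_type": ["none"] * 3 + ["dmso"] * 2,
        })
        # control fraction 0.2; treated well fractions 0.10/0.12/0.14
        rows = []
        fractions = {"W1": 0.10, "W2": 0.12, "W3": 0.14, "C1": 0.2, "C2": 0.2}
        for wid, frac in fractions.items():
            n = 500
            k = int(round(frac * n))
            rows.append(pd.DataFrame({
                "sample_id": "s", "well_id": wid,
                "cell_class": ["plasma"] * k + ["other"] * (n - k),
                "plasma_subtype": ["myeloma"] * k + ["none"] * (n - k),
            }))
        cells = pd.concat(rows)
        wide, per_conc = pcy_scores(cells, layout)
        rcfs = np.array([0.10, 0.12, 0.14]) / 0.2
        assert wide.loc["s", "drug"] == pytest.approx(1 - rcfs.mean(), abs=1e-12)

    def test_no_effect_drug_near_zero(self, scored_cohort):
        wide, _ = pcy_scores(scored_cohort.cells, scored_cohort.layout)
        assert wide["inert"].abs().max() < 0.05

    def test_planted_kill_recovered(self, scored_cohort):
        cfg = scored_cohort.config
        wide, _ = pcy_scores(scored_cohort.cells, scored_cohort.layout)
        mode = cfg.phenogroup_modes[0]
        cls_of = cfg.subcluster_classes
        for i, sid in enumerate(wide.index):
            fb = scored_cohort.truth.fraction_big[sid]
            weights = {}
            for j, p in enumerate(mode):
                c = cls_of[j]
                if c == "plasma":
                    weights["myeloma"] = weights.get("myeloma", 0) + p * fb
                    weights["small"] = weights.get("small", 0) + p * (1 - fb)
                else:
                    weights[c] = weights.get(c, 0) + p
            for trt, kills in cfg.kill_fractions.items():
                exp = oracle_pcy(weights, kills)
                assert wide.loc[sid, trt] == pytest.approx(exp, abs=0.05), (sid, trt)

    def test_off_target_machinery(self, scored_cohort):
        # killing myeloma inflates the other classes' fractions -> negative PCY
        wide_t, _ = pcy_scores(scored_cohort.cells, scored_cohort.layout,
                               target_class="t_cell")
        assert wide_t["killerA"].mean() < 0

    def test_subsampling_invariance(self, scored_cohort):
        wide, _ = pcy_scores(scored_cohort.cells, scored_cohort.layout)
        half = scored_cohort.cells.sample(frac=0.5, random_state=0)
        wide_half, _ = pcy_scores(half, scored_cohort.layout)
        diff = (wide - wide_half).abs().to_numpy()
        assert np.nanmax(diff) < 0.06  # 2x subsampling tolerance


class TestReplicateQC:
    def test_identical_replicates_concordance_one(self):
        layout = pd.DataFrame({
            "sample_id": "s",
            "well_id": [f"W{i}" for i in range(6)] + ["C1", "C2"],
            "treatment": ["d1", "d1", "d2", "d2", "d3", "d3", "DMSO", "DMSO"],
            "drug_class": ["compound"] * 6 + ["control"] * 2,
            "concentration_um": [1.0] * 6 + [0.0] * 2,
            "replicate": [1, 2, 1, 2, 1, 2, 1, 2],
            "control_type": ["none"] * 6 + ["dmso"] * 2,
        })
        fractions = {"W0": 0.05, "W1": 0.05, "W2": 0.10, "W3": 0.10,
                     "W4": 0.15, "W5": 0.15, "C1": 0.2, "C2": 0.2}
        rows = []
        for wid, frac in fractions.items():
            n = 200
            k = int(round(frac * n))
            rows.append(pd.DataFrame({
                "sample_id": "s", "well_id": wid,
                "cell_class": ["plasma"] * k + ["other"] * (n - k),
                "plasma_subtype": ["myeloma"] * k + ["none"] * (n - k)}))
        qc = replicate_qc(pd.concat(rows), layout)
        assert qc["concordance"].iloc[0] == pytest.approx(1.0)
        assert not qc["flagged"].iloc[0]

    def test_noise_sweep_monotone(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(2)
        true = np.linspace(0.0, 0.6, 12)
        concs = []
        sds = [0.01, 0.05, 0.1, 0.2, 0.4]
        for sd in sds:
            reps = [true + rng.normal(0, sd, 12) for _ in range(3)]
            mat = np.column_stack(reps)
            cors = [np.corrcoef(mat[:, i], mat[:, j])[0, 1]
                    for i in range(3) for j in range(i + 1, 3)]
            concs.append(np.mean(cors))
        assert spearmanr(sds, concs)[0] <= 0


class TestLassoImpute:
    def _matrix(self, rng, n=30, missing_col="d0"):
        base = rng.standard_normal((n, 6))
        df = pd.DataFrame(base, columns=[f"d{i}" for i in range(6)],
                          index=[f"s{i}" for i in range(n)])
        df["d0"] = df["d1"] * 1.0  # exact copy -> noiseless recovery
        return df

    def test_noiseless_recovery(self, rng):
        df = self._matrix(rng)
        truth = df["d0"].copy()
        df.loc[df.index[:6], "d0"] = np.nan
        filled, mask = lasso_impute(df, seed=0)
        assert mask["d0"].sum() == 6
        imp = filled.loc[mask["d0"], "d0"]
        r = np.corrcoef(imp, truth[mask["d0"]])[0, 1]
        assert r >= 0.99

    def test_independent_target_filtered(self, rng):
        df = pd.DataFrame(rng.standard_normal((25, 5)),
                          columns=[f"d{i}" for i in range(5)])
        df.loc[df.index[:5], "d0"] = np.nan
        filled, mask = lasso_impute(df, seed=1)
        assert mask["d0"].sum() == 0
        assert filled["d0"].isna().sum() == 5

    def test_too_few_training_samples_skipped(self, rng):
        df = self._matrix(rng, n=12)
        df.loc[df.index[:6], "d0"] = np.nan  # 6 measured < 10
        filled, mask = lasso_impute(df, seed=0)
        assert mask["d0"].sum() == 0

    def test_planted_linear_structure_holdout(self, rng):
        n, d = 60, 8
        latent = rng.standard_normal((n, 2))
        loadings = rng.standard_normal((2, d))
        mat = latent @ loadings + 0.05 * rng.standard_normal((n, d))
        df = pd.DataFrame(mat, columns=[f"d{i}" for i in range(d)])
        truth = df.copy()
        holdout = rng.uniform(size=df.shape) < 0.2
        df = df.mask(holdout)
        filled, mask = lasso_impute(df, seed=2)
        imp = filled.to_numpy()[mask.to_numpy()]
        tru = truth.to_numpy()[mask.to_numpy()]
        assert len(imp) > 20
        assert np.corrcoef(imp, tru)[0, 1] >= 0.9


class TestElasticNet:
    def test_planted_two_protein_model(self, rng):
        n, p = 60, 200
        X = rng.standard_normal((p, n))  # proteins x samples
        prot = pd.DataFrame(X, index=[f"P{i}" for i in range(p)],
                            columns=[f"s{i}" for i in range(n)])
        y = pd.Series(2 * X[0] - 1 * X[1] + 0.1 * rng.standard_normal(n),
                      index=prot.columns, name="drug")
        rank = elasticnet_predictors(prot, y, seed=0)
        assert "P0" in rank.top3_positive
        assert "P1" in rank.top3_negative

    def test_pure_noise_sparse(self, rng):
        n, p = 40, 300
        prot = pd.DataFrame(rng.standard_normal((p, n)),
                            index=[f"P{i}" for i in range(p)],
                            columns=[f"s{i}" for i in range(n)])
        y = pd.Series(rng.standard_normal(n), index=prot.columns)
        rank = elasticnet_predictors(prot, y, seed=0)
        assert (rank.coefficients != 0).mean() <= 0.05

    def test_duplicated_predictors_grouped(self, rng):
        n = 40
        x = rng.standard_normal(n)
        prot = pd.DataFrame({f"s{i}": [x[i], x[i], rng.standard_normal()]
                             for i in range(n)},
                            index=["P0", "P0dup", "Pnoise"])
        y = pd.Series(x + 0.05 * rng.standard_normal(n),
                      index=prot.columns)
        rank = elasticnet_predictors(prot, y, seed=0)  # must not crash
        nz = rank.coefficients[rank.coefficients != 0]
        assert {"P0", "P0dup"} <= set(nz.index)

    def test_min_samples_enforced(self, rng):
        prot = pd.DataFrame(rng.standard_normal((5, 10)),
                            columns=[f"s{i}" for i in range(10)])
        y = pd.Series(rng.standard_normal(10), index=prot.columns)
        with pytest.raises(ValueError, match="15"):
            elasticnet_predictors(prot, y)


def test_imputed_mask_propagation(rng):
    """Imputed entries must never feed downstream statistics."""
    from mmpt.outcomes import compute_ipcy
    from mmpt.proteomics import drug_protein_network
    resp = pd.Series({"a": 0.5, "b": 0.4}, name="pt")
    imputed = pd.Series({"a": True, "b": False})
    ipcy, matched = compute_ipcy(resp, ["a", "b"], imputed=imputed)
    assert matched == ["b"]
    assert ipcy == pytest.approx(0.4)

    prot = pd.DataFrame(rng.standard_normal((3, 12)),
                        index=["P0", "P1", "P2"],
                        columns=[f"s{i}" for i in range(12)])
    drugs = pd.DataFrame({"d": prot.loc["P0"]})
    mask_all = pd.DataFrame(True, index=drugs.index, columns=drugs.columns)
    edges = pd.DataFrame({"a": ["P0"], "b": ["P1"]})
    g, assoc = drug_protein_network(prot, drugs, edges, imputed_mask=mask_all)
    assert len(assoc) == 0  # everything masked -> no usable pairs
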