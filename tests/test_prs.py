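"""Polygenic score construction, quintiles, and stratified effects."""

import numpy as np
import pandas as pd
import pytest

from bestgene.prs import (assign_quintiles, iss_or_by_group,
                          ldpred_inf_weights, prs_r2, score_samples,
                          stratified_effects)


class TestLDpredInf:
    def test_scalar_closed_form(self):
        # ridge M/(N h2) = 100/(1000*0.5) = 0.2 -> shrink 1/1.2
        w = ldpred_inf_weights(np.array([0.12]), [np.eye(1)], 1000, 0.5, 100)
        assert w[0] == pytest.approx(0.12 / 1.2)

    def test_vanishing_h2_kills_weights(self):
        w = ldpred_inf_weights(np.array([0.5, -0.3]), [np.eye(2)], 1000, 1e-6, 2)
        assert np.all(np.abs(w) < 1e-3)

    def test_perfectly_correlated_snps_split_signal(self):
        D = np.ones((2, 2))
        beta = np.array([0.2, 0.2])
        M, N, h2 = 2, 10_000, 0.5
        w = ldpred_inf_weights(beta, [D], N, h2, M)
        ridge = M / (N * h2)
        # closed form for (ridge*I + J)^-1 (b, b)' = b/(ridge+2) * (1, 1)'
        assert w == pytest.approx([0.2 / (ridge + 2)] * 2)

    def test_block_processing_matches_joint_solve(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        D1 = A @ A.T / 3 + np.eye(3)
        beta = rng.normal(size=5)
        w = ldpred_inf_weights(beta, [D1, np.eye(2)], 5000, 0.3, 5)
        ridge = 5 / (5000 * 0.3)
        w1 = np.linalg.solve(ridge * np.eye(3) + D1, beta[:3])
        assert w[:3] == pytest.approx(w1)

    def test_non_psd_block_rejected(self):
        D = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            ldpred_inf_weights(np.array([0.1, 0.1]), [D], 1000, 0.5, 2)

    def test_invalid_h2(self):
        with pytest.raises(ValueError):
            ldpred_inf_weights(np.array([0.1]), [np.eye(1)], 1000, 1.5, 1)


def weight_table(ids, weights, alleles=None):
    return pd.DataFrame({
        "variant_id": ids,
        "effect_allele": alleles if alleles is not None else ["A"] * len(ids),
        "weight": weights,
    })


class TestScoreSamples:
    def test_zero_weights_zero_score(self):
        D = np.ones((4, 3))
        w = weight_table(["v0", "v1", "v2"], [0.0, 0.0, 0.0])
        assert np.allclose(score_samples(D, w, ["v0", "v1", "v2"]), 0.0)

    def test_single_snp_weight_one_returns_dosage(self):
        D = np.array([[0.0], [1.0], [2.0]])
        w = weight_table(["v0"], [1.0])
        assert score_samples(D, w, ["v0"]).tolist() == [0.0, 1.0, 2.0]

    def test_matches_brute_force_dot_product(self):
        rng = np.random.default_rng(1)
        D = rng.binomial(2, 0.3, size=(100, 50)).astype(float)
        wts = rng.normal(size=50)
        ids = [f"v{i}" for i in range(50)]
        got = score_samples(D, weight_table(ids, wts), ids)
        assert np.allclose(got, D @ wts)

    def test_allele_mismatch_flips_weight(self):
        D = np.array([[0.0], [2.0]])
        w = weight_table(["v0"], [0.5], alleles=["A"])
        flipped = score_samples(D, w, ["v0"], dosage_alt_alleles={"v0": "G"})
        straight = score_samples(D, w, ["v0"], dosage_alt_alleles={"v0": "A"})
        assert np.allclose(flipped, -straight)

    def test_missing_dosage_imputed_to_mean(self):
        D = np.array([[0.0], [2.0], [-1.0]])  # missing coded -1
        got = score_samples(D, weight_table(["v0"], [1.0]), ["v0"])
        assert got[2] == pytest.approx(2 * (2.0 / 2 / 2))  # 2*AF = 1.0

    def test_no_overlap_errors(self):
        with pytest.raises(ValueError):
            score_samples(np.ones((2, 1)), weight_table(["x"], [1.0]), ["v0"])

    def test_scoring_is_linear_in_weights(self):
        rng = np.random.default_rng(2)
        D = rng.binomial(2, 0.4, size=(50, 10)).astype(float)
        ids = [f"v{i}" for i in range(10)]
        w1, w2 = rng.normal(size=10), rng.normal(size=10)
        s = score_samples(D, weight_table(ids, w1 + w2), ids)
        assert np.allclose(
            s,
            score_samples(D, weight_table(ids, w1), ids)
            + score_samples(D, weight_table(ids, w2), ids),
        )


class TestQuintiles:
    def test_ten_distinct_scores(self):
        q = assign_quintiles(np.arange(10, dtype=float))
        assert q.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_equal_group_sizes_at_study_scale(self):
        rng = np.random.default_rng(3)
        q = assign_quintiles(rng.normal(size=34_120))
        assert np.bincount(q)[1:].tolist() == [6824] * 5

    def test_remainders_go_to_lower_groups(self):
        q = assign_quintiles(np.arange(12, dtype=float))
        assert np.bincount(q)[1:].tolist() == [3, 3, 2, 2, 2]

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        q = assign_quintiles(rng.normal(size=997))
        assert q.min() == 1 and q.max() == 5 and len(q) == 997

    def test_all_equal_scores_stable_order(self):
        q = assign_quintiles(np.zeros(10))
        assert q.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_monotone_in_score(self):
        rng = np.random.default_rng(5)
        ps = rng.normal(size=503)
        q = assign_quintiles(ps)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= 0)


def stratified_data(seed=0, n=30_000, effect=-0.4, interaction=0.0):
    rng = np.random.default_rng(seed)
    quintiles = rng.integers(1, 6, size=n)
    cls = np.where(rng.random(n) < 0.03, "missense",
                   np.where(rng.random(n) < 0.01, "lof", "none"))
    eff = np.where(cls == "none", 0.0, effect + interaction * (quintiles - 3))
    z = rng.normal(size=n) + eff
    pheno = pd.DataFrame({"z_height": z, "iss": z < -2})
    return pheno, cls, quintiles


class TestStratifiedEffects:
    def test_recovers_effect_in_every_stratum(self):
        pheno, cls, q = stratified_data(effect=-0.5)
        table, het = stratified_effects(pheno, cls, q)
        for _, row in table.iterrows():
            assert row["effect"] - 3 * row["se"] < -0.5 < row["effect"] + 3 * row["se"]

    def test_additive_data_shows_no_heterogeneity(self):
        pheno, cls, q = stratified_data(seed=1, effect=-0.4)
        _, het = stratified_effects(pheno, cls, q)
        for h in het.values():
            assert h.p_het > 0.01

    def test_planted_interaction_detected(self):
        pheno, cls, q = stratified_data(seed=2, n=60_000, effect=-0.5,
                                        interaction=0.25)
        _, het = stratified_effects(pheno, cls, q)
        assert het["missense"].p_het < 0.01
        assert het["missense"].i2 > 0.5

    def test_empty_class_quintile_omitted(self):
        pheno, cls, q = stratified_data(n=2000)
        cls = np.where((q == 5) & (cls == "lof"), "none", cls)
        table, _ = stratified_effects(pheno, cls, q)
        lof_rows = table[table["carrier_class"] == "lof"]
        assert 5 not in lof_rows["quintile"].tolist()


class TestISSOddsRatios:
    def test_reference_is_unity_and_planted_risk_recovered(self):
        rng = np.random.default_rng(6)
        n = 50_000
        q = rng.integers(1, 6, size=n)
        cls = np.full(n, "none", dtype=object)
        p = np.where(q == 1, 0.10, 0.022)  # ~5x odds in PS1
        iss = rng.random(n) < p
        pheno = pd.DataFrame({"z_height": np.zeros(n), "iss": iss})
        table = iss_or_by_group(pheno, cls, q)
        ref = table[table["reference"]]
        assert ref["odds_ratio"].iloc[0] == 1.0
        truth = (0.10 / 0.90) / (0.022 / 0.978)
        row = table[(table.quintile == 1) & (table.carrier_status == "non-carrier")].iloc[0]
        assert row["ci_low"] <= truth <= row["ci_high"]

    def test_degenerate_group_removed_by_se_rule(self):
        rng = np.random.default_rng(7)
        n = 5000
        q = rng.integers(1, 6, size=n)
        cls = np.where(rng.random(n) < 0.02, "lof", "none")
        iss = rng.random(n) < 0.03
        iss[(q == 5) & (cls == "lof")] = False  # zero-case cell
        pheno = pd.DataFrame({"z_height": np.zeros(n), "iss": iss})
        table = iss_or_by_group(pheno, cls, q)
        assert table[(table.quintile == 5) & (table.carrier_status == "carrier")].empty

    def test_reference_without_cases_errors(self):
        pheno = pd.DataFrame({"z_height": np.zeros(100),
                              "iss": np.zeros(100, dtype=bool)})
        with pytest.raises(ValueError):
            iss_or_by_group(pheno, np.full(100, "none"), np.tile(np.arange(1, 6), 20))


class TestPRSR2:
    def test_known_variance_share(self):
        rng = np.random.default_rng(8)
        ps = rng.normal(0, np.sqrt(0.2), size=100_000)
        z = ps + rng.normal(0, np.sqrt(0.8), size=100_000)
        assert prs_r2(ps, z) == pytest.approx(0.2, abs=0.01)
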