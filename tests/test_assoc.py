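"""Phenotype preparation, gene sets, burden and SKAT tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bestgene.assoc import (ANNOTATION_FLAGS, adjust_significance,
                            build_gene_sets, burden_scores, burden_test,
                            define_iss, normalize_height, skat_test)


def pheno_frame(z, iss=None, sex=None, age=None):
    n = len(z)
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "z_height": z,
        "iss": iss if iss is not None else z < -2,
        "sex": sex if sex is not None else np.zeros(n),
        "age": age if age is not None else np.full(n, 55.0),
    })


class TestNormalizeHeight:
    def make_samples(self, n=4000, age_slope=0.0, seed=0):
        rng = np.random.default_rng(seed)
        sex = rng.integers(0, 2, n)
        age = rng.uniform(45, 75, n)
        pcs = rng.normal(size=(n, 5))
        height = (
            np.where(sex == 1, 175.6, 162.2) + age_slope * (age - 60)
            + 6.6 * rng.normal(size=n)
        )
        return pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "sex": np.where(sex == 1, "M", "F"), "age": age,
            **{f"pc{i+1}": pcs[:, i] for i in range(5)},
            "height_cm": height,
        })

    def test_unit_moments_within_sex(self):
        df = self.make_samples()
        z = normalize_height(df).merge(df[["sample_id", "sex"]], on="sample_id")
        for _, grp in z.groupby("sex"):
            assert abs(grp["z_height"].mean()) < 1e-6
            assert grp["z_height"].std(ddof=1) == pytest.approx(1.0, abs=1e-6)

    def test_reduces_to_plain_zscore_without_covariate_effects(self):
        df = self.make_samples(age_slope=0.0)
        z = normalize_height(df).set_index("sample_id")["z_height"]
        f = df[df.sex == "F"]
        plain = (f.height_cm - f.height_cm.mean())
        # residualizing on unrelated covariates barely changes the z-scores
        fitted = z.loc[f.sample_id].to_numpy()
        plain = (plain / plain.std(ddof=1)).to_numpy()
        assert np.corrcoef(fitted, plain)[0, 1] > 0.998

    def test_residuals_uncorrelated_with_planted_age_slope(self):
        df = self.make_samples(n=10_000, age_slope=-0.3, seed=1)
        z = normalize_height(df).merge(df[["sample_id", "age"]], on="sample_id")
        r = np.corrcoef(z["z_height"], z["age"])[0, 1]
        assert abs(r) < 0.01

    def test_missing_covariates_dropped(self):
        df = self.make_samples(n=200)
        df.loc[3, "age"] = np.nan
        z = normalize_height(df)
        assert len(z) == 199

    def test_small_stratum_rejected(self):
        df = self.make_samples(n=40)
        with pytest.raises(ValueError):
            normalize_height(df)


class TestDefineISS:
    def test_strict_threshold(self):
        out = define_iss(pd.DataFrame({"z_height": [-2.1, -2.0, -1.9, 0.0]}))
        assert out["iss"].tolist() == [True, False, False, False]

    def test_gaussian_tail_prevalence(self):
        rng = np.random.default_rng(0)
        out = define_iss(pd.DataFrame({"z_height": rng.normal(size=200_000)}))
        assert out["iss"].mean() == pytest.approx(sps.norm.cdf(-2), abs=0.002)


class TestGeneSets:
    def frame(self, flag_map):
        rows = []
        for gene, flags in flag_map.items():
            rows.append({"gene": gene,
                         **{f: f in flags for f in ANNOTATION_FLAGS}})
        return pd.DataFrame(rows)

    def test_all_32_cells_enumerated(self):
        sets = build_gene_sets(self.frame({"G1": {"GWAS"}}))
        assert sets.n_cells == 32
        assert sets.n_nonempty == 1

    def test_named_set_definitions(self):
        sets = build_gene_sets(self.frame({
            "A": set(ANNOTATION_FLAGS),                       # all five
            "B": set(ANNOTATION_FLAGS) - {"GWAS"},            # four, no GWAS
            "C": {"HGMD_TALL"},
            "D": {"HGMD_SHORT", "OMIM_SHORT"},
            "E": {"GWAS"},
        }))
        assert sets.named["Set1"] == ["A"]
        assert sets.named["Set2"] == ["B"]
        assert sets.named["Bidirectional"] == ["A", "B"]
        assert sets.named["Tall"] == ["C"]
        assert sets.named["Short"] == ["D"]

    def test_tall_only_is_not_bidirectional(self):
        sets = build_gene_sets(self.frame({"C": {"HGMD_TALL"}}))
        assert sets.named["Tall"] == ["C"]
        assert sets.named["Bidirectional"] == []

    def test_flagless_gene_rejected(self):
        with pytest.raises(ValueError):
            build_gene_sets(self.frame({"G1": set()}))


class TestBurden:
    def test_single_variant_unit_equals_marginal_regression(self):
        rng = np.random.default_rng(3)
        g = (rng.random(2000) < 0.02).astype(float)[:, None]
        z = -0.5 * g[:, 0] + rng.normal(size=2000)
        res = burden_test(g, pheno_frame(z), "G", "protein_altering", "linear")
        import statsmodels.api as sm
        fit = sm.OLS(z, sm.add_constant(g[:, 0])).fit()
        assert res.effect == pytest.approx(fit.params[1], rel=1e-12)
        assert res.p == pytest.approx(fit.pvalues[1], rel=1e-12)

    def test_burden_invariant_to_variant_order(self):
        rng = np.random.default_rng(4)
        G = (rng.random((500, 6)) < 0.05).astype(float)
        assert np.allclose(burden_scores(G), burden_scores(G[:, ::-1]))

    def test_carrier_aggregation_mode(self):
        G = np.array([[1, 1], [0, 1], [0, 0]], dtype=float)
        assert burden_scores(G, "carrier").tolist() == [1.0, 1.0, 0.0]

    def test_zero_carriers_flagged_untestable(self):
        G = np.zeros((100, 2))
        res = burden_test(G, pheno_frame(np.zeros(100)), "G", "m", "linear")
        assert res.flag == "untestable" and np.isnan(res.effect)

    def test_linear_recovery_of_planted_effect(self):
        rng = np.random.default_rng(5)
        n = 20_000
        G = (rng.random((n, 30)) < 0.002).astype(float)
        beta = -0.35
        z = G.sum(1) * beta + rng.normal(size=n)
        res = burden_test(G, pheno_frame(z), "set", "m", "linear")
        assert abs(res.effect - beta) < 3.3 * res.se
        assert res.p < 1e-4

    def test_binary_burden_equals_mean_contrast(self):
        rng = np.random.default_rng(6)
        n = 5000
        G = (rng.random((n, 1)) < 0.05).astype(float)
        z = rng.normal(size=n) - 0.3 * G[:, 0]
        res = burden_test(G, pheno_frame(z), "G", "m", "linear")
        carrier, non = z[G[:, 0] > 0], z[G[:, 0] == 0]
        assert res.effect == pytest.approx(carrier.mean() - non.mean(), rel=1e-9)

    def test_logistic_odds_ratio_recovery(self):
        rng = np.random.default_rng(7)
        n = 30_000
        g = (rng.random(n) < 0.05).astype(float)
        p = np.where(g > 0, 0.06, 0.023)
        y = rng.random(n) < p
        truth = (0.06 / 0.94) / (0.023 / 0.977)
        res = burden_test(g[:, None], pheno_frame(np.zeros(n), iss=y),
                          "G", "m", "logistic", logistic_covariates=())
        assert res.ci_low <= truth <= res.ci_high
        assert res.ac_case == int(g[y].sum())
        assert res.ac_control == int(g[~y].sum())

    def test_separation_falls_back_to_firth(self):
        n = 200
        g = np.r_[np.ones(8), np.zeros(n - 8)]
        y = g > 0  # complete separation
        res = burden_test(g[:, None], pheno_frame(np.zeros(n), iss=y),
                          "G", "m", "logistic", logistic_covariates=())
        assert res.flag == "firth"
        assert np.isfinite(res.effect) and np.isfinite(res.se)


class TestSKAT:
    def test_single_variant_reduces_to_score_test(self):
        rng = np.random.default_rng(8)
        n = 1500
        g = (rng.random(n) < 0.03).astype(float)
        z = rng.normal(size=n) - 0.4 * g
        res = skat_test(g[:, None], pheno_frame(z), "G", "m", weights="flat")
        r = z - z.mean()
        sigma2 = r @ r / (n - 1)
        u = g @ r
        v = sigma2 * (g @ g - n * g.mean() ** 2)
        p_score = 2 * sps.norm.sf(abs(u) / np.sqrt(v))
        assert res.p == pytest.approx(p_score, rel=1e-6)

    def test_q_nonnegative_and_all_zero_untestable(self):
        res = skat_test(np.zeros((50, 3)), pheno_frame(np.random.default_rng(0).normal(size=50)),
                        "G", "m")
        assert res.flag == "untestable"

    def test_matches_permutation_oracle(self):
        """Small-sample SKAT p agrees with a phenotype-permutation null."""
        rng = np.random.default_rng(9)
        n, k = 200, 5
        G = (rng.random((n, k)) < 0.08).astype(float)
        z = rng.normal(size=n) - 0.35 * G[:, 0]
        res = skat_test(G, pheno_frame(z), "G", "m", weights="flat")
        r = z - z.mean()
        A = G  # flat weights
        q_obs = float(((A.T @ r) ** 2).sum())
        n_perm = 200_000
        q_perm = np.empty(n_perm)
        chunk = 20_000
        for s in range(0, n_perm, chunk):
            R = np.array([rng.permutation(r) for _ in range(chunk)])
            q_perm[s:s + chunk] = ((R @ A) ** 2).sum(axis=1)
        p_mc = float((q_perm >= q_obs).mean())
        se = np.sqrt(max(p_mc * (1 - p_mc), 1e-9) / n_perm)
        # permutation conditions on the observed residuals; allow both MC
        # error and the asymptotic-vs-exact gap at n=200
        assert abs(res.p - p_mc) < max(3 * se, 0.15 * p_mc + 2e-4)

    def test_planted_effects_shrink_p(self):
        rng = np.random.default_rng(10)
        n = 4000
        G = (rng.random((n, 12)) < 0.01).astype(float)
        z0 = rng.normal(size=n)
        p_null = skat_test(G, pheno_frame(z0), "G", "m").p
        z1 = z0 - 0.8 * G.sum(1)
        p_alt = skat_test(G, pheno_frame(z1), "G", "m").p
        assert p_alt < p_null


class TestAdjustSignificance:
    def test_bonferroni_boundaries(self):
        from bestgene.assoc import AssocResult
        mk = lambda p: AssocResult("G", "m", "burden_linear", 0, 1, -2, 2, p, 10)
        table = adjust_significance([mk(0.009), mk(0.011)], 5)
        assert table["significant"].tolist() == [True, False]
        table = adjust_significance([mk(0.049)], 1)
        assert table["significant"].tolist() == [True]
        with pytest.raises(ValueError):
            adjust_significance([mk(0.5)], 0)
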