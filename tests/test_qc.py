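"""Sample/variant QC cascade, relatedness pruning, and analysis masks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bestgene.config import QCThresholds
from bestgene.qc import (build_masks, external_af_concordance, filter_samples,
                         filter_variants, remove_related)


def passing_sample(sample_id="S0", **kw):
    rec = dict(
        sample_id=sample_id, sex="F", age=55.0, height_cm=165.0,
        ancestry_flag=True, aneuploidy_flag=False, het_rate=0.19,
        n_non_ref=60_000, n_singletons=10, het_hom_ratio=1.55, ti_tv=3.0,
        call_rate=0.999, chip_het_concordance=0.995,
    )
    rec.update(kw)
    return rec


def sample_frame(rows):
    return pd.DataFrame(rows)


class TestFilterSamples:
    def test_all_passing_kept(self):
        kept, att = filter_samples(sample_frame(
            [passing_sample(f"S{i}") for i in range(5)]))
        assert len(kept) == 5
        assert att["removed"].sum() == 0

    @pytest.mark.parametrize("field, value", [
        ("het_rate", 0.22), ("het_rate", 0.16),
        ("n_non_ref", 80_001), ("n_singletons", 201),
        ("het_hom_ratio", 1.29), ("het_hom_ratio", 1.86),
        ("call_rate", 0.984), ("chip_het_concordance", 0.97),
        ("ancestry_flag", False), ("aneuploidy_flag", True),
    ])
    def test_single_failure_excludes(self, field, value):
        kept, _ = filter_samples(sample_frame([passing_sample(**{field: value})]))
        assert kept == []

    @pytest.mark.parametrize("field, value", [
        ("het_rate", 0.21), ("het_rate", 0.17),     # window is inclusive
        ("n_non_ref", 80_000), ("n_singletons", 200),  # strict '>'
        ("het_hom_ratio", 1.3), ("het_hom_ratio", 1.85),
        ("call_rate", 0.985),
    ])
    def test_boundary_values_kept(self, field, value):
        kept, _ = filter_samples(sample_frame([passing_sample(**{field: value})]))
        assert kept == ["S0"]

    def test_titv_rule_off_by_default_but_available(self):
        row = passing_sample(ti_tv=3.0)
        kept, _ = filter_samples(sample_frame([row]))
        assert kept == ["S0"]
        kept, _ = filter_samples(sample_frame([row]),
                                 QCThresholds(apply_titv=True))
        assert kept == []

    def test_missing_metric_errors_with_names(self):
        df = sample_frame([passing_sample()])
        df.loc[0, "het_rate"] = np.nan
        with pytest.raises(ValueError, match="S0.*het_rate"):
            filter_samples(df)

    def test_attrition_accounts_for_every_removal(self):
        rows = [passing_sample(f"S{i}") for i in range(10)]
        rows[1]["het_rate"] = 0.25
        rows[2]["n_singletons"] = 500
        rows[3]["call_rate"] = 0.5
        rows[4]["het_rate"] = 0.25
        rows[4]["call_rate"] = 0.5   # fails two criteria, counted once
        df = sample_frame(rows)
        kept, att = filter_samples(df)
        assert len(kept) == 6
        assert att["removed"].sum() == len(df) - len(kept)
        assert att["remaining"].iloc[-1] == len(kept)

    def test_conjunctive_cascade_order_insensitive(self):
        rows = [passing_sample(f"S{i}") for i in range(8)]
        rows[2]["het_rate"] = 0.3
        rows[5]["n_non_ref"] = 100_000
        df = sample_frame(rows)
        kept1, _ = filter_samples(df)
        kept2, _ = filter_samples(df.iloc[::-1].reset_index(drop=True))
        assert sorted(kept1) == sorted(kept2)


class TestRemoveRelated:
    def test_one_pair_one_removed(self):
        kept = remove_related(["A", "B", "C"], [("A", "B", 2)])
        assert len(kept) == 2 and "C" in kept

    def test_third_degree_pair_kept(self):
        kept = remove_related(["A", "B"], [("A", "B", 3)])
        assert kept == ["A", "B"]

    def test_triangle_removes_two(self):
        kept = remove_related(["A", "B", "C"], [
            ("A", "B", 1), ("B", "C", 2), ("A", "C", 2)])
        assert len(kept) == 1

    def test_no_close_pair_survives_random_graphs(self):
        # brute-force check on random kinship graphs: the pruned set never
        # contains a close pair, and the removal is never larger than the
        # number of close pairs (each removal kills at least one pair)
        rng = np.random.default_rng(2)
        ids = [f"S{i}" for i in range(8)]
        for _ in range(25):
            pairs = [
                (ids[i], ids[j], int(rng.integers(1, 4)))
                for i, j in itertools.combinations(range(8), 2)
                if rng.random() < 0.25
            ]
            kept = remove_related(ids, pairs)
            kept_set = set(kept)
            close = [(i, j) for i, j, d in pairs if d <= 2]
            assert not any(i in kept_set and j in kept_set for i, j in close)
            assert 8 - len(kept) <= len(close)

    def test_deterministic(self):
        pairs = [("A", "B", 2), ("B", "C", 2), ("D", "E", 1)]
        k1 = remove_related(list("ABCDE"), pairs)
        k2 = remove_related(list("ABCDE"), list(reversed(pairs)))
        assert k1 == k2


class TestFilterVariants:
    def frame(self, **kw):
        rec = dict(variant_id="v1", call_rate=1.0, hwe_p=1.0)
        rec.update(kw)
        return pd.DataFrame([rec])

    def test_call_rate_below_cutoff_dropped(self):
        assert filter_variants(self.frame(call_rate=0.985)).empty

    def test_hwe_violation_dropped(self):
        assert filter_variants(self.frame(hwe_p=1e-11)).empty

    def test_boundaries_kept(self):
        assert len(filter_variants(self.frame(call_rate=0.99))) == 1
        assert len(filter_variants(self.frame(hwe_p=1e-10))) == 1


class TestExternalAFConcordance:
    def test_inflated_count_dropped(self):
        p, keep = external_af_concordance(100, 60_000, 1e-5)
        assert p < 1e-7 and not keep

    def test_concordant_count_kept(self):
        p, keep = external_af_concordance(12, 60_000, 2e-4)
        assert keep and p > 0.1

    def test_zero_count_kept(self):
        _, keep = external_af_concordance(0, 60_000, 1e-3)
        assert keep

    def test_missing_reference_unfilterable(self):
        p, keep = external_af_concordance(5, 60_000, None)
        assert keep and np.isnan(p)

    def test_absent_in_reference_uses_floor(self):
        p, keep = external_af_concordance(50, 60_000, 0.0, ref_panel_size=64_000)
        assert not keep  # 50 observed vs expected ~0.5 under the floor

    def test_matches_monte_carlo_binomial(self):
        ac, an, af = 9, 20_000, 2e-4
        p, _ = external_af_concordance(ac, an, af)
        rng = np.random.default_rng(7)
        n_sim = 200_000
        draws = rng.binomial(an, af, size=n_sim)
        # two-sided: outcomes at most as probable as the observed one
        from scipy.stats import binom
        p_obs = binom.pmf(ac, an, af)
        mc = float((binom.pmf(draws, an, af) <= p_obs * (1 + 1e-9)).mean())
        se = np.sqrt(mc * (1 - mc) / n_sim)
        assert abs(p - mc) < 3 * se


def variant_row(vid, gene, cls, impact, ac, an=200_000, **kw):
    rec = dict(variant_id=vid, gene=gene, consequence_class=cls, impact=impact,
               cohort_ac=ac, cohort_an=an, call_rate=1.0, hwe_p=1.0)
    rec.update(kw)
    return rec


class TestBuildMasks:
    def test_mask_membership_rules(self):
        variants = pd.DataFrame([
            variant_row("v1", "G1", "stop_gained", "high", 10),      # maf 5e-5
            variant_row("v2", "G1", "missense", "moderate", 10),
            variant_row("v3", "G1", "missense", "moderate", 40),     # maf 2e-4
            variant_row("v4", "G1", "other", "other", 2),
        ])
        masks, genes = build_masks(variants)
        assert masks["protein_altering"].variants_by_gene["G1"] == ["v1", "v2"]
        assert masks["ptv"].variants_by_gene["G1"] == ["v1"]

    def test_ptv_subset_of_protein_altering(self, small_cohort):
        masks, _ = build_masks(
            filter_variants(small_cohort.variants))
        for gene, ptv_ids in masks["ptv"].variants_by_gene.items():
            pa = set(masks["protein_altering"].variants_by_gene.get(gene, []))
            assert set(ptv_ids) <= pa

    def test_cumulative_ac_filter(self):
        variants = pd.DataFrame(
            [variant_row(f"v{i}", "G1", "missense", "moderate", 1)
             for i in range(19)]
            + [variant_row(f"w{i}", "G2", "missense", "moderate", 2)
               for i in range(10)]
        )
        masks, genes = build_masks(variants)
        assert "G1" not in masks["protein_altering"].variants_by_gene  # AC 19
        assert "G2" in masks["protein_altering"].variants_by_gene      # AC 20
        row = genes.set_index("gene").loc["G1"]
        assert row["cumulative_ac"] == 19 and not row["tested"]
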