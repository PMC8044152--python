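"""Exome cohort sample/variant QC cascade and rare-variant analysis masks.

Sample filters (ancestry, aneuploidy, heterozygosity window, non-reference
and singleton counts, het/hom ratio, call rate, chip concordance),
relatedness pruning, variant filters (call rate, Hardy-Weinberg exact test,
external-reference allele-frequency concordance), and the construction of
the protein-altering and PTV variant masks with the per-gene cumulative
allele-count filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import QCThresholds
from .stats import hwe_exact_p

logger = logging.getLogger(__name__)

PTV_CLASSES = {"stop_gained", "frameshift", "splice_acceptor", "splice_donor"}

SAMPLE_METRICS = [
    "ancestry_flag", "aneuploidy_flag", "het_rate", "n_non_ref",
    "n_singletons", "het_hom_ratio", "ti_tv", "call_rate",
]


# ----------------------------------------------------------------------
# Sample-level filters


def filter_samples(
    samples: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply the sample QC cascade; returns kept ids and an attrition table.

    Criteria are conjunctive, so the kept set does not depend on order; the
    attrition table reports, in application order, how many samples each
    criterion removed from those still standing.
    """
    thr = thresholds or QCThresholds()
    for col in SAMPLE_METRICS:
        if col not in samples.columns:
            raise ValueError(f"sample table missing required metric {col!r}")
        missing = samples[col].isna()
        if missing.any():
            sid = samples.loc[missing, "sample_id"].iloc[0]
            raise ValueError(f"sample {sid!r} missing required metric {col!r}")

    criteria: list[tuple[str, pd.Series]] = [
        ("ancestry", ~samples["ancestry_flag"].astype(bool)),
        ("sex_chromosome_aneuploidy", samples["aneuploidy_flag"].astype(bool)),
        ("heterozygosity_window",
         (samples["het_rate"] < thr.het_rate_low) | (samples["het_rate"] > thr.het_rate_high)),
        ("non_reference_count", samples["n_non_ref"] > thr.max_non_ref),
        ("singleton_count", samples["n_singletons"] > thr.max_singletons),
        ("het_hom_ratio",
         (samples["het_hom_ratio"] < thr.het_hom_low) | (samples["het_hom_ratio"] > thr.het_hom_high)),
        ("call_rate", samples["call_rate"] < thr.sample_call_rate),
    ]
    if thr.apply_titv:
        criteria.append(("ti_tv", samples["ti_tv"] > thr.titv_max))
    if "chip_het_concordance" in samples.columns:
        conc = samples["chip_het_concordance"]
        criteria.append(("chip_concordance", conc.notna() & (conc < thr.chip_concordance)))

    alive = pd.Series(True, index=samples.index)
    rows = []
    for name, fails in criteria:
        removed = int((alive & fails).sum())
        alive &= ~fails
        rows.append({"criterion": name, "removed": removed, "remaining": int(alive.sum())})
    attrition = pd.DataFrame(rows)
    kept = samples.loc[alive, "sample_id"].tolist()
    return kept, attrition


def remove_related(
    kept_ids: list[str], kinship_pairs: list[tuple[str, str, int]],
    max_degree: int = 2,
) -> list[str]:
    """Prune one member of every related pair of degree <= ``max_degree``.

    Greedy: repeatedly remove the sample with the most remaining close-kin
    connections (ties broken by sample id), until no close pair remains.
    Deterministic for a given input set.
    """
    kept = set(kept_ids)
    edges = {
        frozenset((i, j))
        for i, j, deg in kinship_pairs
        if deg <= max_degree and i in kept and j in kept and i != j
    }
    while edges:
        counts: dict[str, int] = {}
        for e in edges:
            for s in e:
                counts[s] = counts.get(s, 0) + 1
        victim = sorted(counts, key=lambda s: (-counts[s], s))[0]
        kept.discard(victim)
        edges = {e for e in edges if victim not in e}
    return [s for s in kept_ids if s in kept]


# ----------------------------------------------------------------------
# Variant-level filters


def filter_variants(
    variants: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Keep variants with call rate >= 0.99 and HWE exact p >= 1e-10."""
    thr = thresholds or QCThresholds()
    if variants["hwe_p"].isna().any():
        raise ValueError("hwe_p must be computed for all variants")
    keep = (variants["call_rate"] >= thr.variant_call_rate) & (
        variants["hwe_p"] >= thr.hwe_p
    )
    return variants[keep]


def external_af_concordance(
    cohort_ac: int, cohort_an: int, ref_af: float | None,
    p_cutoff: float = 1e-7, ref_panel_size: int | None = None,
) -> tuple[float, bool]:
    """Two-sided binomial test of the cohort allele count against an external
    reference allele frequency; keep iff p >= cutoff.

    A missing reference frequency keeps the variant (unfilterable: the rule
    only applies to variants observed in the reference).  ``ref_af == 0``
    with a known reference panel size uses the frequency floor
    1/(2 * panel size) for an absent-but-covered variant.
    """
    if cohort_an <= 0:
        raise ValueError("cohort_an must be positive")
    if ref_af is None or (isinstance(ref_af, float) and np.isnan(ref_af)):
        return float("nan"), True
    if not 0.0 <= ref_af <= 1.0:
        raise ValueError("ref_af must be in [0, 1]")
    if cohort_ac == 0:
        return 1.0, True
    p_ref = ref_af
    if p_ref == 0.0:
        if ref_panel_size is None:
            return float("nan"), True
        p_ref = 1.0 / (2.0 * ref_panel_size)
    p = float(sps.binomtest(int(cohort_ac), int(cohort_an), p_ref).pvalue)
    return p, p >= p_cutoff


def hwe_from_genotypes(geno: np.ndarray) -> float:
    """Convenience: exact HWE p from a 0/1/2 dosage vector (missing = -1)."""
    g = geno[geno >= 0]
    return hwe_exact_p(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))


# ----------------------------------------------------------------------
# Analysis masks


@dataclass
class VariantMask:
    name: str  # "protein_altering" or "ptv"
    maf_cutoff: float
    variants_by_gene: dict[str, list[str]] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted(self.variants_by_gene)

    def variant_ids(self, genes: list[str] | None = None) -> list[str]:
        genes = self.genes() if genes is None else genes
        out: list[str] = []
        for g in genes:
            out.extend(self.variants_by_gene.get(g, []))
        return out


def build_masks(
    variants: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[dict[str, VariantMask], pd.DataFrame]:
    """Build the protein-altering and PTV masks from QC-passed variants.

    protein_altering: VEP impact high (protein truncation) or moderate
    (missense) with within-cohort MAF below the cutoff; ptv: the
    truncating consequence classes at the same cutoff.  Genes whose
    cumulative protein-altering allele count falls below the minimum are
    excluded from gene-level testing; the returned gene table records the
    cumulative AC and exclusion status per gene.
    """
    thr = thresholds or QCThresholds()
    v = variants.copy()
    af = v["cohort_ac"] / v["cohort_an"]
    v["maf"] = np.minimum(af, 1.0 - af)
    rare = v["maf"] < thr.maf_cutoff
    pa = rare & v["impact"].isin(["high", "moderate"])
    ptv = rare & v["consequence_class"].isin(PTV_CLASSES)

    gene_ac = (
        v.loc[pa].groupby("gene")["cohort_ac"].sum().rename("cumulative_ac")
    )
    gene_table = gene_ac.reset_index()
    gene_table["tested"] = gene_table["cumulative_ac"] >= thr.min_cumulative_ac
    tested = set(gene_table.loc[gene_table["tested"], "gene"])

    def _mask(sel: pd.Series, name: str) -> VariantMask:
        by_gene: dict[str, list[str]] = {}
        for gene, grp in v.loc[sel].groupby("gene"):
            if gene in tested:
                by_gene[gene] = grp["variant_id"].tolist()
        return VariantMask(name, thr.maf_cutoff, by_gene)

    masks = {
        "protein_altering": _mask(pa, "protein_altering"),
        "ptv": _mask(ptv, "ptv"),
    }
    return masks, gene_table
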