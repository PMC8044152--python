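"""Synthetic-data generators for every input the pipeline consumes.

Four generators share one root seed through named substreams (catalog /
trials / cohort / functional), so each stage is independently reproducible:

* a gene-disease mutation catalog with planted bidirectional genes;
* a clinical-trial target-indication table with phase-transition outcomes
  in which genetically supported pairs carry a planted Phase I -> Approval
  relative risk, plus the gene-trait evidence table and the
  indication-trait similarity matrix;
* an exome-style cohort: common-SNP dosages with GWAS summary statistics
  (for the polygenic score), rare protein-altering variants with planted
  height effects in the bidirectional gene set, covariates, height, and
  per-sample/per-variant QC metrics with a sprinkling of planted failures;
* a functional-assay table (cGMP activity relative to wild type) for the
  variants of a focal receptor-like gene whose effects follow the activity
  model.

The planted effect structure is calibrated to the study conditions the
pipeline is meant to recover: mean -0.20 SD height per rare alt allele and
an ISS odds ratio near 2.75 in the bidirectional set, a polygenic score
explaining 20% of height variance, and a 4x planted approval relative risk.
A homogeneous -0.20 SD shift cannot produce an odds ratio of 2.75 at the
z < -2 tail (it gives ~1.6), so missense effects are a spike-and-null
mixture whose (fraction, magnitude) pair is solved from the two target
quantities at generation time; see docs/methods.md.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy import stats as sps

from .config import ConfigurationError, SimulationConfig
from .qc import PTV_CLASSES
from .stats import hwe_exact_p

logger = logging.getLogger(__name__)

TRIAL_CATEGORIES = [
    "lipids", "clotting", "reproduction", "height", "glucose",
    "cardiovascular", "metabolic", "other",
]

# focal-gene activity mixture: (weight, low, high) uniform components for
# missense variants; PTVs draw from U(0, 0.1).  The series is deliberately
# rich in supranormal (gain-of-function) alleles -- the focal gene is
# bidirectional, so roughly half its missense variants push activity above
# wild type -- with a distinct low-activity (<0.2) pathogenic cluster.
ACTIVITY_MIXTURE = [(0.10, 0.0, 0.2), (0.36, 0.2, 1.0), (0.54, 1.0, 1.4)]

# mild gain-of-function effect (SD units) of the non-pathogenic missense
# background in the bidirectional set (its tall-direction allelic tail)
GOF_MISSENSE_EFFECT = 0.12


def gene_names(cfg: SimulationConfig) -> list[str]:
    return [f"GENE{i:04d}" for i in range(cfg.n_genes)]


def best_gene_names(cfg: SimulationConfig) -> list[str]:
    return gene_names(cfg)[: cfg.n_best_genes]


# ======================================================================
# Mutation catalog


def simulate_catalog(cfg: SimulationConfig) -> pd.DataFrame:
    """Gene-disease records in which exactly ``n_best_genes`` genes carry
    opposing-direction labels on a shared axis.

    Remaining genes cycle through negative-control patterns: unidirectional
    pairs, benign/molecular labels, single-disease genes (exercising the
    minimum-two-diseases filter), same-direction and opposite-direction
    labels on *different* axes.  Labels are drawn from the lexicon itself so
    the screen's planted recall is exactly 1.
    """
    rng = cfg.rng("catalog")
    import yaml
    from importlib import resources
    with resources.files("bestgene.data").joinpath("lexicon.yaml").open() as fh:
        axes_raw: dict[str, dict[str, list[str]]] = yaml.safe_load(fh)["axes"]
    axis_list = sorted(axes_raw)

    def up(axis: str) -> str:
        return str(rng.choice(axes_raw[axis]["up_terms"]))

    def down(axis: str) -> str:
        return str(rng.choice(axes_raw[axis]["down_terms"]))

    rows: list[dict] = []

    def add(gene: str, disease: str, variant_class: str = "DM") -> None:
        rows.append({"gene": gene, "disease": disease, "variant_class": variant_class})

    genes = gene_names(cfg)
    best = set(best_gene_names(cfg))
    for i, gene in enumerate(genes):
        axis = axis_list[i % len(axis_list)]
        other = axis_list[(i + 1) % len(axis_list)]
        if gene in best:
            add(gene, up(axis).title())
            add(gene, f"{down(axis)}, familial")
            if rng.random() < 0.5:  # extra benign label must not matter
                add(gene, "increased enzyme activity", "DM?")
        else:
            pattern = i % 5
            if pattern == 0:  # unidirectional, two unique diseases
                term = down(axis)
                add(gene, f"{term}, type 1")
                add(gene, f"{term}, type 2")
            elif pattern == 1:  # benign/molecular labels only
                add(gene, "increased enzyme activity")
                add(gene, "decreased cell permeability")
            elif pattern == 2:  # single disease -> min-2 filter drops it
                add(gene, up(axis))
            elif pattern == 3:  # same direction, different axes
                add(gene, up(axis))
                add(gene, up(other))
            else:  # opposite directions on different axes
                add(gene, up(axis))
                add(gene, down(other))
        if rng.random() < 0.3:  # duplicate records collapse downstream
            add(gene, rows[-1]["disease"])
    return pd.DataFrame(rows, columns=["gene", "disease", "variant_class"])


# ======================================================================
# Clinical trials


@dataclass
class TrialData:
    table: pd.DataFrame        # target_gene, indication, reached, category
    evidence: pd.DataFrame     # gene, trait, class, category
    similarity: pd.DataFrame   # indication, trait, value (long form)


def simulate_trials(cfg: SimulationConfig,
                    best_genes: list[str] | None = None) -> TrialData:
    """Target-indication pairs traversing Phase I -> Approval as Bernoulli
    chains, with planted support effects.

    A pair is "supported" when its target carries genetic evidence for a
    trait whose similarity to the pair's indication exceeds
    ``cfg.sim_threshold`` -- exactly the rule the downstream annotation
    applies.  Supported pairs have each per-transition success probability
    multiplied by rr^(1/3) (class-specific rr), so the planted
    Phase I -> Approval risk ratio equals the class rr.
    """
    if cfg.trial_rr <= 0:
        raise ConfigurationError("trial_rr must be positive")
    rng = cfg.rng("trials")
    best_genes = best_gene_names(cfg) if best_genes is None else list(best_genes)

    n_omim = max(1, 3 * max(len(best_genes), 1))
    n_gwasg = max(1, 6 * max(len(best_genes), 1))
    pool = [g for g in gene_names(cfg) if g not in set(best_genes)]
    extra = [f"TGT{i:04d}" for i in range(max(0, n_omim + n_gwasg - len(pool)) + 400)]
    pool = pool + extra
    omim_genes = pool[:n_omim]
    gwas_genes = pool[n_omim : n_omim + n_gwasg]
    unsupported_targets = pool[n_omim + n_gwasg :]

    ev_rows = []
    traits = {}
    for i, (gene, cls) in enumerate(
        [(g, "BEST") for g in best_genes]
        + [(g, "OMIM_unidirectional") for g in omim_genes]
        + [(g, "GWAS") for g in gwas_genes]
    ):
        trait = f"T{i:04d}"
        traits[gene] = trait
        ev_rows.append({
            "gene": gene, "trait": trait, "class": cls,
            "category": TRIAL_CATEGORIES[i % len(TRIAL_CATEGORIES)],
        })
    evidence = pd.DataFrame(ev_rows)

    indications = [f"IND{i:04d}" for i in range(cfg.n_indications)]
    trait_list = sorted(evidence["trait"])
    # each trait gets a handful of semantically matching indications
    n_match = max(2, cfg.n_indications // 50)
    matched: dict[str, list[str]] = {
        t: list(rng.choice(indications, size=n_match, replace=False))
        for t in trait_list
    }
    sim_rows = []
    for t in trait_list:
        match_set = set(matched[t])
        vals = rng.beta(2.0, 6.0, size=len(indications))
        high = rng.beta(40.0, 3.0, size=len(indications))
        for ind, v, hv in zip(indications, vals, high):
            sim_rows.append({
                "indication": ind, "trait": t,
                "value": float(hv if ind in match_set else v),
            })
    similarity = pd.DataFrame(sim_rows)
    sim_lookup = similarity.set_index(["indication", "trait"])["value"]

    class_rr = {"BEST": cfg.trial_rr, "OMIM_unidirectional": cfg.omim_rr,
                "GWAS": cfg.gwas_rr}
    gene_class = dict(zip(evidence["gene"], evidence["class"]))
    gene_cat = dict(zip(evidence["gene"], evidence["category"]))
    base = np.asarray(cfg.phase_attrition, dtype=float)

    n_best_pairs = int(round(cfg.best_target_share * cfg.n_pairs)) if best_genes else 0
    n_omim_pairs = int(round(0.05 * cfg.n_pairs)) if omim_genes else 0
    n_gwas_pairs = int(round(0.08 * cfg.n_pairs)) if gwas_genes else 0
    n_unsup = cfg.n_pairs - n_best_pairs - n_omim_pairs - n_gwas_pairs
    chunks = []
    for genes_pool, count in [
        (best_genes, n_best_pairs), (omim_genes, n_omim_pairs),
        (gwas_genes, n_gwas_pairs), (unsupported_targets, n_unsup),
    ]:
        if count > 0:
            chunks.append(rng.choice(genes_pool, size=count))
    targets = np.concatenate(chunks).astype(object)

    capped_warned = False
    rows = []
    for gene in targets:
        cls = gene_class.get(gene)
        if cls is not None and rng.random() < 0.7:
            indication = str(rng.choice(matched[traits[gene]]))
        else:
            indication = str(rng.choice(indications))
        mult = 1.0
        if cls is not None:
            sim = float(sim_lookup.loc[(indication, traits[gene])])
            if sim > cfg.sim_threshold:
                mult = class_rr[cls] ** (1.0 / 3.0)
        probs = base * mult
        if np.any(probs > 1.0):
            probs = np.minimum(probs, 1.0)
            if not capped_warned:
                warnings.warn(
                    "planted transition probability capped at 1; the realized "
                    "relative risk will fall short of the configured value"
                )
                capped_warned = True
        n_passed = 0
        for p in probs:
            if rng.random() < p:
                n_passed += 1
            else:
                break
        reached = ["PhaseI", "PhaseII", "PhaseIII", "Approved"][n_passed]
        rows.append({
            "target_gene": gene, "indication": indication, "reached": reached,
            "category": gene_cat.get(gene, TRIAL_CATEGORIES[hash(gene) % len(TRIAL_CATEGORIES)]),
        })
    table = pd.DataFrame(rows)
    return TrialData(table, evidence, similarity)


# ======================================================================
# Cohort


@dataclass
class Cohort:
    samples: pd.DataFrame
    variants: pd.DataFrame
    rare_dosages: sparse.csc_matrix
    common_variants: pd.DataFrame
    common_dosages: np.ndarray
    sumstats: pd.DataFrame
    annotations: pd.DataFrame
    kinship_pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._rare_index = {v: i for i, v in enumerate(self.variants["variant_id"])}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def rare_dosage(self, variant_ids: list[str]) -> np.ndarray:
        idx = [self._rare_index[v] for v in variant_ids]
        return np.asarray(self.rare_dosages[:, idx].todense(), dtype=float)

    def subset_samples(self, sample_ids: list[str]) -> "Cohort":
        keep = self.samples["sample_id"].isin(set(sample_ids)).to_numpy()
        rare = self.rare_dosages[keep]
        variants = self.variants.copy()
        ac = np.asarray(rare.sum(axis=0)).ravel()
        variants["cohort_ac"] = ac.astype(int)
        variants["cohort_an"] = 2 * int(keep.sum())
        return Cohort(
            self.samples.loc[keep].reset_index(drop=True),
            variants, sparse.csc_matrix(rare),
            self.common_variants, self.common_dosages[keep],
            self.sumstats, self.annotations,
            [p for p in self.kinship_pairs],
        )


def _assign_spike_effects(variants: pd.DataFrame, cfg: SimulationConfig,
                          best: set, focal_gene: str | None,
                          rng: np.random.Generator) -> None:
    """Plant the missense spike from the realized allele counts.

    Within the maskable bidirectional-set variants (ultra-rare, QC-clean,
    protein-altering) the PTV and focal-gene effects are already fixed; a
    subset of the remaining missense alleles receives one shared large
    negative effect.  The subset's allele count and the effect size are
    solved jointly so that, in this very realization, (i) the allele-
    weighted mean effect equals ``rare_effect_sd`` and (ii) the expected
    per-allele carrier ISS odds ratio equals ``set_iss_or``.  Among the
    solutions the mildest spike (largest allele count) is chosen; if the
    target odds ratio is unattainable for this draw the closest achievable
    planting is used with a warning.
    """
    t = cfg.iss_threshold
    r0 = float(sps.norm.cdf(t))
    maf = variants["cohort_ac"] / variants["cohort_an"]
    maskable = (
        (np.minimum(maf, 1 - maf) < 1e-4)
        & variants["impact"].isin(["high", "moderate"])
        & (variants["call_rate"] >= 0.99)
        & (variants["hwe_p"] >= 1e-10)
        & variants["gene"].isin(best)
    ).to_numpy()
    eff = variants["effect_sd"].to_numpy().copy()
    ac = variants["cohort_ac"].to_numpy().astype(float)
    is_focal = (variants["gene"] == focal_gene).to_numpy()
    is_mis = (variants["consequence_class"] == "missense").to_numpy()
    fixed = maskable & (is_focal | ~is_mis)
    cand = maskable & ~is_focal & is_mis
    ac_total = float(ac[maskable].sum())
    ac_mis = float(ac[cand].sum())
    if ac_total == 0 or ac_mis == 0:
        logger.warning("no maskable missense alleles; spike not planted")
        return
    resid = cfg.rare_effect_sd * ac_total - float(np.sum(ac[fixed] * eff[fixed]))
    if resid >= 0:
        logger.warning("fixed effects already reach the target mean; "
                       "no spike planted")
        return
    risk_fixed = float(np.sum(ac[fixed] * sps.norm.cdf(t - eff[fixed])))
    odds1 = cfg.set_iss_or * r0 / (1 - r0)
    r1_target = odds1 / (1 + odds1)
    # non-spiked missense alleles carry a mild gain-of-function (tall) tail,
    # as expected of the benign background in a bidirectional gene set
    delta = GOF_MISSENSE_EFFECT
    r_null = float(sps.norm.cdf(t - delta))

    def spike_beta(a_s: float) -> float:
        return (resid - delta * (ac_mis - a_s)) / a_s

    def carrier_risk(a_s: float) -> float:
        return (risk_fixed + a_s * sps.norm.cdf(t - spike_beta(a_s))
                + (ac_mis - a_s) * r_null) / ac_total

    grid = np.linspace(max(1.0, 0.002 * ac_mis), ac_mis, 600)
    risks = np.array([carrier_risk(a) for a in grid])
    i_peak = int(np.argmax(risks))
    if risks[i_peak] < r1_target:
        logger.warning(
            "target ISS odds ratio %.2f unattainable in this realization "
            "(max achievable %.2f); planting the maximum",
            cfg.set_iss_or,
            (risks[i_peak] / (1 - risks[i_peak])) / (r0 / (1 - r0)))
        a_star = float(grid[i_peak])
    elif carrier_risk(ac_mis) >= r1_target:
        a_star = ac_mis
    else:
        a_star = float(optimize.brentq(
            lambda a: carrier_risk(a) - r1_target,
            float(grid[i_peak]), ac_mis, xtol=1e-6))
    idx = np.flatnonzero(cand)
    order = idx[rng.permutation(idx.size)]
    csum = np.cumsum(ac[order])
    k = min(int(np.searchsorted(csum, a_star)) + 1, order.size)
    chosen = order[:k]
    ac_sel = float(ac[chosen].sum())
    eff[cand] = delta
    eff[chosen] = (resid - delta * (ac_mis - ac_sel)) / ac_sel
    variants["effect_sd"] = eff


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Generate the full synthetic exome cohort (see module docstring)."""
    if cfg.n_samples < 100:
        raise ConfigurationError("n_samples must be at least 100")
    if cfg.carrier_freq * cfg.n_samples < 1:
        warnings.warn("carrier_freq * n_samples < 1: carrier sets will be empty")
    n = cfg.n_samples
    rng_s = cfg.rng("cohort.samples")
    rng_c = cfg.rng("cohort.common")
    rng_r = cfg.rng("cohort.rare")
    rng_q = cfg.rng("cohort.qc")

    # --- samples and covariates
    sample_ids = [f"S{i:06d}" for i in range(n)]
    sex = rng_s.integers(0, 2, size=n)  # 0 = F, 1 = M
    age = rng_s.uniform(45, 75, size=n)
    pcs = rng_s.normal(0.0, 1.0, size=(n, 5))

    # --- common SNPs, true weights, GWAS summary statistics
    m = cfg.n_common_snps
    af = rng_c.uniform(0.05, 0.5, size=m)
    X = rng_c.binomial(2, af, size=(n, m)).astype(np.int8)
    u = rng_c.normal(0.0, np.sqrt(max(cfg.prs_h2, 1e-12) / m), size=m)
    b_allele = u / np.sqrt(2 * af * (1 - af))
    if cfg.prs_h2 == 0:
        b_allele = np.zeros(m)
    ps_true = (X - 2 * af) @ b_allele
    se_gwas = 1.0 / np.sqrt(cfg.n_gwas * 2 * af * (1 - af))
    beta_hat = b_allele + rng_c.normal(0.0, se_gwas)
    common_ids = [f"snp{j:05d}" for j in range(m)]
    bases = np.array(list("ACGT"))
    common_variants = pd.DataFrame({
        "variant_id": common_ids,
        "chrom": [f"chr{(j % 22) + 1}" for j in range(m)],
        "pos": np.arange(1, m + 1) * 1000,
        "ref": bases[rng_c.integers(0, 4, size=m)],
        "alt": "T",
        "af": af,
        "true_weight": b_allele,
    })
    common_variants["alt"] = [
        "T" if r != "T" else "G" for r in common_variants["ref"]
    ]
    sumstats = pd.DataFrame({
        "variant_id": common_ids,
        "effect_allele": common_variants["alt"],
        "beta": beta_hat,
        "se": se_gwas,
        "af": af,
        "n": cfg.n_gwas,
    })

    # --- gene annotations
    genes = gene_names(cfg)
    best = best_gene_names(cfg)
    flag_patterns = [
        ("GWAS",), ("HGMD_SHORT",), ("HGMD_TALL", "OMIM_OVERGROWTH"),
        ("HGMD_SHORT", "OMIM_SHORT"), ("OMIM_OVERGROWTH",), ("GWAS", "HGMD_SHORT"),
        ("OMIM_SHORT",), ("GWAS", "HGMD_TALL"), ("HGMD_TALL",),
        ("GWAS", "OMIM_SHORT", "HGMD_SHORT"), ("GWAS", "OMIM_OVERGROWTH"),
        ("HGMD_SHORT", "HGMD_TALL"),
    ]
    ann_rows = []
    for i, g in enumerate(genes):
        if g in best:
            flags = ["HGMD_SHORT", "HGMD_TALL", "OMIM_SHORT", "OMIM_OVERGROWTH"]
            if i % 2 == 0:
                flags.append("GWAS")  # even-index best genes form Set1
        else:
            flags = list(flag_patterns[i % len(flag_patterns)])
        row = {"gene": g}
        for fl in ("GWAS", "HGMD_SHORT", "HGMD_TALL", "OMIM_SHORT", "OMIM_OVERGROWTH"):
            row[fl] = fl in flags
        ann_rows.append(row)
    annotations = pd.DataFrame(ann_rows)

    # --- rare variants
    focal_gene = best[0] if best else None
    plant_effects = cfg.rare_effect_sd != 0 and cfg.n_best_genes > 0
    ptv_pool = sorted(PTV_CLASSES)
    var_rows: list[dict] = []
    cols: list[np.ndarray] = []       # carrier indices per variant
    vals: list[np.ndarray] = []
    pos_counter = {}
    for gi, gene in enumerate(genes):
        n_var = rng_r.poisson(cfg.mean_variants_per_gene)
        if n_var == 0:
            continue
        total_ac = rng_r.binomial(n, cfg.carrier_freq)
        if total_ac == 0:
            continue
        ac = rng_r.multinomial(total_ac, np.full(n_var, 1.0 / n_var))
        keep = ac > 0
        ac = ac[keep]
        n_var = int(keep.sum())
        is_ptv = rng_r.random(n_var) < cfg.ptv_fraction
        is_mis = ~is_ptv & (rng_r.random(n_var) < 0.85)
        chrom = f"chr{(gi % 22) + 1}"
        base_pos = pos_counter.get(chrom, 0)
        pos_counter[chrom] = base_pos + n_var + 10
        effects = np.zeros(n_var)
        activity = np.full(n_var, np.nan)
        if plant_effects and gene in set(best):
            if gene == focal_gene:
                # activity-driven allelic series
                comp = rng_r.choice(len(ACTIVITY_MIXTURE), size=n_var,
                                    p=[w for w, _, _ in ACTIVITY_MIXTURE])
                a = np.array([
                    rng_r.uniform(ACTIVITY_MIXTURE[c][1], ACTIVITY_MIXTURE[c][2])
                    for c in comp
                ])
                a[is_ptv] = rng_r.uniform(0.0, 0.1, size=int(is_ptv.sum()))
                a[~is_ptv & ~is_mis] = 1.0  # non-coding-like: neutral
                activity = a
                effects = cfg.functional_slope * (a - 1.0)
                effects[~is_ptv & ~is_mis] = 0.0
            else:
                # missense spike effects are assigned after genotype draw,
                # from the realized allele counts (see below)
                effects[is_ptv] = cfg.ptv_effect_sd
        for j in range(n_var):
            carriers = np.sort(rng_r.choice(n, size=int(ac[j]), replace=False))
            cols.append(carriers)
            vals.append(np.ones(ac[j], dtype=np.int8))
            cls = (
                ptv_pool[int(rng_r.integers(0, len(ptv_pool)))] if is_ptv[j]
                else ("missense" if is_mis[j] else "other")
            )
            impact = "high" if is_ptv[j] else ("moderate" if is_mis[j] else "other")
            ref = bases[int(rng_r.integers(0, 4))]
            var_rows.append({
                "variant_id": f"{gene}:v{j:04d}",
                "chrom": chrom, "pos": base_pos + j + 1,
                "ref": ref, "alt": "A" if ref != "A" else "C",
                "gene": gene, "consequence_class": cls, "impact": impact,
                "cohort_ac": int(ac[j]), "cohort_an": 2 * n,
                "effect_sd": float(effects[j]),
                "activity_true": float(activity[j]) if not np.isnan(activity[j]) else np.nan,
            })
    variant_columns = [
        "variant_id", "chrom", "pos", "ref", "alt", "gene",
        "consequence_class", "impact", "cohort_ac", "cohort_an",
        "effect_sd", "activity_true",
    ]
    variants = pd.DataFrame(var_rows, columns=variant_columns)
    n_rare = len(variants)

    # --- planted QC failures, restricted to genes with no planted effects
    call_rate_v = np.ones(n_rare)
    ext_af = np.full(n_rare, np.nan)
    if n_rare:
        null_gene = ~variants["gene"].isin(set(best)).to_numpy()
        idx_null = np.flatnonzero(null_gene)
        if idx_null.size:
            n_badcall = min(max(1, int(0.004 * n_rare)), idx_null.size)
            bad_call = rng_q.choice(idx_null, size=n_badcall, replace=False)
            call_rate_v[bad_call] = rng_q.uniform(0.95, 0.989, size=bad_call.size)
            remaining = np.setdiff1d(idx_null, bad_call)
            # excess-homozygosity plants: all carriers become homozygous
            n_hwe = min(max(1, int(0.003 * n_rare)), remaining.size)
            bad_hwe = rng_q.choice(remaining, size=n_hwe, replace=False)
            for j in bad_hwe:
                cols[j] = np.sort(rng_q.choice(n, size=3, replace=False))
                vals[j] = np.full(3, 2, dtype=np.int8)
            # external-AF plants: cohort count far above the reference AF
            remaining = np.setdiff1d(remaining, bad_hwe)
            n_ext = min(max(1, int(0.002 * n_rare)), remaining.size)
            bad_ext = rng_q.choice(remaining, size=n_ext, replace=False)
            for j in bad_ext:
                cols[j] = np.sort(rng_q.choice(n, size=min(60, n // 10), replace=False))
                vals[j] = np.ones(cols[j].size, dtype=np.int8)
                ext_af[j] = 1e-7

    indptr = np.zeros(n_rare + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(c) for c in cols])
    rare = sparse.csc_matrix(
        (np.concatenate(vals) if vals else np.array([], dtype=np.int8),
         np.concatenate(cols) if cols else np.array([], dtype=np.int64),
         indptr),
        shape=(n, n_rare),
    )

    hwe = np.ones(n_rare)
    if n_rare:
        variants["cohort_ac"] = [int(v.sum()) for v in vals]
        n_het_per = np.array([int((v == 1).sum()) for v in vals])
        n_hom_per = np.array([int((v == 2).sum()) for v in vals])
        for j in range(n_rare):
            hwe[j] = hwe_exact_p(
                n - n_het_per[j] - n_hom_per[j], n_het_per[j], n_hom_per[j]
            )
        # half the variants carry a concordant external reference frequency
        known = (rng_q.random(n_rare) < 0.5) & np.isnan(ext_af)
        ext_af[known] = np.maximum(
            variants.loc[known, "cohort_ac"].to_numpy() / (2 * n)
            * rng_q.uniform(0.5, 2.0, size=int(known.sum())),
            1e-6,
        )
    variants["call_rate"] = call_rate_v
    variants["hwe_p"] = hwe
    variants["external_ref_af"] = ext_af

    # --- solve the non-focal missense spike from the realized allele
    # counts, so the maskable set matches both the mean per-allele effect
    # and the target ISS odds ratio in this realization
    if plant_effects and n_rare:
        _assign_spike_effects(variants, cfg, set(best), focal_gene, rng_r)

    # --- height
    rng_h = cfg.rng("cohort.height")
    rare_shift = np.zeros(n)
    if n_rare:
        rare_shift = rare @ variants["effect_sd"].to_numpy()
    noise = rng_h.normal(0.0, np.sqrt(max(1.0 - cfg.prs_h2, 0.0)), size=n)
    latent = ps_true + rare_shift + noise
    height_cm = (
        np.asarray(cfg.sex_means_cm)[sex]
        + cfg.age_slope_cm * (age - 60.0)
        + pcs @ np.asarray(cfg.pc_slopes_cm)
        + cfg.sex_sd_cm * latent
    )

    # --- sample QC metrics with planted failures
    het_rate = rng_q.normal(0.19, 0.006, size=n)
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "sex": np.where(sex == 1, "M", "F"),
        "age": age,
        **{f"pc{i+1}": pcs[:, i] for i in range(5)},
        "height_cm": height_cm,
        "true_z": latent,
        "true_ps": ps_true,
        "ancestry_flag": rng_q.random(n) > 0.015,
        "aneuploidy_flag": rng_q.random(n) < 0.002,
        "het_rate": het_rate,
        "n_non_ref": rng_q.normal(60_000, 7_000, size=n).round().astype(int),
        "n_singletons": rng_q.poisson(9, size=n),
        "het_hom_ratio": rng_q.normal(1.57, 0.07, size=n),
        "ti_tv": rng_q.normal(3.0, 0.08, size=n),
        "call_rate": 1.0 - np.abs(rng_q.normal(0.0, 2e-5, size=n)),
        "chip_het_concordance": 1.0 - np.abs(rng_q.normal(0.0, 0.002, size=n)),
    })
    for col, value in [("n_singletons", 250), ("call_rate", 0.97),
                       ("chip_het_concordance", 0.95), ("n_non_ref", 90_000)]:
        bad = rng_q.choice(n, size=max(1, int(0.002 * n)), replace=False)
        samples.loc[bad, col] = value

    # --- relatedness plants: disjoint 2nd-degree pairs, one triangle, one
    # 3rd-degree pair (which must be kept)
    n_rel_pairs = max(1, int(0.003 * n))
    flat = rng_q.choice(n, size=2 * n_rel_pairs + 5, replace=False)
    kin: list[tuple[str, str, int]] = []
    for k in range(n_rel_pairs):
        kin.append((sample_ids[flat[2 * k]], sample_ids[flat[2 * k + 1]], 2))
    t0, t1, t2, u0, u1 = flat[-5:]
    kin += [
        (sample_ids[t0], sample_ids[t1], 1),
        (sample_ids[t1], sample_ids[t2], 2),
        (sample_ids[t0], sample_ids[t2], 2),
        (sample_ids[u0], sample_ids[u1], 3),
    ]

    return Cohort(samples, variants, sparse.csc_matrix(rare), common_variants,
                  X, sumstats, annotations, kin)


# ======================================================================
# Functional assay


def simulate_functional(cohort: Cohort, cfg: SimulationConfig,
                        z: pd.DataFrame | None = None,
                        gene: str | None = None) -> pd.DataFrame:
    """cGMP activities (relative to wild type) for the focal gene's variants.

    Observed activity = true activity + triplicate measurement noise,
    clipped at 0; the in-silico deleteriousness score is a weak noisy
    correlate of the planted effect, mimicking an annotation-based
    predictor.  ``carrier_heights`` holds each variant's carrier
    standardized heights (from ``z`` when given, else the generator's
    latent height truth).
    """
    gene = gene or (best_gene_names(cfg)[0] if cfg.n_best_genes else None)
    if gene is None:
        raise ConfigurationError("no focal gene available (n_best_genes = 0)")
    focal = cohort.variants[
        (cohort.variants["gene"] == gene)
        & cohort.variants["activity_true"].notna()
    ]
    if focal.empty:
        raise ValueError(f"no assayed variants for gene {gene}")
    rng = cfg.rng("functional")
    if z is not None:
        zmap = z.set_index("sample_id")["z_height"]
        heights_all = cohort.samples["sample_id"].map(zmap).to_numpy()
    else:
        heights_all = cohort.samples["true_z"].to_numpy()
    rows = []
    for _, row in focal.iterrows():
        a_true = float(row["activity_true"])
        sd = float(abs(rng.normal(0.05, 0.02)))
        a_obs = max(0.0, a_true + rng.normal(0.0, sd / np.sqrt(3)))
        score = 20.0 - 2.0 * float(row["effect_sd"]) + rng.normal(0.0, 3.7)
        col = np.asarray(
            cohort.rare_dosages[:, cohort._rare_index[row["variant_id"]]].todense()
        ).ravel()
        carriers = np.flatnonzero(col > 0)
        heights = heights_all[carriers]
        heights = heights[~np.isnan(heights)]
        rows.append({
            "variant_id": row["variant_id"],
            "activity": a_obs,
            "activity_sd": sd,
            "n_replicates": 3,
            "insilico_score": score,
            "carrier_heights": heights.tolist(),
        })
    return pd.DataFrame(rows)
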