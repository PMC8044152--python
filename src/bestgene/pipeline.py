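"""End-to-end pipeline driver: screen -> approval odds -> QC -> association
-> polygenic stratification -> functional integration, on one manifest.

Each stage writes its tables under the run directory and registers them in
``manifest.json`` together with the configuration hash and every threshold
used, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import write_phenotypes, write_sumstats, write_tsv, write_vcf
from .screen import best_genes_frame, call_bidirectional
from .approval import annotate_evidence, estimate_transitions, sweep_thresholds
from .qc import (build_masks, external_af_concordance, filter_samples,
                 filter_variants, remove_related)
from .assoc import (adjust_significance, build_gene_sets, burden_test,
                    define_iss, normalize_height, skat_test)
from .prs import (assign_quintiles, iss_or_by_group, ldpred_inf_weights,
                  prs_r2, score_samples, stratified_effects)
from .functional import activity_regression, bin_activity, compare_predictors
from .simulate import (Cohort, best_gene_names, simulate_catalog,
                       simulate_cohort, simulate_functional, simulate_trials)

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "screen", "approval", "qc", "assoc", "prs", "functional"]
STAGE_DEPS = {
    "screen": ["simulate"],
    "approval": ["simulate", "screen"],
    "qc": ["simulate"],
    "assoc": ["simulate", "qc"],
    "prs": ["simulate", "qc", "assoc"],
    "functional": ["simulate", "qc", "assoc"],
}


def carrier_classes(cohort: Cohort, masks: dict, genes: list[str]) -> np.ndarray:
    """Per-sample carrier class over a gene set: 'lof' for PTV carriers,
    'missense' for other protein-altering carriers, else 'none' (lof takes
    precedence for samples carrying both)."""
    pa_ids = masks["protein_altering"].variant_ids(
        [g for g in genes if g in masks["protein_altering"].variants_by_gene])
    ptv_ids = masks["ptv"].variant_ids(
        [g for g in genes if g in masks["ptv"].variants_by_gene])
    n = cohort.n_samples
    out = np.full(n, "none", dtype=object)
    if pa_ids:
        pa_carrier = cohort.rare_dosage(pa_ids).sum(axis=1) > 0
        out[pa_carrier] = "missense"
    if ptv_ids:
        lof_carrier = cohort.rare_dosage(ptv_ids).sum(axis=1) > 0
        out[lof_carrier] = "lof"
    return out


def run_pipeline(config: PipelineConfig, write_genotype_vcf: bool = False) -> dict:
    """Execute the configured stages in order and return the report bundle.

    Any stage failure aborts with the stage name; outputs of completed
    stages remain on disk.  Stages refuse to run when a stage they depend
    on is toggled off.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    for st in stages:
        missing = [d for d in STAGE_DEPS.get(st, []) if d not in stages]
        if missing:
            raise ValueError(
                f"stage '{st}' requires stage(s) {missing}; enable them in "
                "the config or drop the dependent stage"
            )

    manifest: dict = {
        "tool_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.simulation.seed,
        "stages": {},
    }
    report: dict = {}
    state: dict = {}
    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        fn = _STAGES[stage]
        try:
            files = fn(config, state, report, out, write_genotype_vcf)
        except Exception as exc:  # pragma: no cover - error path
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = files
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    report["manifest"] = manifest
    return report


# ----------------------------------------------------------------------
# Stage implementations


def _stage_simulate(config, state, report, out, write_genotype_vcf):
    cfg = config.simulation
    catalog = simulate_catalog(cfg)
    trials = simulate_trials(cfg, best_gene_names(cfg))
    cohort = simulate_cohort(cfg)
    state.update(catalog=catalog, trials=trials, cohort=cohort)
    write_tsv(out / "catalog.tsv", catalog)
    write_tsv(out / "target_indications.tsv", trials.table)
    write_tsv(out / "evidence.tsv", trials.evidence)
    write_tsv(out / "similarity.tsv", trials.similarity)
    write_phenotypes(out / "phenotypes.tsv", cohort.samples)
    write_sumstats(out / "sumstats.tsv", cohort.sumstats)
    write_tsv(out / "variants.tsv", cohort.variants.drop(
        columns=["effect_sd", "activity_true"]))
    files = ["catalog.tsv", "target_indications.tsv", "evidence.tsv",
             "similarity.tsv", "phenotypes.tsv", "sumstats.tsv", "variants.tsv"]
    if write_genotype_vcf:
        write_vcf(out / "cohort.vcf", cohort.variants, cohort.rare_dosages,
                  cohort.samples["sample_id"].tolist())
        files.append("cohort.vcf")
    return files


def _stage_screen(config, state, report, out, _):
    best, review = call_bidirectional(state["catalog"])
    state["best_genes"] = sorted({b.gene for b in best})
    frame = best_genes_frame(best)
    write_tsv(out / "best_genes.tsv", frame)
    write_tsv(out / "review_queue.tsv", review)
    report["best_genes"] = frame
    return ["best_genes.tsv", "review_queue.tsv"]


def _stage_approval(config, state, report, out, _):
    trials = state["trials"]
    grid = np.round(np.arange(0.0, 1.0 + 1e-9, config.similarity_grid_step),
                    int(-np.log10(config.similarity_grid_step)) + 1)
    sweep, argmax_thr = sweep_thresholds(
        trials.table, trials.evidence, trials.similarity, grid)
    annotated = annotate_evidence(
        trials.table, trials.evidence, trials.similarity,
        config.simulation.sim_threshold)
    rows = []
    for cls in ("BEST", "OMIM_unidirectional", "GWAS"):
        for est in estimate_transitions(annotated, cls,
                                        config.simulation.sim_threshold):
            rows.append(est.to_row())
    estimates = pd.DataFrame(rows)
    write_tsv(out / "approval_sweep.tsv", sweep)
    write_tsv(out / "approval_estimates.tsv", estimates)
    report["approval"] = estimates
    report["approval_sweep"] = sweep
    report["approval_argmax_threshold"] = argmax_thr
    return ["approval_sweep.tsv", "approval_estimates.tsv"]


def _stage_qc(config, state, report, out, _):
    cohort: Cohort = state["cohort"]
    kept, attrition = filter_samples(cohort.samples, config.qc)
    kept = remove_related(kept, cohort.kinship_pairs)
    cohort_q = cohort.subset_samples(kept)
    variants = filter_variants(cohort_q.variants, config.qc)
    keep_ext = []
    for _, row in variants.iterrows():
        _, keep = external_af_concordance(
            int(row["cohort_ac"]), int(row["cohort_an"]),
            row["external_ref_af"], config.qc.external_af_p)
        keep_ext.append(keep)
    variants = variants[np.asarray(keep_ext, dtype=bool)]
    masks, gene_table = build_masks(variants, config.qc)
    state.update(cohort_q=cohort_q, masks=masks, gene_table=gene_table)
    write_tsv(out / "sample_attrition.tsv", attrition)
    write_tsv(out / "gene_cumulative_ac.tsv", gene_table)
    mask_rows = [
        {"gene": g, "variant_id": v, "mask": name}
        for name, mask in masks.items()
        for g, vs in mask.variants_by_gene.items() for v in vs
    ]
    write_tsv(out / "masks.tsv", pd.DataFrame(mask_rows))
    report["attrition"] = attrition
    report["n_samples_post_qc"] = cohort_q.n_samples
    return ["sample_attrition.tsv", "gene_cumulative_ac.tsv", "masks.tsv"]


def _stage_assoc(config, state, report, out, _):
    cohort: Cohort = state["cohort_q"]
    masks = state["masks"]
    z = normalize_height(cohort.samples)
    pheno = cohort.samples[["sample_id", "sex", "age"]].merge(z, on="sample_id")
    if len(pheno) != cohort.n_samples:
        raise RuntimeError("phenotype rows lost during normalization")
    pheno = define_iss(pheno, config.iss_threshold)
    pheno["sex"] = (pheno["sex"] == "M").astype(float)
    state["pheno"] = pheno

    tested_genes = set(masks["protein_altering"].genes())
    ann = cohort.annotations[cohort.annotations["gene"].isin(tested_genes)]
    sets = build_gene_sets(ann)
    state["gene_sets"] = sets

    results = []
    units: list[tuple[str, list[str]]] = [(g, [g]) for g in sorted(tested_genes)]
    named_units = [(name, genes) for name, genes in sets.named.items() if genes]
    combined = sorted(set(sets.named["Set1"]) | set(sets.named["Set2"]))
    if combined:
        named_units.append(("Set1+Set2", combined))
    for unit, genes in units + named_units:
        for mask_name in ("protein_altering", "ptv"):
            ids = masks[mask_name].variant_ids(
                [g for g in genes if g in masks[mask_name].variants_by_gene])
            if not ids:
                continue
            G = cohort.rare_dosage(ids)
            results.append(burden_test(G, pheno, unit, mask_name, "linear"))
            if mask_name == "protein_altering":
                results.append(burden_test(G, pheno, unit, mask_name, "logistic"))
    gene_results = adjust_significance(
        [r for r in results if r.unit in tested_genes],
        config.bonferroni_gene_tests)
    set_results = [r for r in results if r.unit not in tested_genes]

    skat_results = []
    cell_units = [("+".join(combo) or "none", genes)
                  for combo, genes in sets.cells.items() if genes]
    for unit, genes in cell_units + named_units:
        ids = masks["protein_altering"].variant_ids(
            [g for g in genes if g in masks["protein_altering"].variants_by_gene])
        if not ids:
            continue
        G = cohort.rare_dosage(ids)
        skat_results.append(skat_test(G, pheno, unit, "protein_altering"))
    n_set_tests = max(1, len([u for u, _ in cell_units]))
    set_table = adjust_significance(set_results + skat_results, n_set_tests)

    write_tsv(out / "assoc_genes.tsv", gene_results)
    write_tsv(out / "assoc_sets.tsv", set_table)
    report["assoc_genes"] = gene_results
    report["assoc_sets"] = set_table
    report["n_intersections_nonempty"] = sets.n_nonempty
    return ["assoc_genes.tsv", "assoc_sets.tsv"]


def _stage_prs(config, state, report, out, _):
    cohort: Cohort = state["cohort_q"]
    pheno = state["pheno"]
    ss = cohort.sumstats
    blocks = [np.eye(1)] * len(ss)
    shrunk = ldpred_inf_weights(
        ss["beta"].to_numpy(), blocks, int(ss["n"].iloc[0]),
        config.simulation.prs_h2 if config.simulation.prs_h2 > 0 else 0.5)
    weights = pd.DataFrame({
        "variant_id": ss["variant_id"],
        "effect_allele": ss["effect_allele"],
        "weight": shrunk,
    })
    alt_map = dict(zip(cohort.common_variants["variant_id"],
                       cohort.common_variants["alt"]))
    ps = score_samples(cohort.common_dosages, weights,
                       cohort.common_variants["variant_id"].tolist(), alt_map)
    quintiles = assign_quintiles(ps, config.n_quintiles)
    best = sorted(set(state["gene_sets"].named["Bidirectional"]))
    classes = carrier_classes(cohort, state["masks"], best)
    strat, het = stratified_effects(pheno, classes, quintiles)
    or_table = iss_or_by_group(pheno, classes, quintiles,
                               reference_quintile=(config.n_quintiles + 1) // 2)
    z = pheno["z_height"].to_numpy()
    r2 = prs_r2(ps, z)
    import statsmodels.api as sm
    qfit = sm.OLS(z, sm.add_constant(quintiles.astype(float))).fit()
    het_rows = [{"carrier_class": cls, "Q": h.q, "df": h.df, "i2": h.i2,
                 "p_het": h.p_het, "pooled_effect": h.pooled_effect,
                 "pooled_se": h.pooled_se} for cls, h in het.items()]
    write_tsv(out / "ps_weights.tsv", weights)
    write_tsv(out / "ps_scores.tsv", pd.DataFrame(
        {"sample_id": cohort.samples["sample_id"], "ps": ps, "quintile": quintiles}))
    write_tsv(out / "stratified_effects.tsv", strat)
    write_tsv(out / "heterogeneity.tsv", pd.DataFrame(het_rows))
    write_tsv(out / "iss_or_table.tsv", or_table)
    report.update(
        ps_r2=r2, beta_per_quintile=float(qfit.params[1]),
        stratified=strat, heterogeneity=het, iss_or=or_table,
    )
    state.update(quintiles=quintiles, carrier_class=classes, ps=ps)
    return ["ps_weights.tsv", "ps_scores.tsv", "stratified_effects.tsv",
            "heterogeneity.tsv", "iss_or_table.tsv"]


def _stage_functional(config, state, report, out, _):
    cohort: Cohort = state["cohort_q"]
    pheno = state["pheno"]
    table = simulate_functional(cohort, config.simulation,
                                z=pheno[["sample_id", "z_height"]])
    table["activity_bin"] = table["activity"].map(bin_activity)
    with_carriers = table[table["carrier_heights"].map(len) > 0]
    reg = activity_regression(with_carriers)
    comp = compare_predictors(with_carriers)
    out_table = table.copy()
    out_table["carrier_heights"] = out_table["carrier_heights"].map(
        lambda hs: ";".join(f"{h:.4f}" for h in hs))
    write_tsv(out / "functional.tsv", out_table)
    write_tsv(out / "functional_predictors.tsv", comp)
    report["functional"] = table
    report["activity_regression"] = reg
    report["predictor_comparison"] = comp
    return ["functional.tsv", "functional_predictors.tsv"]


_STAGES = {
    "simulate": _stage_simulate,
    "screen": _stage_screen,
    "approval": _stage_approval,
    "qc": _stage_qc,
    "assoc": _stage_assoc,
    "prs": _stage_prs,
    "functional": _stage_functional,
}
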