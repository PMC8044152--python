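"""Readers and writers for the pipeline's interchange formats.

TSV is the interchange format between stages (auditable, diffable); VCF
v4.2 only at the genotype boundary, with per-variant INFO fields GENE,
CSQ_IMPACT and CSQ_CLASS carrying the consequence annotations the analyses
consume.  Multi-allelic records are rejected (pre-split upstream).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import sparse

logger = logging.getLogger(__name__)

PHENO_COLUMNS = ["sample_id", "sex", "age", "pc1", "pc2", "pc3", "pc4", "pc5",
                 "height_cm"]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol (canonical model)">
##INFO=<ID=CSQ_IMPACT,Number=1,Type=String,Description="Predicted impact: high/moderate/other">
##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(path: str | Path, variants: pd.DataFrame,
              dosages, sample_ids: list[str]) -> None:
    """Write a VCF v4.2 with GT genotypes from a (samples x variants) dosage
    matrix (dense or sparse, values 0/1/2, -1 = missing)."""
    D = dosages.tocsc() if sparse.issparse(dosages) else np.asarray(dosages)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        order = variants.sort_values(["chrom", "pos"]).index
        for j_out, idx in enumerate(order):
            row = variants.loc[idx]
            j = variants.index.get_loc(idx)
            col = (np.asarray(D[:, j].todense()).ravel()
                   if sparse.issparse(D) else D[:, j])
            info = (f"GENE={row['gene']};CSQ_IMPACT={row['impact']};"
                    f"CSQ_CLASS={row['consequence_class']}")
            gts = "\t".join(_GT[int(g)] for g in col)
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['variant_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, sparse.csc_matrix, list[str]]:
    """Read a VCF into (variant table, samples x variants dosage matrix,
    sample ids).  Requires the GENE INFO tag; rejects multi-allelic records
    with instructions to pre-split."""
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, cols_data = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {v.CHROM}:{v.POS}; split into "
                "bi-allelic records before loading"
            )
        gene = v.INFO.get("GENE")
        if gene is None:
            raise ValueError(f"variant {v.CHROM}:{v.POS} missing the GENE INFO tag")
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(v.gt_types)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        rows.append({
            "variant_id": v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}",
            "chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0],
            "gene": gene,
            "impact": v.INFO.get("CSQ_IMPACT", "other"),
            "consequence_class": v.INFO.get("CSQ_CLASS", "other"),
        })
        cols_data.append(dosage.astype(np.int8))
    variants = pd.DataFrame(rows)
    if cols_data:
        dense = np.column_stack(cols_data)
        variants["cohort_ac"] = np.where(dense > 0, dense, 0).sum(axis=0).astype(int)
        variants["cohort_an"] = 2 * (dense >= 0).sum(axis=0).astype(int)
        D = sparse.csc_matrix(dense)
    else:
        D = sparse.csc_matrix((len(sample_ids), 0), dtype=np.int8)
        variants["cohort_ac"] = pd.Series(dtype=int)
        variants["cohort_an"] = pd.Series(dtype=int)
    return variants, D, sample_ids


def write_phenotypes(path: str | Path, samples: pd.DataFrame) -> None:
    samples[PHENO_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    return df


def load_cohort(vcf_path: str | Path, pheno_path: str | Path):
    """Load genotypes + phenotypes, checking the sample universes agree.

    Returns (variants, dosages, phenotypes) with phenotype rows ordered as
    the VCF samples.  Sample-id mismatches raise with the orphan lists;
    phenotype rows without genotypes are dropped with a logged count.
    """
    variants, D, sample_ids = read_vcf(vcf_path)
    pheno = read_phenotypes(pheno_path)
    vcf_set, ph_set = set(sample_ids), set(pheno["sample_id"])
    orphans_vcf = sorted(vcf_set - ph_set)
    if orphans_vcf:
        raise ValueError(
            f"{len(orphans_vcf)} VCF samples lack phenotype rows "
            f"(first: {orphans_vcf[:5]})"
        )
    extra = ph_set - vcf_set
    if extra:
        logger.info("dropping %d phenotype rows without genotypes", len(extra))
        pheno = pheno[pheno["sample_id"].isin(vcf_set)]
    pheno = pheno.set_index("sample_id").loc[sample_ids].reset_index()
    return variants, D, pheno


def write_sumstats(path: str | Path, sumstats: pd.DataFrame) -> None:
    sumstats.to_csv(path, sep="\t", index=False)


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
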