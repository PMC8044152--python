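"""Rare-variant association battery: phenotype normalization, gene-set
construction, burden tests (linear on standardized height, logistic on ISS)
and the SKAT variance-component test with Davies-method p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .stats import davies_pvalue, firth_logit

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054

ANNOTATION_FLAGS = [
    "GWAS", "HGMD_SHORT", "HGMD_TALL", "OMIM_SHORT", "OMIM_OVERGROWTH",
]


# ----------------------------------------------------------------------
# Phenotype preparation


def normalize_height(samples: pd.DataFrame, n_pcs: int = 5,
                     min_stratum: int = 30) -> pd.DataFrame:
    """Sex-stratified standardization of height.

    Within each sex, height (cm) is residualized on age and the first
    ``n_pcs`` principal components by least squares and the residuals are
    divided by their standard deviation, so z_height has mean 0 and SD 1
    within each sex stratum.  Samples with missing covariates are dropped
    with a log line.
    """
    cov_cols = ["age"] + [f"pc{i}" for i in range(1, n_pcs + 1)]
    required = ["sample_id", "sex", "height_cm"] + cov_cols
    missing_cols = [c for c in required if c not in samples.columns]
    if missing_cols:
        raise ValueError(f"phenotype table missing columns {missing_cols}")
    complete = samples[required].notna().all(axis=1)
    if (~complete).any():
        logger.info("dropping %d samples with missing covariates", int((~complete).sum()))
    df = samples.loc[complete].copy()
    out = []
    for sex, grp in df.groupby("sex"):
        if len(grp) < min_stratum:
            raise ValueError(f"sex stratum {sex!r} has fewer than {min_stratum} samples")
        X = sm.add_constant(grp[cov_cols].to_numpy(dtype=float))
        resid = sm.OLS(grp["height_cm"].to_numpy(dtype=float), X).fit().resid
        z = resid / resid.std(ddof=1)
        out.append(pd.DataFrame({"sample_id": grp["sample_id"].to_numpy(), "z_height": z}))
    return pd.concat(out, ignore_index=True)


def define_iss(z: pd.DataFrame, threshold: float = -2.0) -> pd.DataFrame:
    """Idiopathic short stature: strictly more than |threshold| SD below the
    sex-specific mean (z < threshold)."""
    out = z.copy()
    out["iss"] = out["z_height"] < threshold
    return out


# ----------------------------------------------------------------------
# Gene sets from evidence annotations


@dataclass
class GeneSets:
    cells: dict[tuple[str, ...], list[str]]  # exclusive flag combination -> genes
    named: dict[str, list[str]]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_nonempty(self) -> int:
        return sum(1 for genes in self.cells.values() if genes)


def build_gene_sets(annotations: pd.DataFrame) -> GeneSets:
    """Enumerate all 2^5 exclusive flag-combination cells and the named sets.

    Named sets: Set1 = genes carrying all five annotations; Set2 = the four
    HGMD/OMIM annotations without GWAS; Bidirectional = all four HGMD/OMIM
    annotations (Set1 union Set2 on the flag level); Tall = tall-side
    evidence without short-side; Short = both short-side annotations without
    tall-side evidence.
    """
    flags = annotations.set_index("gene")[ANNOTATION_FLAGS].astype(bool)
    if not flags.any(axis=1).all():
        bad = flags.index[~flags.any(axis=1)].tolist()
        raise ValueError(f"genes with no annotation flags: {bad}")

    cells: dict[tuple[str, ...], list[str]] = {}
    for k in range(len(ANNOTATION_FLAGS) + 1):
        for combo in combinations(ANNOTATION_FLAGS, k):
            cells[combo] = []
    for gene, row in flags.iterrows():
        combo = tuple(f for f in ANNOTATION_FLAGS if row[f])
        cells[combo].append(gene)

    tall_side = flags["HGMD_TALL"] | flags["OMIM_OVERGROWTH"]
    short_side = flags["HGMD_SHORT"] | flags["OMIM_SHORT"]
    bidir = (flags[["HGMD_SHORT", "HGMD_TALL", "OMIM_SHORT", "OMIM_OVERGROWTH"]]
             .all(axis=1))
    named = {
        "Set1": sorted(flags.index[bidir & flags["GWAS"]]),
        "Set2": sorted(flags.index[bidir & ~flags["GWAS"]]),
        "Bidirectional": sorted(flags.index[bidir]),
        "Tall": sorted(flags.index[tall_side & ~short_side]),
        "Short": sorted(
            flags.index[flags["HGMD_SHORT"] & flags["OMIM_SHORT"] & ~tall_side]
        ),
    }
    return GeneSets(cells, named)


# ----------------------------------------------------------------------
# Association results


@dataclass
class AssocResult:
    unit: str
    mask: str
    test: str           # burden_linear, burden_logistic, skat
    effect: float       # beta (SD units) or odds ratio
    se: float
    ci_low: float
    ci_high: float
    p: float
    ac: int
    ac_case: int | None = None
    ac_control: int | None = None
    n_variants: int | None = None
    flag: str = ""

    def to_row(self) -> dict:
        return self.__dict__.copy()


def burden_scores(G: np.ndarray, aggregation: str = "allele") -> np.ndarray:
    """Per-sample burden over a variant mask: summed alternate-allele
    dosages ("allele") or a 0/1 carrier indicator ("carrier")."""
    s = np.asarray(G, dtype=float).sum(axis=1)
    if aggregation == "carrier":
        return (s > 0).astype(float)
    if aggregation != "allele":
        raise ValueError("aggregation must be 'allele' or 'carrier'")
    return s


def burden_test(
    G: np.ndarray,
    phenotype: pd.DataFrame,
    unit: str,
    mask: str,
    kind: str = "linear",
    aggregation: str = "allele",
    logistic_covariates: tuple[str, ...] = ("sex", "age"),
) -> AssocResult:
    """Burden regression of z_height (linear) or ISS (logistic) on the
    summed rare-allele dosage over the mask variants of ``unit``.

    Logistic effects are odds ratios with Wald CIs; complete separation
    falls back to a Firth-penalized fit, flagged.  A unit with no carriers
    is returned flagged ``untestable``.
    """
    burden = burden_scores(G, aggregation)
    ac = int(round(np.asarray(G).sum()))
    test = f"burden_{kind}"
    if not np.any(burden > 0):
        return AssocResult(unit, mask, test, np.nan, np.nan, np.nan, np.nan,
                           np.nan, ac, flag="untestable")
    if kind == "linear":
        y = phenotype["z_height"].to_numpy(dtype=float)
        X = sm.add_constant(burden)
        fit = sm.OLS(y, X).fit()
        beta, se = fit.params[1], fit.bse[1]
        return AssocResult(
            unit, mask, test, float(beta), float(se),
            float(beta - Z975 * se), float(beta + Z975 * se),
            float(fit.pvalues[1]), ac, n_variants=G.shape[1],
        )
    if kind != "logistic":
        raise ValueError("kind must be 'linear' or 'logistic'")
    y = phenotype["iss"].to_numpy(dtype=float)
    cols = [burden] + [
        phenotype[c].to_numpy(dtype=float) for c in logistic_covariates
        if c in phenotype.columns
    ]
    X = sm.add_constant(np.column_stack(cols))
    flag = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False) or not np.isfinite(fit.bse[1]) \
                or fit.bse[1] > 50:
            raise sps.FitError("logistic fit unstable")
        beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
    except Exception:
        ffit = firth_logit(y, X)
        beta, se = ffit.params[1], ffit.bse[1]
        p = 2 * sps.norm.sf(abs(beta) / se) if se > 0 else np.nan
        flag = "firth"
    is_case = y > 0.5
    ac_case = int(round(np.asarray(G)[is_case].sum()))
    ac_control = ac - ac_case
    return AssocResult(
        unit, mask, test, float(np.exp(beta)), float(se),
        float(np.exp(beta - Z975 * se)), float(np.exp(beta + Z975 * se)),
        float(p), ac, ac_case, ac_control, G.shape[1], flag,
    )


def skat_weights(G: np.ndarray, scheme: str = "beta") -> np.ndarray:
    """Per-variant weights: Beta(1, 25) density of the MAF (the SKAT
    convention, upweighting the rarest variants) or flat."""
    k = np.asarray(G).shape[1]
    if scheme == "flat":
        return np.ones(k)
    if scheme != "beta":
        raise ValueError("weights must be 'beta' or 'flat'")
    af = np.asarray(G, dtype=float).mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    return sps.beta.pdf(np.clip(maf, 1e-12, 1 - 1e-12), 1.0, 25.0)


def skat_test(
    G: np.ndarray,
    phenotype: pd.DataFrame,
    unit: str,
    mask: str,
    weights: str = "beta",
) -> AssocResult:
    """SKAT variance-component score test on standardized height.

    Q = r' G W^2 G' r with r the intercept-only null residuals of z_height
    (covariates are already absorbed into z); the null distribution of Q is
    the weighted chi-square mixture given by the eigenvalues of the
    projected weighted kernel, evaluated with the Davies method (Liu
    moment-matching fallback).
    """
    G = np.asarray(G, dtype=float)
    keep = G.any(axis=0)
    if not keep.any():
        return AssocResult(unit, mask, "skat", np.nan, np.nan, np.nan, np.nan,
                           np.nan, 0, flag="untestable")
    G = G[:, keep]
    n, k = G.shape
    y = phenotype["z_height"].to_numpy(dtype=float)
    r = y - y.mean()
    sigma2 = float(r @ r) / (n - 1)
    w = skat_weights(G, weights)
    A = G * w  # columns scaled by weights
    u = A.T @ r
    q = float(u @ u)
    col_means = A.mean(axis=0)
    M = A.T @ A - n * np.outer(col_means, col_means)  # W G' P G W
    lam = np.linalg.eigvalsh(M)
    lam = lam[lam > max(1e-10 * lam.max(), 0.0)]
    if lam.size == 0:
        return AssocResult(unit, mask, "skat", np.nan, np.nan, np.nan, np.nan,
                           np.nan, int(G.sum()), flag="degenerate")
    res = davies_pvalue(lam * sigma2, q)
    return AssocResult(
        unit, mask, "skat", np.nan, np.nan, np.nan, np.nan, res.p,
        int(round(G.sum())), n_variants=k, flag=res.method,
    )


def adjust_significance(results: list[AssocResult], n_tests: int) -> pd.DataFrame:
    """Bonferroni flagging: significant iff p < 0.05 / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    rows = []
    for r in results:
        row = r.to_row()
        row["significant"] = bool(np.isfinite(r.p) and r.p < 0.05 / n_tests)
        rows.append(row)
    return pd.DataFrame(rows)
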