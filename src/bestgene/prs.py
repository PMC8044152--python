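"""Polygenic score construction and stratified rare-variant effects.

Summary-statistic weights are shrunk with the closed-form infinitesimal
model (per LD block, ``(M/(N h2) I + D)^-1 beta_hat``), samples are scored
and split into quintiles, and the height contrast for rare-variant carriers
is estimated within each quintile with fixed-effect meta-analysis and
I-squared heterogeneity across strata; ISS odds ratios are estimated for
each (quintile x carrier class) group against the middle-quintile
non-carrier reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .stats import HeterogeneityStats, fixed_effect_meta

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054

CARRIER_CLASSES = ["none", "missense", "lof"]


# ----------------------------------------------------------------------
# Infinitesimal-model weights


def ldpred_inf_weights(
    marginal_betas: np.ndarray,
    ld_blocks: list[np.ndarray],
    n_gwas: int,
    h2: float,
    m_snps: int | None = None,
) -> np.ndarray:
    """Closed-form infinitesimal shrinkage of marginal GWAS effects.

    Per LD block with correlation matrix D, the posterior mean weight is
    ``(M/(N h2) I + D)^-1 beta_hat``; the ridge term makes the solve
    well-posed for any h2 > 0.  Blocks are processed independently.
    """
    beta = np.asarray(marginal_betas, dtype=float)
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    if n_gwas <= 0:
        raise ValueError("n_gwas must be positive")
    m = m_snps if m_snps is not None else beta.size
    sizes = [np.asarray(D).shape[0] for D in ld_blocks]
    if sum(sizes) != beta.size:
        raise ValueError("LD blocks do not tile the marginal effect vector")
    ridge = m / (n_gwas * h2)
    out = np.empty_like(beta)
    offset = 0
    for D in ld_blocks:
        D = np.asarray(D, dtype=float)
        k = D.shape[0]
        eigmin = np.linalg.eigvalsh(D).min() if k > 1 else float(D.reshape(()))
        if eigmin < -1e-8:
            raise ValueError("LD block is not positive semi-definite")
        out[offset : offset + k] = np.linalg.solve(
            ridge * np.eye(k) + D, beta[offset : offset + k]
        )
        offset += k
    return out


# ----------------------------------------------------------------------
# Scoring and quintiles


def score_samples(
    dosages: np.ndarray,
    weights: pd.DataFrame,
    variant_ids: list[str],
    dosage_alt_alleles: dict[str, str] | None = None,
) -> np.ndarray:
    """PS = sum_j w_j * dosage_j over the overlap of weight table and cohort.

    ``weights`` has columns variant_id, effect_allele, weight.  When the
    effect allele does not match the dosage-counted alternate allele the
    weight's sign is flipped (dosage of the other allele = 2 - d, which
    only shifts the score by a constant).  Missing dosages (coded < 0) are
    imputed to twice the cohort allele frequency.
    """
    w = weights.drop_duplicates("variant_id").set_index("variant_id")
    idx = [i for i, vid in enumerate(variant_ids) if vid in w.index]
    if not idx:
        raise ValueError("no overlap between weight table and cohort variants")
    X = np.asarray(dosages, dtype=float)[:, idx]
    ordered = [variant_ids[i] for i in idx]
    wvec = w.loc[ordered, "weight"].to_numpy(dtype=float)
    if dosage_alt_alleles is not None and "effect_allele" in w.columns:
        flip = np.array(
            [w.loc[v, "effect_allele"] != dosage_alt_alleles.get(v) for v in ordered]
        )
        wvec = np.where(flip, -wvec, wvec)
    miss = X < 0
    if miss.any():
        af = np.where(
            miss.all(axis=0), 0.0,
            np.where(miss, 0.0, X).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1) / 2.0,
        )
        X = np.where(miss, 2.0 * af, X)
    return X @ wvec


def assign_quintiles(ps: np.ndarray, n_groups: int = 5) -> np.ndarray:
    """Rank-based split into equal groups (1 = lowest score).

    Remainders go to the lower groups; ties are broken by stable input
    order, so equal scores still yield a deterministic partition.
    """
    ps = np.asarray(ps, dtype=float)
    n = ps.size
    if n < n_groups:
        raise ValueError("need at least one sample per group")
    if np.unique(ps).size == 1:
        logger.warning("all scores identical; quintile assignment is by input order")
    order = np.argsort(ps, kind="stable")
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
    labels = np.repeat(np.arange(1, n_groups + 1), sizes)
    out = np.empty(n, dtype=int)
    out[order] = labels
    return out


# ----------------------------------------------------------------------
# Stratified carrier effects


@dataclass
class StratifiedEffect:
    quintile: int
    carrier_class: str
    effect: float
    se: float
    n_carriers: int

    def to_row(self) -> dict:
        return self.__dict__.copy()


def stratified_effects(
    phenotype: pd.DataFrame,
    carrier_class: pd.Series | np.ndarray,
    quintiles: np.ndarray,
    classes: tuple[str, ...] = ("missense", "lof"),
) -> tuple[pd.DataFrame, dict[str, HeterogeneityStats]]:
    """Carrier-vs-non-carrier height contrast per quintile and class, with
    fixed-effect meta-analysis and I-squared across quintiles per class.

    ``carrier_class`` holds one of {none, missense, lof} per sample (a
    sample carrying both a PTV and a missense allele counts as lof).
    Quintiles with no carriers of a class are omitted from that class's
    meta-analysis with a log line.
    """
    cc = np.asarray(carrier_class, dtype=object)
    z = phenotype["z_height"].to_numpy(dtype=float)
    q = np.asarray(quintiles)
    rows: list[StratifiedEffect] = []
    het: dict[str, HeterogeneityStats] = {}
    for cls in classes:
        effs, ses = [], []
        for g in sorted(np.unique(q)):
            in_q = q == g
            carrier = in_q & (cc == cls)
            ref = in_q & (cc == "none")
            if carrier.sum() == 0:
                logger.info("quintile %d has no %s carriers; omitted", g, cls)
                continue
            x = np.concatenate([np.zeros(ref.sum()), np.ones(carrier.sum())])
            y = np.concatenate([z[ref], z[carrier]])
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            eff, se = float(fit.params[1]), float(fit.bse[1])
            rows.append(StratifiedEffect(int(g), cls, eff, se, int(carrier.sum())))
            effs.append(eff)
            ses.append(se)
        if len(effs) >= 2:
            het[cls] = fixed_effect_meta(effs, ses)
    table = pd.DataFrame([r.to_row() for r in rows])
    return table, het


def iss_or_by_group(
    phenotype: pd.DataFrame,
    carrier_class: pd.Series | np.ndarray,
    quintiles: np.ndarray,
    reference_quintile: int = 3,
    max_se: float = 100.0,
) -> pd.DataFrame:
    """ISS odds ratio of every (quintile x carrier status) group against the
    middle-quintile non-carrier reference, from one logistic regression on
    group indicators.  Groups whose coefficient SE exceeds ``max_se``
    (essentially empty case cells) are removed from the output.
    """
    cc = np.asarray(carrier_class, dtype=object)
    carrier = cc != "none"
    q = np.asarray(quintiles)
    y = phenotype["iss"].to_numpy(dtype=float)
    ref = (q == reference_quintile) & ~carrier
    if ref.sum() == 0 or y[ref].sum() == 0:
        raise ValueError("reference group empty or has no ISS cases")
    groups = []
    cols = []
    for g in sorted(np.unique(q)):
        for is_carrier in (False, True):
            if g == reference_quintile and not is_carrier:
                continue
            member = (q == g) & (carrier == is_carrier)
            if member.sum() == 0:
                continue
            groups.append((int(g), "carrier" if is_carrier else "non-carrier"))
            cols.append(member.astype(float))
    X = sm.add_constant(np.column_stack(cols))
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        # IRLS: a zero-case cell drifts to a divergent coefficient with an
        # enormous standard error, which the SE rule below then removes
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    rows = [{
        "quintile": reference_quintile, "carrier_status": "non-carrier",
        "odds_ratio": 1.0, "ci_low": 1.0, "ci_high": 1.0, "p": np.nan,
        "n": int(ref.sum()), "n_cases": int(y[ref].sum()), "reference": True,
    }]
    for j, (g, status) in enumerate(groups):
        beta, se, p = fit.params[j + 1], fit.bse[j + 1], fit.pvalues[j + 1]
        if not np.isfinite(se) or se > max_se:
            logger.info("group (PS%d, %s) removed: SE=%.3g", g, status, se)
            continue
        member = cols[j] > 0
        rows.append({
            "quintile": g, "carrier_status": status,
            "odds_ratio": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - Z975 * se)),
            "ci_high": float(np.exp(beta + Z975 * se)),
            "p": float(p), "n": int(member.sum()),
            "n_cases": int(y[member].sum()), "reference": False,
        })
    return pd.DataFrame(rows).sort_values(
        ["quintile", "carrier_status"]).reset_index(drop=True)


def prs_r2(ps: np.ndarray, z: np.ndarray) -> float:
    """Fraction of height variance explained by the score (squared Pearson
    correlation with standardized height)."""
    r = np.corrcoef(np.asarray(ps, float), np.asarray(z, float))[0, 1]
    return float(r * r)
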