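"""Integration of a per-variant functional readout with carrier phenotypes.

The readout is cGMP production relative to wild type (1.0 = wild-type
activity) for receptor variants assayed in cells; variants are binned into
low / intermediate / supranormal activity, carrier heights are regressed on
activity, and the assay is compared against an in-silico deleteriousness
score as a predictor of carrier height.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


def bin_activity(activity: float) -> str:
    """low (< 0.2), supranormal (> 1), else intermediate.

    Boundary values 0.2 and 1.0 are intermediate (strict inequalities)."""
    if activity < 0:
        raise ValueError("activity must be non-negative")
    if activity < 0.2:
        return "low"
    if activity > 1.0:
        return "supranormal"
    return "intermediate"


@dataclass
class RegressionReport:
    predictor: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    r2: float
    n_obs: int


def _per_carrier_frame(table: pd.DataFrame, predictor: str) -> pd.DataFrame:
    rows = []
    for _, row in table.iterrows():
        heights = row["carrier_heights"]
        if isinstance(heights, str):
            heights = [float(x) for x in heights.split(";") if x != ""]
        if pd.isna(row[predictor]):
            continue
        for h in heights:
            rows.append({"x": float(row[predictor]), "z_height": float(h)})
    return pd.DataFrame(rows)


def _regress(df: pd.DataFrame, predictor: str) -> RegressionReport:
    x = df["x"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"{predictor} is constant; slope undefined")
    y = df["z_height"].to_numpy(dtype=float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    return RegressionReport(
        predictor, beta, se, beta - Z975 * se, beta + Z975 * se,
        float(fit.pvalues[1]), float(fit.rsquared), len(df),
    )


def activity_regression(table: pd.DataFrame, per_variant: bool = False) -> RegressionReport:
    """Slope of carrier standardized height on activity, in SD per 100%
    cGMP relative to wild type.

    By default every carrier is one observation; ``per_variant`` collapses
    each variant to its mean carrier height instead.
    """
    df = _per_carrier_frame(table, "activity")
    n_var = (table["carrier_heights"].map(
        lambda h: len(h.split(";")) if isinstance(h, str) else len(h)) > 0).sum()
    if n_var < 3:
        raise ValueError("need at least 3 variants with carriers")
    if per_variant:
        df = df.groupby("x", as_index=False)["z_height"].mean()
    return _regress(df, "activity")


def compare_predictors(table: pd.DataFrame) -> pd.DataFrame:
    """Fit carrier height on the assay activity and on the in-silico score
    separately; report slope, p and R^2 for each and flag the better
    classifier (higher R^2).  Variants missing either value are excluded
    pairwise, logged."""
    reports = []
    for predictor in ("activity", "insilico_score"):
        df = _per_carrier_frame(table, predictor)
        n_excl = len(table) - table[predictor].notna().sum()
        if n_excl:
            logger.info("%d variants missing %s; excluded", n_excl, predictor)
        reports.append(_regress(df, predictor))
    out = pd.DataFrame([r.__dict__ for r in reports])
    out["best_r2"] = out["r2"] == out["r2"].max()
    return out
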