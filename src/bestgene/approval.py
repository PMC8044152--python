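"""Clinical-phase transition enrichment for genetically supported targets.

For every target-indication pair we ask whether the target gene carries
genetic evidence (bidirectional BEST, unidirectional OMIM, or GWAS) for a
trait semantically similar to the indication, and estimate the relative
risk of advancing between clinical phases for supported versus unsupported
pairs, across a grid of similarity thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHASES = ["PhaseI", "PhaseII", "PhaseIII", "Approved"]
PHASE_RANK = {p: i for i, p in enumerate(PHASES)}
TRANSITIONS = [
    ("PhaseI", "PhaseII"),
    ("PhaseII", "PhaseIII"),
    ("PhaseIII", "Approved"),
    ("PhaseI", "Approved"),
]
EVIDENCE_PRECEDENCE = ["BEST", "OMIM_unidirectional", "GWAS"]


@dataclass
class RelativeRiskEstimate:
    transition: tuple[str, str]
    rr: float
    ci_low: float
    ci_high: float
    counts: tuple[int, int, int, int]  # a, b, c, d
    threshold: float | None = None
    evidence_class: str | None = None
    corrected: bool = False
    odds_ratio: float = float("nan")

    def to_row(self) -> dict:
        a, b, c, d = self.counts
        return {
            "transition": f"{self.transition[0]}->{self.transition[1]}",
            "evidence_class": self.evidence_class,
            "threshold": self.threshold,
            "a": a, "b": b, "c": c, "d": d,
            "rr": self.rr, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "odds_ratio": self.odds_ratio, "corrected": self.corrected,
        }


def relative_risk(a: int, b: int, c: int, d: int,
                  transition: tuple[str, str] = ("PhaseI", "Approved"),
                  ) -> RelativeRiskEstimate:
    """Risk ratio from a 2x2 table with the Katz log-method 95% CI.

    a/b: supported pairs that did / did not make the transition;
    c/d: unsupported pairs likewise.  A zero numerator cell (a or c)
    triggers the 0.5 continuity correction on all cells, flagged.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 cells must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("both exposure groups must be non-empty")
    corrected = a == 0 or c == 0
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    rr = (aa / (aa + bb)) / (cc / (cc + dd))
    se_log = math.sqrt(1 / aa - 1 / (aa + bb) + 1 / cc - 1 / (cc + dd))
    ci_low = rr * math.exp(-1.959963984540054 * se_log)
    ci_high = rr * math.exp(1.959963984540054 * se_log)
    odds = (aa * dd) / (bb * cc) if bb * cc > 0 else float("inf")
    return RelativeRiskEstimate(
        transition, float(rr), float(ci_low), float(ci_high),
        (int(a), int(b), int(c), int(d)), corrected=corrected,
        odds_ratio=float(odds),
    )


# ----------------------------------------------------------------------
# Evidence annotation


def pair_class_similarity(
    table: pd.DataFrame,
    evidence: pd.DataFrame,
    similarity: pd.DataFrame,
) -> pd.DataFrame:
    """Max indication-trait similarity per (pair, evidence class).

    ``table`` rows are target-indication pairs; ``evidence`` maps gene ->
    (trait, class); ``similarity`` is long-form (indication, trait, value).
    Evidence genes absent from the table are ignored (logged).  The result
    lets every similarity threshold be applied by a single comparison.
    """
    ev = evidence.rename(columns={"class": "evidence_class"}).copy()
    unknown = set(ev["gene"]) - set(table["target_gene"])
    if unknown:
        logger.info("%d evidence genes not among targets; ignored", len(unknown))
    t = table.reset_index().rename(columns={"index": "pair_id"})
    cand = t.merge(ev, left_on="target_gene", right_on="gene", how="inner")
    cand = cand.merge(similarity, on=["indication", "trait"], how="inner")
    if cand.empty:
        return pd.DataFrame(columns=["pair_id", "evidence_class", "max_sim"])
    out = (
        cand.groupby(["pair_id", "evidence_class"], as_index=False)["value"]
        .max()
        .rename(columns={"value": "max_sim"})
    )
    return out


def annotate_evidence(
    table: pd.DataFrame,
    evidence: pd.DataFrame,
    similarity: pd.DataFrame,
    threshold: float = 0.83,
    precedence: list[str] | None = None,
    _pair_class: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach the best supporting evidence class to each pair.

    A pair is supported by class C iff its target has class-C evidence for a
    trait whose similarity to the indication exceeds ``threshold``; when
    several classes apply the configurable precedence (default
    BEST > OMIM_unidirectional > GWAS) decides.
    """
    precedence = precedence or EVIDENCE_PRECEDENCE
    pc = pair_class_similarity(table, evidence, similarity) if _pair_class is None else _pair_class
    annotated = table.copy()
    annotated["evidence_class"] = "none"
    annotated["support_similarity"] = np.nan
    hits = pc[pc["max_sim"] > threshold]
    rank = {c: i for i, c in enumerate(precedence)}
    if not hits.empty:
        hits = hits.assign(rank=hits["evidence_class"].map(rank))
        best = hits.sort_values(["pair_id", "rank"]).drop_duplicates("pair_id")
        annotated.loc[best["pair_id"].to_numpy(), "evidence_class"] = (
            best["evidence_class"].to_numpy()
        )
        annotated.loc[best["pair_id"].to_numpy(), "support_similarity"] = (
            best["max_sim"].to_numpy()
        )
    return annotated


# ----------------------------------------------------------------------
# Transition estimates


def transition_counts(annotated: pd.DataFrame, transition: tuple[str, str],
                      evidence_class: str = "BEST",
                      control: str = "unsupported") -> tuple[int, int, int, int]:
    """2x2 counts for one transition: success = reached >= target phase,
    denominated on reached >= source phase."""
    src, dst = transition
    rank = annotated["reached"].map(PHASE_RANK)
    if rank.isna().any():
        bad = annotated.loc[rank.isna(), "reached"].unique()
        raise ValueError(f"unknown phase labels: {bad}")
    at_risk = rank >= PHASE_RANK[src]
    success = rank >= PHASE_RANK[dst]
    exposed = annotated["evidence_class"] == evidence_class
    if control == "unsupported":
        ctrl = annotated["evidence_class"] == "none"
    elif control == "rest":
        ctrl = ~exposed
    else:
        raise ValueError("control must be 'unsupported' or 'rest'")
    a = int((at_risk & exposed & success).sum())
    b = int((at_risk & exposed & ~success).sum())
    c = int((at_risk & ctrl & success).sum())
    d = int((at_risk & ctrl & ~success).sum())
    return a, b, c, d


def estimate_transitions(
    annotated: pd.DataFrame,
    evidence_class: str = "BEST",
    threshold: float | None = None,
    control: str = "unsupported",
) -> list[RelativeRiskEstimate]:
    out = []
    for transition in TRANSITIONS:
        a, b, c, d = transition_counts(annotated, transition, evidence_class, control)
        if a + b == 0 or c + d == 0:
            logger.info("empty group for %s at threshold %s; omitted", transition, threshold)
            continue
        est = relative_risk(a, b, c, d, transition)
        est.threshold = threshold
        est.evidence_class = evidence_class
        out.append(est)
    return out


def sweep_thresholds(
    table: pd.DataFrame,
    evidence: pd.DataFrame,
    similarity: pd.DataFrame,
    grid: np.ndarray | None = None,
    evidence_class: str = "BEST",
    control: str = "unsupported",
) -> tuple[pd.DataFrame, float]:
    """One estimate per (threshold, transition); returns the sweep table and
    the threshold maximizing the PhaseI->Approval RR (ties -> smallest)."""
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    pc = pair_class_similarity(table, evidence, similarity)
    rows = []
    best_thr, best_rr = float("nan"), -np.inf
    for thr in grid:
        annotated = annotate_evidence(table, evidence, similarity, thr, _pair_class=pc)
        for est in estimate_transitions(annotated, evidence_class, float(thr), control):
            rows.append(est.to_row())
            if est.transition == ("PhaseI", "Approved") and est.rr > best_rr:
                best_rr, best_thr = est.rr, float(thr)
    return pd.DataFrame(rows), best_thr


def sensitivity_analysis(
    table: pd.DataFrame,
    evidence: pd.DataFrame,
    similarity: pd.DataFrame,
    mode: str,
    categories: list[str],
    threshold: float = 0.83,
    evidence_class: str = "BEST",
    min_best_genes: int = 5,
) -> dict[str, list[RelativeRiskEstimate]]:
    """Category-level robustness checks.

    ``exclude`` drops evidence annotations in the named categories and
    recomputes globally; ``stratify`` estimates per category, skipping
    categories with <= ``min_best_genes`` BEST genes.
    """
    if mode not in {"exclude", "stratify"}:
        raise ValueError("mode must be 'exclude' or 'stratify'")
    if "category" not in evidence.columns:
        raise ValueError("evidence table must carry a 'category' column")
    if mode == "exclude":
        kept = evidence[~evidence["category"].isin(categories)]
        if kept.empty:
            raise ValueError("sensitivity exclusion removed all evidence")
        annotated = annotate_evidence(table, kept, similarity, threshold)
        return {"excluded": estimate_transitions(annotated, evidence_class, threshold)}
    results: dict[str, list[RelativeRiskEstimate]] = {}
    for cat in categories:
        n_best = evidence.loc[
            (evidence["category"] == cat) & (evidence["class"] == "BEST"), "gene"
        ].nunique()
        if n_best <= min_best_genes:
            logger.info("category %s has %d BEST genes (<=%d); skipped",
                        cat, n_best, min_best_genes)
            continue
        sub = table[table["category"] == cat]
        if sub.empty:
            logger.info("category %s has no pairs; skipped", cat)
            continue
        annotated = annotate_evidence(sub, evidence, similarity, threshold)
        results[cat] = estimate_transitions(annotated, evidence_class, threshold)
    return results
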