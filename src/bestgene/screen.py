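"""Bidirectional-effect gene screen over a gene-disease mutation catalog.

A gene is a BEST (Bidirectional Effect Selected Target) candidate when its
disease associations include at least one label pushing a phenotype axis up
and one pushing the same axis down -- e.g. "hypercholesterolemia" and
"hypocholesterolemia", or "tall stature" and "short stature".  The original
selection was a manual curation; here the rule is made explicit as a
direction lexicon, and surviving-but-unclassified labels are exported to a
review queue so a human can catch what the lexicon cannot.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .config import ConfigurationError

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = ["gene", "disease", "variant_class"]


@dataclass(frozen=True)
class DirectionalCall:
    axis: str
    direction: str  # "up" or "down"
    matched_term: str


@dataclass
class BestGene:
    gene: str
    axis: str
    n_up: int
    n_down: int
    evidence: list[str] = field(default_factory=list)


class DirectionLexicon:
    """Axis -> antonym phrase lists, plus an exclusion list.

    Matching is whole-phrase containment after lowercasing and punctuation
    stripping, so "Familial high LDL cholesterol, type 2" still matches
    "high ldl cholesterol" while "shorthand" can never match "short".
    """

    def __init__(self, axes: dict[str, dict[str, list[str]]],
                 exclusions: list[str] | None = None) -> None:
        self.exclusions = [normalize_label(t) for t in (exclusions or [])]
        self._patterns: list[tuple[re.Pattern, str, str, str]] = []
        if not isinstance(axes, dict) or not axes:
            raise ConfigurationError("lexicon must define at least one axis")
        for axis in sorted(axes):
            spec = axes[axis]
            if not isinstance(spec, dict) or not (
                spec.get("up_terms") and spec.get("down_terms")
            ):
                raise ConfigurationError(
                    f"axis {axis!r} must define non-empty up_terms and down_terms"
                )
            for direction in ("up", "down"):
                for term in spec[f"{direction}_terms"]:
                    norm = normalize_label(term)
                    pat = re.compile(rf"(?<![a-z0-9]){re.escape(norm)}(?![a-z0-9])")
                    self._patterns.append((pat, axis, direction, term))
        self.axes = sorted(axes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DirectionLexicon":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "axes" not in raw:
            raise ConfigurationError("lexicon YAML must contain an 'axes' mapping")
        return cls(raw["axes"], raw.get("exclusions"))

    @classmethod
    def default(cls) -> "DirectionLexicon":
        with resources.files("bestgene.data").joinpath("lexicon.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        return cls(raw["axes"], raw.get("exclusions"))

    def match(self, normalized_label: str) -> list[tuple[str, str, str]]:
        return [
            (axis, direction, term)
            for pat, axis, direction, term in self._patterns
            if pat.search(normalized_label)
        ]


def normalize_label(label: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    label = re.sub(r"[^\w\s]", " ", label.lower())
    return re.sub(r"\s+", " ", label).strip()


def classify_direction(disease: str, lexicon: DirectionLexicon) -> DirectionalCall | None:
    """Classify one disease label, or return None.

    None means: an excluded molecular/benign phenotype, no lexicon hit, or
    an ambiguous label matching more than one (axis, direction).
    """
    norm = normalize_label(disease)
    if any(excl in norm for excl in lexicon.exclusions):
        return None
    hits = lexicon.match(norm)
    calls = {(axis, direction) for axis, direction, _ in hits}
    if len(calls) != 1:
        if len(calls) > 1:
            logger.debug("ambiguous label %r -> %s", disease, sorted(calls))
        return None
    axis, direction, term = hits[0]
    return DirectionalCall(axis, direction, term)


def call_bidirectional(
    catalog: pd.DataFrame,
    lexicon: DirectionLexicon | None = None,
    dm_only: bool = False,
) -> tuple[list[BestGene], pd.DataFrame]:
    """Run the screen over a catalog of (gene, disease[, variant_class]) rows.

    Returns the BEST genes (one entry per gene x axis, sorted by gene) and a
    review-queue DataFrame of labels on surviving genes that the lexicon
    could not classify.

    Duplicate (gene, disease) rows collapse first; genes with fewer than two
    unique disease associations are excluded before any direction logic.
    """
    lexicon = lexicon or DirectionLexicon.default()
    if catalog.empty:
        warnings.warn("empty mutation catalog: screen returns no genes")
        return [], pd.DataFrame(columns=["gene", "disease"])
    df = catalog.copy()
    if dm_only:
        if "variant_class" not in df.columns:
            raise ConfigurationError("dm_only requires a variant_class column")
        df = df[df["variant_class"] == "DM"]
    bad = df["gene"].astype(str).str.strip().eq("") | df["disease"].astype(str).str.strip().eq("")
    if bad.any():
        raise ValueError("catalog rows must have non-empty gene and disease")
    pairs = df[["gene", "disease"]].drop_duplicates()

    counts = pairs.groupby("gene")["disease"].nunique()
    surviving = set(counts.index[counts >= 2])
    pairs = pairs[pairs["gene"].isin(surviving)]

    best: list[BestGene] = []
    review_rows: list[dict] = []
    for gene, grp in pairs.sort_values(["gene", "disease"]).groupby("gene", sort=True):
        per_axis: dict[str, dict[str, list[str]]] = {}
        for disease in grp["disease"]:
            call = classify_direction(disease, lexicon)
            if call is None:
                review_rows.append({"gene": gene, "disease": disease})
                continue
            per_axis.setdefault(call.axis, {"up": [], "down": []})
            per_axis[call.axis][call.direction].append(disease)
        for axis in sorted(per_axis):
            ups, downs = per_axis[axis]["up"], per_axis[axis]["down"]
            if ups and downs:
                best.append(BestGene(gene, axis, len(ups), len(downs), ups + downs))
    review = pd.DataFrame(review_rows, columns=["gene", "disease"])
    return best, review


def best_genes_frame(best: list[BestGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": b.gene,
                "axis": b.axis,
                "n_up": b.n_up,
                "n_down": b.n_down,
                "evidence": ";".join(b.evidence),
            }
            for b in best
        ],
        columns=["gene", "axis", "n_up", "n_down", "evidence"],
    )
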