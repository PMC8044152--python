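"""Configuration objects for the simulation and the pipeline.

All tunable constants of the analysis (QC thresholds, MAF cutoffs, the
similarity grid, the ISS cutoff) live here with the values used throughout
the package as defaults, so every run records exactly what it used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-data generator.

    The defaults encode the study conditions the pipeline is designed to
    reproduce: a ~34k-sample exome cohort in which idiopathic short stature
    (ISS) is the z < -2 tail of standardized height, a five-gene
    bidirectional set whose rare protein-altering alleles lower height by
    0.20 SD on average and carry an ISS odds ratio near 2.75, a polygenic
    score explaining 20% of height variance, and clinical-trial attrition in
    which genetically supported target-indication pairs are 4x as likely to
    travel from Phase I to approval.
    """

    seed: int = 0
    # cohort
    n_samples: int = 34_000
    n_genes: int = 40
    n_best_genes: int = 5
    carrier_freq: float = 0.01          # per-gene carrier probability
    rare_effect_sd: float = -0.20       # mean height effect per rare alt allele, SD units
    prs_h2: float = 0.20                # variance in height explained by the common-variant score
    iss_threshold: float = -2.0         # z-score cutoff defining ISS
    set_iss_or: float = 2.75            # target ISS odds ratio per rare alt allele in the set
    ptv_fraction: float = 0.10          # fraction of rare variants that are protein-truncating
    ptv_effect_sd: float = -0.85        # height effect per PTV allele, SD units
    mean_variants_per_gene: float = 204.0
    n_common_snps: int = 2_000
    n_gwas: int = 700_000               # GWAS sample size behind the summary statistics
    functional_slope: float = 0.9       # SD height per 100% cGMP activity in the focal gene
    # covariate structure (height in cm)
    sex_means_cm: tuple[float, float] = (162.2, 175.6)   # (female, male)
    sex_sd_cm: float = 6.6
    age_slope_cm: float = -0.05
    pc_slopes_cm: tuple[float, ...] = (0.3, -0.2, 0.1, 0.0, 0.0)
    # clinical trials
    trial_rr: float = 4.0               # planted PhaseI->Approval risk ratio for BEST support
    omim_rr: float = 2.0
    gwas_rr: float = 1.1
    phase_attrition: tuple[float, float, float] = (0.56, 0.36, 0.55)
    n_pairs: int = 26_884
    n_indications: int = 400
    best_target_share: float = 0.03     # fraction of pairs whose target is a BEST gene
    sim_threshold: float = 0.83         # similarity above which planted support applies

    def __post_init__(self) -> None:
        probs = {
            "carrier_freq": self.carrier_freq,
            "prs_h2": self.prs_h2,
            "best_target_share": self.best_target_share,
            "sim_threshold": self.sim_threshold,
            "ptv_fraction": self.ptv_fraction,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for i, p in enumerate(self.phase_attrition):
            if not 0.0 < p < 1.0:
                raise ConfigurationError(
                    f"phase_attrition[{i}] must be in (0, 1), got {p}"
                )
        if self.n_best_genes > self.n_genes:
            raise ConfigurationError("n_best_genes must not exceed n_genes")
        if self.n_best_genes < 0:
            raise ConfigurationError("n_best_genes must be non-negative")
        if self.trial_rr <= 0 or self.omim_rr <= 0 or self.gwas_rr <= 0:
            raise ConfigurationError("planted relative risks must be positive")
        if self.set_iss_or <= 0:
            raise ConfigurationError("set_iss_or must be positive")

    # -- seeding ---------------------------------------------------------
    # All randomness flows from one root seed through named substreams so
    # each stage is independently reproducible.
    def rng(self, stream: str) -> np.random.Generator:
        return substream(self.seed, stream)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("phase_attrition", "sex_means_cm", "pc_slopes_cm"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _stream_key(stream: str) -> tuple[int, ...]:
    digest = hashlib.sha256(stream.encode("utf-8")).digest()
    return tuple(int.from_bytes(digest[i : i + 4], "little") for i in range(0, 8, 4))


def substream(seed: int, stream: str) -> np.random.Generator:
    """Child generator for ``stream`` derived from a root ``seed``."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=_stream_key(stream))
    )


# ----------------------------------------------------------------------
# QC / analysis thresholds (defaults are the values used by the study design)


@dataclass
class QCThresholds:
    het_rate_low: float = 0.17
    het_rate_high: float = 0.21
    max_non_ref: int = 80_000
    max_singletons: int = 200
    het_hom_low: float = 1.3
    het_hom_high: float = 1.85
    sample_call_rate: float = 0.985
    chip_concordance: float = 0.98
    # the printed Ti/Tv rule (">2.5") would exclude typical exomes (~3.0);
    # off by default, available verbatim behind the flag
    apply_titv: bool = False
    titv_max: float = 2.5
    variant_call_rate: float = 0.99
    hwe_p: float = 1e-10
    external_af_p: float = 1e-7
    maf_cutoff: float = 1e-4
    min_cumulative_ac: int = 20


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, serializable to YAML."""

    out_dir: str = "bestgene_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    iss_threshold: float = -2.0
    similarity_grid_step: float = 0.01
    bonferroni_gene_tests: int = 5
    n_quintiles: int = 5
    stages: tuple[str, ...] = (
        "simulate", "screen", "approval", "qc", "assoc", "prs", "functional",
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds(**d["qc"])
        if "stages" in d and isinstance(d["stages"], list):
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
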