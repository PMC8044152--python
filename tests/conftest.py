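import numpy as np
import pandas as pd
import pytest

from bestgene.config import SimulationConfig
from bestgene.screen import DirectionLexicon
from bestgene.simulate import simulate_catalog, simulate_cohort, simulate_trials


def small_config(seed: int = 7, **kw) -> SimulationConfig:
    """A desk-scale configuration for unit tests: same structure as the
    default study conditions, smaller sizes."""
    defaults = dict(
        seed=seed, n_samples=3000, n_genes=12, n_best_genes=5,
        mean_variants_per_gene=30, n_common_snps=300, n_pairs=4000,
        n_indications=120,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def lexicon():
    return DirectionLexicon.default()


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def catalog(small_cfg):
    return simulate_catalog(small_cfg)


@pytest.fixture(scope="session")
def trials(small_cfg):
    return simulate_trials(small_cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """Full study-scale cohort (the default generator conditions), shared
    across the recovery tests to amortize the generation cost."""
    return simulate_cohort(SimulationConfig(seed=1))


def mini_lexicon() -> DirectionLexicon:
    return DirectionLexicon(
        {
            "X": {"up_terms": ["high x"], "down_terms": ["low x"]},
            "Y": {"up_terms": ["high y"], "down_terms": ["low y"]},
        },
        exclusions=["enzyme activity"],
    )


def make_catalog(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["gene", "disease", "variant_class"])
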