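import numpy as np
import pandas as pd
import pytest

from cryptomes.catalog import default_catalog
from cryptomes.simulate import SimulationConfig, generate_cohort
from cryptomes.trinuc import CHANNELS


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def orthogonal_catalog():
    """Three signatures with disjoint channel support (identifiable mixtures)."""
    vals = np.zeros((96, 3))
    vals[0:32, 0] = 1 / 32
    vals[32:64, 1] = 1 / 32
    vals[64:96, 2] = 1 / 32
    return pd.DataFrame(vals, index=pd.Index(CHANNELS, name="channel"),
                        columns=["ORTHO1", "ORTHO2", "ORTHO3"])


@pytest.fixture(scope="session")
def small_cohort():
    """Two-patient cohort small enough for fast unit tests."""
    cfg = SimulationConfig(
        seed=11, n_patients=2, crypts_per_patient=5, genome_length=120_000,
        germline_het_count=150, artifact_count=40, age_range=(35.0, 55.0),
        apobec_episode_prob=0.25,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def labelled_cohort():
    """The filter-chain benchmark cohort: 5 patients x 8 crypts at depth 25."""
    cfg = SimulationConfig(
        seed=7, n_patients=5, crypts_per_patient=8, genome_length=300_000,
        germline_het_count=400, artifact_count=150,
    )
    return cfg, generate_cohort(cfg)
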