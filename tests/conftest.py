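import numpy as np
import pytest

from phagoscope.markers import MarkerDB
from phagoscope.quantify import PhageGenomeDB, quantify_cohort
from phagoscope.simulate import (marker_db_from, phage_db_from,
                                 simulate_cohort, toy_config)


@pytest.fixture(scope="session")
def toy_cohort():
    """Small two-genus / three-phage cohort with six samples."""
    return simulate_cohort(toy_config(seed=1))


@pytest.fixture(scope="session")
def toy_phage_db(toy_cohort) -> PhageGenomeDB:
    return phage_db_from(toy_cohort.config, toy_cohort.genomes)


@pytest.fixture(scope="session")
def toy_marker_db(toy_cohort) -> MarkerDB:
    return marker_db_from(toy_cohort.genomes)


@pytest.fixture(scope="session")
def toy_quant(toy_cohort, toy_phage_db):
    return quantify_cohort(toy_cohort.contigs, toy_cohort.reads, toy_phage_db)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
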