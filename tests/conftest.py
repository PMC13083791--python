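import numpy as np
import pytest

from chromodyn import GenomicInterval, PeakSet, SampleKey
from chromodyn.simulate import simulate_study, study_config


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_counts():
    return {
        "PO": 60,
        "OC1": 20, "OC2": 15, "OC3": 12, "OC4": 10, "OC5": 8,
        "CO1": 25, "CO2": 20, "CO3": 15, "CO4": 12, "CO5": 10,
        "NE": 30,
    }


@pytest.fixture(scope="session")
def small_study(small_counts):
    """One small zero-noise study shared by read-only tests."""
    config = study_config(seed=7, module_counts=small_counts, n_null_genes=50)
    return simulate_study(config)


def make_peakset(condition, timepoint, triples):
    return PeakSet(
        intervals=tuple(GenomicInterval(c, s, e) for c, s, e in triples),
        sample=SampleKey(condition, timepoint),
    )
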