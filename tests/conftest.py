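import numpy as np
import pytest

from mediatornet.cohort import Cohort, SampleRecord
from mediatornet.panel import DEFAULT_PANEL
from mediatornet.simulate import generate_cohort, paperlike_config


def make_cohort(values_by_subgroup, panel=DEFAULT_PANEL):
    """Build a cohort from {(group, trimester): 2-D array (n x 27)}."""
    samples = []
    for (group, t), data in values_by_subgroup.items():
        data = np.asarray(data, dtype=float)
        for i, row in enumerate(data):
            conc = {a: float(v) for a, v in zip(panel.mediators, row)}
            samples.append(SampleRecord(f"{group}{t}-{i:03d}", group, t, conc))
    return Cohort(panel=panel, samples=samples)


def random_cohort(rng, sizes, scale=1.0, panel=DEFAULT_PANEL):
    """Independent log-normal cohort with the given subgroup sizes."""
    return make_cohort({key: scale * rng.lognormal(size=(n, 27))
                        for key, n in sizes.items()}, panel=panel)


@pytest.fixture(scope="session")
def panel():
    return DEFAULT_PANEL


@pytest.fixture(scope="session")
def paperlike_cohort():
    """One deterministic study-like synthetic cohort shared across tests."""
    return generate_cohort(paperlike_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230412)
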