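import numpy as np
import pytest

import simonlca as sl
from simonlca.model import Congruency, Response


@pytest.fixture(scope="session")
def default_params():
    return sl.ModelParameters()


@pytest.fixture(scope="session")
def preparation_variant():
    return sl.VariantSpec(pi_freq=0.9)


@pytest.fixture(scope="session")
def conditions():
    return [(r, c) for r in (Response.FREQUENT, Response.INFREQUENT)
            for c in (Congruency.CONGRUENT, Congruency.INCONGRUENT)]


@pytest.fixture(scope="session")
def small_dataset(default_params, preparation_variant):
    """A 6-participant synthetic dataset from the baseline design."""
    design = sl.PRESETS["exp1"]
    data, truth = sl.generate_synthetic_dataset(
        design, default_params, preparation_variant,
        sl.ParticipantVariability(), seed=2024, participants=6)
    return data, truth


def rng(seed=0):
    return np.random.default_rng(seed)
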