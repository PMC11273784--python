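import numpy as np
import pandas as pd
import pytest

from hemocloud.synthetic import EffectConfig, cohort_tables, generate_cohort
from hemocloud.types import HemodynamicCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cloud(rng, n=200, case_id="case_test"):
    """A valid random cloud with area weights."""
    xyz = rng.normal(size=(n, 3)) * 3.0
    return HemodynamicCloud.from_arrays(
        case_id,
        xyz,
        wss=rng.lognormal(1.0, 0.5, n),
        osi=rng.uniform(0.0, 0.5, n),
        pressure=rng.normal(13000, 200, n),
        velocity=rng.lognormal(-1.5, 0.3, n),
        area_weight=rng.uniform(0.5, 1.5, n),
    )


@pytest.fixture
def cloud_factory():
    return random_cloud


@pytest.fixture(scope="session")
def small_cohort():
    """30-case cohort with the default (label-linked) effect sizes."""
    cases = generate_cohort(EffectConfig(n_unruptured=22, n_ruptured=8, seed=7))
    return cases, cohort_tables(cases)
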