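"""Shared fixtures.

Expensive artefacts (the default synthetic study and its 46-feature table)
are built once per session; small-study fixtures keep unit tests fast.
"""

import numpy as np
import pytest

from egmst import SimConfig, build_feature_table, generate_study
from egmst.core_model import Channel, EGMTrace


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=7, n_subjects=2, points_per_map=30)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_study(small_cfg, check_prevalence=False)


@pytest.fixture(scope="session")
def small_table(small_study):
    return build_feature_table(small_study)


@pytest.fixture(scope="session")
def default_study():
    """The default simulated study conditions (seed 0)."""
    return generate_study(SimConfig(seed=0))


@pytest.fixture(scope="session")
def feature_table(default_study):
    return build_feature_table(default_study)


def make_trace(samples, fs=1000.0, kind=Channel.BIPOLAR,
               qrs_on=None, qrs_end=None, t_end=None):
    """EGMTrace from raw samples with sensible default windows."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    qrs_on = 0 if qrs_on is None else qrs_on
    qrs_end = n // 2 if qrs_end is None else qrs_end
    t_end = n if t_end is None else t_end
    return EGMTrace(x, fs, kind, qrs_on, qrs_end, t_end)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
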