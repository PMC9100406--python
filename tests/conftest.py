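"""Shared fixtures: small synthetic cohorts and their feature tables.

Session-scoped so the expensive generation + feature extraction runs once.
"""

import numpy as np
import pytest

import gaitdx as g


@pytest.fixture(scope="session")
def default_config() -> g.CohortConfig:
    return g.CohortConfig(seed=11)


@pytest.fixture(scope="session")
def small_config() -> g.CohortConfig:
    # 9 subjects x 6 cycles: enough for 5 subject-wise folds and per-fold SMOTE
    return g.CohortConfig(n_control=3, n_dn=3, n_dfu=3, cycles_per_subject=6, seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> list[g.GaitRecording]:
    return g.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    return g.extract_feature_tables(small_cohort, ("GL", "VL", "TA", "GRFz"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
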