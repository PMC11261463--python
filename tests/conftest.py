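import dataclasses

import numpy as np
import pytest

from cpmtools import CohortSpec, generate_cohort

SMALL_GROUPS = {"melancholic": 9, "non_melancholic": 8, "control": 7}


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Small but structurally complete cohort design for fast tests."""
    return CohortSpec(n_nodes=48, group_sizes=dict(SMALL_GROUPS),
                      edge_behavior_r=0.6, subtype_diff_d=1.5, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def respec(spec, **kw):
    return dataclasses.replace(spec, **kw)
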