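import dataclasses
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from netcog.atlas import default_atlas
from netcog.simulate import default_config, generate_cohort, generate_three_cohorts


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """One small cohort (n=200) with all three weightings."""
    cfg = default_config(seed=11, scale=0.1)
    return generate_cohort(cfg, "cohortA")


@pytest.fixture(scope="session")
def three_small_cohorts():
    cfg = default_config(seed=12, scale=0.1)
    return generate_three_cohorts(cfg)


@pytest.fixture(scope="session")
def clean_recovery_cohort():
    """n=2000 cohort with only the global SC-g effect (no edge effects)."""
    cfg = dataclasses.replace(default_config(seed=21, scale=1.0),
                              beta_edge_map=())
    return generate_cohort(cfg, "cohortA", weightings=("SC",))


def random_graph(rng: np.random.Generator, n: int, density: float = 0.5):
    """Random symmetric nonnegative weighted graph for oracle tests."""
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    w = np.where(present, rng.uniform(0.1, 5.0, len(iu[0])), 0.0)
    W[iu] = w
    return W + W.T
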