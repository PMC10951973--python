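import warnings

import numpy as np
import pytest

from stratmr import SimConfig, simulate_cohort

warnings.filterwarnings("ignore", message=".*did not converge.*")


def true_score(sim):
    """Raw weighted score from the generator's own weight table."""
    w = sim.variants
    return sim.cohort[list(w["variant_id"])].to_numpy(float) @ w["beta"].to_numpy(float)


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized cohort under full generator defaults (sick-quitter on)."""
    return simulate_cohort(SimConfig(n_individuals=30_000, seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """No causal effect, no confounding, no pleiotropy."""
    return simulate_cohort(SimConfig(
        n_individuals=20_000, seed=7, theta=0.0,
        confounding_strength=0.0, abstainer_fraction=0.0))
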