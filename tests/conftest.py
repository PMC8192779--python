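import numpy as np
import pandas as pd
import pytest

from stagenet.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at generator defaults, shared across read-only tests."""
    return generate_cohort(SimConfig(seed=0))


@pytest.fixture()
def tiny_expression():
    """A 4-gene, 7-sample matrix with one exact linear pair."""
    samples = [f"s{i}" for i in range(7)]
    rng = np.random.default_rng(42)
    base = rng.normal(7, 1, 7)
    em = pd.DataFrame(
        {
            "L1": base,
            "L2": rng.normal(7, 1, 7),
            "M1": 2 * base + 1,  # exactly collinear with L1
            "M2": rng.normal(7, 1, 7),
        },
        index=samples,
    ).T
    return em, samples
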