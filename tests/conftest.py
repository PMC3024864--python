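import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import premirclass as pm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return pm.EnergyModel()


@pytest.fixture(scope="session")
def gc_hairpin():
    """Three GC stacks closing a 4-nt loop: MFE -9 under the default model."""
    return pm.SequenceRecord("gc_hairpin", "GGGAAAACCC")


@pytest.fixture(scope="session")
def two_branch():
    """Legal two-hairpin fixture matching '((.((...)).((...)).))..'."""
    seq = "GGAGGAAACCAGGAAACCACCAA"
    struct = "((.((...)).((...)).)).."
    return pm.SequenceRecord("two_branch", seq), struct


@pytest.fixture(scope="session")
def separable_table():
    """Documented generator settings for the end-to-end recovery checks."""
    return pm.make_separable_table(n_pos=30, n_neg=90, effect_size=3.0, seed=7)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
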