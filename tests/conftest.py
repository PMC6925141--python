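import numpy as np
import pytest

from dwiprost import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def micro_spec():
    """A 18-patient cohort spec small enough for repeated training runs."""
    return synthetic.CohortSpec(
        composition={
            "train": (3, 3, 6, 26),
            "validation": (3, 3, 6, 26),
            "test": (3, 3, 6, 26),
        },
        image_size=64,
        seed=7,
    )


@pytest.fixture(scope="session")
def micro_cohort(micro_spec):
    studies, assignment = synthetic.generate_cohort(micro_spec)
    return studies, assignment
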