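import numpy as np
import pandas as pd
import pytest

from fairdep import Cohort


@pytest.fixture
def tiny_cohort() -> Cohort:
    """10 participants, 4 male / 6 female, mixed outcomes."""
    sex = ["male"] * 4 + ["female"] * 6
    return Cohort(
        ids=pd.Index([f"P{i}" for i in range(10)]),
        protected=pd.DataFrame({"sex": sex}),
        features=pd.DataFrame({"score": np.arange(10, dtype=float)}),
        labels=np.array([0, 1, 0, 1, 0, 0, 1, 1, 1, 0]),
    )


@pytest.fixture
def two_attr_cohort() -> Cohort:
    """Cohort with two protected attributes and a numeric + categorical feature."""
    rng = np.random.default_rng(7)
    n = 60
    return Cohort(
        ids=pd.RangeIndex(n),
        protected=pd.DataFrame(
            {
                "sex": rng.choice(["female", "male"], n),
                "age_band": rng.choice(["young", "mid", "old"], n),
            }
        ),
        features=pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "site": rng.choice(["A", "B"], n),
            }
        ),
        labels=rng.integers(0, 2, n),
    )
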