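import pandas as pd
import pytest
from hypothesis import settings

from dlqimap.olr import bundled_model
from dlqimap.synthetic import CohortConfig, generate_cohort

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def published_model():
    """The bundled published mapping model."""
    return bundled_model()


@pytest.fixture(scope="session")
def small_cohort():
    """A complete synthetic cohort (n=600) drawn from the bundled model."""
    return generate_cohort(CohortConfig(n=600, missing_rate=0.0, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    """A complete synthetic cohort (n=3000) for fitting tests."""
    return generate_cohort(CohortConfig(n=3000, missing_rate=0.0, seed=7))


@pytest.fixture()
def tiny_cohort():
    """A hand-built 3-subject cohort with observed EQ-5D."""
    rows = []
    for i, (age, sex, items, eq) in enumerate(
        [
            (30.0, 0, [0] * 10, [1, 1, 1, 1, 1]),
            (55.5, 1, [2, 1, 0, 3, 0, 0, 1, 0, 0, 1], [2, 1, 2, 2, 2]),
            (70.0, 1, [3] * 10, [3, 2, 3, 3, 3]),
        ]
    ):
        row = {"id": f"P{i+1}", "age": age, "sex": sex}
        row.update({f"dlqi{j+1}": items[j] for j in range(10)})
        row.update(
            dict(zip(["eq5d_mo", "eq5d_sc", "eq5d_ua", "eq5d_pd", "eq5d_ad"], eq))
        )
        rows.append(row)
    return pd.DataFrame(rows)
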