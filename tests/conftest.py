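import numpy as np
import pytest

from nearestcc.core_data import BINARY, CONTINUOUS, CohortTable, Schema


@pytest.fixture
def small_schema() -> Schema:
    return Schema(
        feature_names=("hb", "aca"),
        feature_kinds={"hb": CONTINUOUS, "aca": BINARY},
        class_column="class",
        time_column="months",
        event_column="event",
    )


@pytest.fixture
def small_table(small_schema) -> CohortTable:
    X = np.array([[12.0, 0.0], [13.5, 1.0], [10.1, 0.0], [14.2, 1.0]])
    return CohortTable(
        schema=small_schema,
        X=X,
        y=np.array(["1", "2", "1", "2"], dtype=object),
        time=np.array([30.0, 70.0, 45.0, 90.0]),
        event=np.array([1.0, 0.0, 1.0, 0.0]),
    )


def random_points(rng: np.random.Generator, m: int, d: int) -> np.ndarray:
    return rng.normal(size=(m, d))
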