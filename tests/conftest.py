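import numpy as np
import pandas as pd
import pytest

import tausustain as ts


@pytest.fixture
def two_region_events() -> ts.EventSet:
    """2 regions x thresholds (2, 5), ceiling 10 -> 4 events."""
    return ts.build_event_set(["A", "B"], [(2, 5), (2, 5)], [10, 10])


@pytest.fixture
def three_region_events() -> ts.EventSet:
    return ts.build_event_set(["A", "B", "C"], [(2, 5)] * 3, [10] * 3)


@pytest.fixture
def tiny_cohort_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": ["c1", "c2", "c3", "p1", "p1"],
            "visit_index": [0, 0, 0, 0, 1],
            "time_from_baseline": [0.0, 0.0, 0.0, 0.0, 1.5],
            "group": ["control"] * 3 + ["patient"] * 2,
            "A": [1.0, 1.2, 1.4, 2.0, 2.4],
            "B": [0.9, 1.0, 1.1, 1.8, 2.2],
        }
    )


@pytest.fixture
def tiny_cohort(tiny_cohort_frame) -> ts.CohortTable:
    return ts.CohortTable(data=tiny_cohort_frame, regions=("A", "B"))


@pytest.fixture
def fitted_small_model(two_region_events):
    """A deterministic 2-subtype model with opposite orderings."""
    es = two_region_events
    return ts.SubtypeModel(
        event_set=es,
        sequences=[np.array([0, 1, 2, 3]), np.array([2, 3, 0, 1])],
        fractions=np.array([0.5, 0.5]),
        sigma=np.ones(2),
    )
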