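import numpy as np
import pandas as pd
import pytest

from growthcv.data import Cohort
from growthcv.simulate import (faltering_preset, make_synthetic_reference,
                               simulate_cohort)


@pytest.fixture(scope="session")
def reference():
    return make_synthetic_reference((0.0, 730.0), "height")


@pytest.fixture(scope="session")
def weight_reference():
    return make_synthetic_reference((0.0, 1000.0), "weight")


@pytest.fixture(scope="session")
def faltering_cohort(reference):
    cfg = faltering_preset(n_subjects=80, seed=42)
    cohort, truth = simulate_cohort(cfg, reference)
    return cohort, truth, cfg


def make_cohort(rows):
    """Build a cohort from (sid, sex, age, kind, raw[, z]) tuples."""
    cols = ["subject_id", "sex", "age_days", "measure_kind", "value_raw",
            "value_z"]
    rows = [tuple(r) + (np.nan,) * (6 - len(r)) for r in rows]
    return Cohort(pd.DataFrame(rows, columns=cols))


@pytest.fixture
def tiny_cohort():
    return make_cohort([
        ("a", "male", 30.0, "height", 52.0),
        ("a", "male", 400.0, "height", 70.0),
        ("a", "male", 200.0, "height", 62.0),
        ("b", "female", 100.0, "height", 57.0),
        ("b", "female", 300.0, "height", 66.0),
    ])
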