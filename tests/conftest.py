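import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from audtrans.panel import CovariateSchema, PanelCohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_cohort(rows: list[dict], ranges: dict | None = None) -> PanelCohort:
    """Build a small validated cohort from literal observation rows."""
    from audtrans.panel import validate_panel

    df = pd.DataFrame(rows)
    covs = [c for c in df.columns if c not in ("subject_id", "time", "state", "age")]
    schema = CovariateSchema(ranges=ranges or {c: (-1e6, 1e6) for c in covs})
    return PanelCohort(data=validate_panel(df, schema), schema=schema)


@pytest.fixture
def toy_cohort():
    """Three subjects, irregular gaps, one covariate — small enough to hand-check."""
    return make_cohort([
        {"subject_id": "a", "time": 0.0, "state": 0, "age": 17.0, "x": 0.2},
        {"subject_id": "a", "time": 6.1, "state": 0, "age": 17.5, "x": -0.4},
        {"subject_id": "a", "time": 12.7, "state": 1, "age": 18.1, "x": 1.1},
        {"subject_id": "b", "time": 0.0, "state": 1, "age": 22.0, "x": 0.0},
        {"subject_id": "b", "time": 12.7, "state": 0, "age": 23.1, "x": 0.9},
        {"subject_id": "c", "time": 0.0, "state": 0, "age": 20.9, "x": -1.0},
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
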