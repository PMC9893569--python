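import numpy as np
import pandas as pd
import pytest

from healthineq.data import SurveyMicrodata


@pytest.fixture
def rng():
    return np.random.default_rng(20230301)


def make_microdata(
    income,
    weight=None,
    outcome=None,
    outcome_name="use",
    region=None,
    sex=None,
    age=None,
    extra=None,
    covariate_roles=None,
):
    """Hand-build a small SurveyMicrodata table for pipeline tests."""
    n = len(income)
    df = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "household_id": np.arange(n),
            "income_pc": np.asarray(income, float),
            "weight": np.ones(n) if weight is None else np.asarray(weight, float),
            "stratum_id": ["s0"] * n,
            "psu_id": [f"p{i % 4}" for i in range(n)],
            "region": ["South"] * n if region is None else list(region),
            "age": np.full(n, 40.0) if age is None else np.asarray(age, float),
            "sex": ["female"] * n if sex is None else list(sex),
        }
    )
    outcomes = []
    if outcome is not None:
        df[outcome_name] = np.asarray(outcome, float)
        outcomes = [outcome_name]
    for name, vals in (extra or {}).items():
        df[name] = vals
    return SurveyMicrodata(
        table=df, covariate_roles=dict(covariate_roles or {}), outcomes=outcomes
    ).validate()
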