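"""Person-level survey microdata container.

Canonical column names mirror the roles a household health survey provides:
``person_id``, ``household_id``, ``income_pc`` (household income per capita),
``weight`` (survey weight), ``stratum_id``, ``psu_id``, ``region``, ``age``,
``sex``, plus named covariate and binary-outcome columns.  Outcome columns are
floats taking 0.0, 1.0 or NaN — NaN marks persons outside an outcome's
eligible population (e.g. men for a mammogram indicator), so that eligibility
filtering is an explicit, testable pipeline step rather than a silent drop at
generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurveyMicrodata", "CORE_COLUMNS"]

CORE_COLUMNS = (
    "person_id",
    "household_id",
    "income_pc",
    "weight",
    "stratum_id",
    "psu_id",
    "region",
    "age",
    "sex",
)


@dataclass
class SurveyMicrodata:
    """A validated person-level table with declared covariate and outcome roles."""

    table: pd.DataFrame
    covariate_roles: dict = field(default_factory=dict)  # column -> Andersen role
    outcomes: list = field(default_factory=list)

    def validate(self) -> "SurveyMicrodata":
        df = self.table
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"microdata is missing required columns: {missing}")
        w = df["weight"].to_numpy(float)
        bad = np.nonzero(~np.isfinite(w) | (w <= 0))[0]
        if bad.size:
            raise ValueError(
                f"non-positive or non-finite weights at rows {bad[:10].tolist()}"
            )
        inc = df["income_pc"].to_numpy(float)
        bad = np.nonzero(~np.isfinite(inc) | (inc < 0))[0]
        if bad.size:
            raise ValueError(
                f"negative or non-finite income_pc at rows {bad[:10].tolist()}"
            )
        for col in self.outcomes:
            if col not in df.columns:
                raise ValueError(f"declared outcome column {col!r} is absent")
            vals = df[col].to_numpy(float)
            ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
            if not ok.all():
                rows = np.nonzero(~ok)[0]
                raise ValueError(
                    f"outcome {col!r} has non-binary values at rows "
                    f"{rows[:10].tolist()}"
                )
        for col in self.covariate_roles:
            if col not in df.columns:
                raise ValueError(f"declared covariate column {col!r} is absent")
            if df[col].isna().any():
                rows = np.nonzero(df[col].isna().to_numpy())[0]
                raise ValueError(
                    f"covariate {col!r} has missing values at rows "
                    f"{rows[:10].tolist()}"
                )
        return self

    @property
    def n(self) -> int:
        return len(self.table)

    def subset(self, mask) -> "SurveyMicrodata":
        """Row-subset sharing the same declarations (index is reset)."""
        return SurveyMicrodata(
            table=self.table.loc[mask].reset_index(drop=True),
            covariate_roles=dict(self.covariate_roles),
            outcomes=list(self.outcomes),
        )
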