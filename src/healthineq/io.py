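"""Reading and writing survey microdata with a sidecar column mapping.

Microdata travel as CSV (RFC-4180, UTF-8, header row) or Parquet.  Column
roles — which column is the income, the weight, which are covariates (and
their Andersen role) and which are outcomes — are declared in a YAML sidecar
mapping so externally produced tables with arbitrary column names can be
ingested.  ``write_microdata`` always emits the sidecar next to the data
file; the generator's ground truth is serialised as JSON the same way.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import CORE_COLUMNS, SurveyMicrodata
from .synthetic import GeneratorTruth, OutcomeTruth

__all__ = [
    "write_microdata",
    "read_microdata",
    "mapping_path",
    "write_truth",
    "read_truth",
]


def mapping_path(path) -> Path:
    return Path(str(path) + ".mapping.yaml")


def _build_mapping(data: SurveyMicrodata) -> dict:
    extra = [
        c
        for c in data.table.columns
        if c not in CORE_COLUMNS
        and c not in data.covariate_roles
        and c not in data.outcomes
    ]
    return {
        "roles": {role: role for role in CORE_COLUMNS},
        "covariates": dict(data.covariate_roles),
        "outcomes": list(data.outcomes),
        "extra_columns": extra,
    }


def write_microdata(data: SurveyMicrodata, path, format: str = "csv") -> Path:
    """Write the table plus a ``<path>.mapping.yaml`` sidecar; round-trips
    losslessly through :func:`read_microdata` (CSV floats use shortest
    round-trip representation)."""
    path = Path(path)
    if format == "csv":
        # shortest round-trip float representation keeps CSV lossless
        data.table.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    elif format == "parquet":
        data.table.to_parquet(path, index=False)
    else:
        raise ValueError(f"unsupported format {format!r}; use 'csv' or 'parquet'")
    with open(mapping_path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(_build_mapping(data), fh, sort_keys=False)
    return path


def read_microdata(path, mapping=None) -> SurveyMicrodata:
    """Read a microdata table and validate it against its column mapping.

    ``mapping`` may be a dict, a path to a YAML file, or None (the sidecar
    written by :func:`write_microdata` is looked up).  ``mapping["roles"]``
    maps each required role to the column carrying it; roles are renamed to
    the canonical column names on ingestion.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if mapping is None:
        mapping = mapping_path(path)
    if not isinstance(mapping, dict):
        with open(mapping, encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh)

    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, float_precision="round_trip")

    roles = mapping.get("roles", {})
    missing_roles = [r for r in CORE_COLUMNS if r not in roles]
    if missing_roles:
        raise ValueError(f"mapping lacks required roles: {missing_roles}")
    rename = {col: role for role, col in roles.items() if col != role}
    absent = [col for col in roles.values() if col not in df.columns]
    absent += [c for c in mapping.get("covariates", {}) if c not in df.columns]
    absent += [c for c in mapping.get("outcomes", []) if c not in df.columns]
    if absent:
        raise ValueError(f"mapped columns absent from {path.name}: {sorted(set(absent))}")
    df = df.rename(columns=rename)

    for col in mapping.get("outcomes", []):
        df[col] = df[col].astype(float)

    data = SurveyMicrodata(
        table=df,
        covariate_roles=dict(mapping.get("covariates", {})),
        outcomes=list(mapping.get("outcomes", [])),
    )
    return data.validate()


def write_truth(truth: GeneratorTruth, path) -> Path:
    path = Path(path)
    truth.to_json(path)
    return path


def read_truth(path) -> GeneratorTruth:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return GeneratorTruth(
        outcomes={k: OutcomeTruth(**v) for k, v in payload.items()}
    )
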