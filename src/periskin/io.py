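"""Cohort/feature table CSV schema with strict validation.

Canonical header::

    id, age, Wb, Wu, Wa, Pb, Pu, Md, Mw, D1..D7, sun_hours, sunscreen_freq, smoker

The derived D0 (any-disease) column is never stored; it is recomputed on
read. Validation errors name the offending column and the 1-based data row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import FEATURE_NAMES, DISEASE_CODES

SCHEMA = (
    "id",
    "age",
    *FEATURE_NAMES,
    *DISEASE_CODES,
    "sun_hours",
    "sunscreen_freq",
    "smoker",
)

_BINARY = (*DISEASE_CODES, "smoker")


class SchemaError(ValueError):
    """A cohort table violates the documented CSV schema."""


def validate_cohort(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` naming the first schema violation."""
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in SCHEMA and c != "D0"]
    if unknown:
        raise SchemaError(f"unknown column(s): {', '.join(unknown)}")

    def first_bad(mask: np.ndarray) -> int:
        return int(np.flatnonzero(mask)[0]) + 1  # 1-based data row

    age = df["age"].to_numpy(dtype=float)
    bad = ~np.isfinite(age) | (age < 0) | (age > 120)
    if bad.any():
        raise SchemaError(f"age out of range [0, 120] at row {first_bad(bad)}")
    for name in FEATURE_NAMES:
        vals = df[name].to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals < 0) | (vals > 100)
        if bad.any():
            raise SchemaError(
                f"feature {name} out of range [0, 100] at row {first_bad(bad)}"
            )
    for name in _BINARY:
        vals = df[name].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            raise SchemaError(f"column {name} must be binary 0/1 at row {first_bad(bad)}")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate subject id {dup!r}")


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table in canonical column order (D0 is not stored)."""
    validate_cohort(df)
    df.loc[:, list(SCHEMA)].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; the derived D0 column is recomputed."""
    df = pd.read_csv(path)
    validate_cohort(df)
    df = df.loc[:, list(SCHEMA)]
    df["D0"] = df.loc[:, list(DISEASE_CODES)].max(axis=1)
    return df
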