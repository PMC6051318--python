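"""Cohort tables: typed CSV reading and the packaged reference demographics."""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "read_cohort",
    "load_reference_cohort",
    "reference_cohort_summary",
]

_DEMO_COLUMNS = ("id", "age", "edu", "onset")


@dataclass
class CohortTable:
    """Per-patient demographics, labels and complete test-score battery."""

    data: pd.DataFrame
    test_columns: list

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def scores(self) -> pd.DataFrame:
        return self.data[self.test_columns]

    @property
    def demographics(self) -> pd.DataFrame:
        return self.data[list(_DEMO_COLUMNS)]

    def __repr__(self) -> str:
        return f"CohortTable(n={self.n}, tests={len(self.test_columns)})"


def read_cohort(csv_path: str | Path, expected_tests: list | None = None) -> CohortTable:
    """Read and validate a cohort CSV (comma-separated, period decimal, UTF-8).

    The header must contain id, age, edu, onset and every expected test
    column; scores must be numeric (strings like ``"87%"`` are rejected) and
    complete, and ids must be unique.
    """
    df = pd.read_csv(csv_path, encoding="utf-8")
    if expected_tests is None:
        expected_tests = [c for c in df.columns if c.startswith("test_")]
    missing = [c for c in (*_DEMO_COLUMNS, *expected_tests) if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing required column(s): {missing}")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"{csv_path}: duplicate patient id(s): {dup}")
    numeric = ["age", "edu", "onset", *expected_tests]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df[col][parsed.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{csv_path}: non-numeric value(s) in {col!r}: {bad.iloc[0]!r}"
            )
        if parsed.isna().any():
            raise ValueError(f"{csv_path}: missing value(s) in {col!r}")
        df[col] = parsed
    if (df[["age", "edu", "onset"]] <= 0).any().any():
        raise ValueError(f"{csv_path}: age/edu/onset must be positive")
    return CohortTable(df, list(expected_tests))


def load_reference_cohort() -> pd.DataFrame:
    """The packaged 70-patient chronic-aphasia reference demographics.

    Columns: id, subtype (BDAE label), sex, age (years), edu (years),
    onset (months post stroke) and lesion_volume (voxels at 2 mm isotropic).
    """
    with resources.files("aphasiamap.data").joinpath("reference_cohort.csv").open() as f:
        return pd.read_csv(f)


def reference_cohort_summary() -> dict:
    """Recomputed summary statistics of the reference cohort."""
    df = load_reference_cohort()
    return {
        "n": int(len(df)),
        "n_male": int((df["sex"] == "m").sum()),
        "mean_age": round(float(df["age"].mean()), 2),
        "sd_age": round(float(df["age"].std(ddof=1)), 2),
        "mean_edu": round(float(df["edu"].mean()), 2),
        "sd_edu": round(float(df["edu"].std(ddof=1)), 2),
        "mean_onset": round(float(df["onset"].mean()), 1),
        "sd_onset": round(float(df["onset"].std(ddof=1)), 2),
        "min_lesion_volume": int(df["lesion_volume"].min()),
        "max_lesion_volume": int(df["lesion_volume"].max()),
        "subtype_counts": df["subtype"].value_counts().to_dict(),
    }
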