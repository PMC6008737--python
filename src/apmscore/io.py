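"""Cohort CSV reading, validation and writing.

One dialect only: comma-separated, UTF-8, header required.  The documented
schema is ``id, apm_mm_1, apm_mm_2, apm_mm_3, apm_mm, gcs, apache2, apache3,
age, sex, albumin_g_dl, subtype, death``; extra columns (per-variable point
decompositions, nuisance covariates) pass through untouched.  When ``apm_mm``
is absent but the three raw readings are present, the averaged (and rounded)
thickness is filled in.
"""

from __future__ import annotations

import pandas as pd

from .severity import (
    APACHE2_MAX,
    APACHE3_MAX,
    ApmMeasurement,
    ValidationError,
    average_apm,
)

__all__ = ["REQUIRED_COLUMNS", "OPTIONAL_COLUMNS", "read_cohort", "write_cohort",
           "CohortValidationError"]

REQUIRED_COLUMNS = ("id", "apm_mm", "gcs", "apache2", "apache3", "death")
OPTIONAL_COLUMNS = ("apm_mm_1", "apm_mm_2", "apm_mm_3", "age", "sex",
                    "albumin_g_dl", "subtype")

READING_COLS = ("apm_mm_1", "apm_mm_2", "apm_mm_3")


class CohortValidationError(ValidationError):
    """Row-level validation failures, with 1-based data row numbers."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("cohort validation failed:\n  " + "\n  ".join(errors))


def _row_errors(df: pd.DataFrame) -> list[str]:
    errs: list[str] = []

    def check(mask, message):
        for idx in df.index[mask]:
            errs.append(f"row {idx + 1}: {message}")

    check(~df["death"].isin([0, 1]), "death not in {0, 1}")
    check(~df["apm_mm"].between(1, 40), "apm_mm outside [1, 40] mm")
    check(~df["apache2"].between(0, APACHE2_MAX),
          f"apache2 outside [0, {APACHE2_MAX}]")
    check(~df["apache3"].between(0, APACHE3_MAX),
          f"apache3 outside [0, {APACHE3_MAX}]")
    check(~df["gcs"].between(3, 15), "gcs outside [3, 15]")
    return errs


def read_cohort(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    In strict mode (default) any validation failure raises
    :class:`CohortValidationError` listing every offending row; with
    ``strict=False`` offending rows are dropped and the errors attached to
    the returned frame as ``df.attrs["row_errors"]``.
    """
    df = pd.read_csv(path)
    have_readings = all(c in df.columns for c in READING_COLS)
    missing = [c for c in REQUIRED_COLUMNS
               if c not in df.columns and not (c == "apm_mm" and have_readings)]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")
    numeric = [c for c in ("apm_mm", "gcs", "apache2", "apache3", "death",
                           *READING_COLS, "age", "albumin_g_dl")
               if c in df.columns]
    for c in numeric:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            raise ValidationError(
                f"non-numeric value in column '{c}' at row(s) "
                f"{[i + 1 for i in df.index[bad]][:5]}")
        df[c] = coerced
    if "apm_mm" not in df.columns or df["apm_mm"].isna().all():
        df["apm_mm"] = [
            average_apm(ApmMeasurement((r1, r2, r3)))[1]
            for r1, r2, r3 in df[list(READING_COLS)].itertuples(index=False)
        ]
    errs = _row_errors(df)
    if errs:
        if strict:
            raise CohortValidationError(errs)
        bad_rows = sorted({int(e.split()[1].rstrip(":")) - 1 for e in errs})
        df = df.drop(index=bad_rows).reset_index(drop=True)
        df.attrs["row_errors"] = errs
    df["death"] = df["death"].astype(int)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV (comma, UTF-8, header; stable column order)."""
    front = [c for c in (*REQUIRED_COLUMNS[:1], *READING_COLS, "apm_mm", "gcs",
                         "apache2", "apache3", "age", "sex", "albumin_g_dl",
                         "subtype", "death") if c in df.columns]
    rest = [c for c in df.columns if c not in front]
    df[front + rest].to_csv(path, index=False)
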