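"""Knee-level cohort table schema and validation.

A cohort table is a pandas DataFrame with one row per knee:

* ``person_id`` — individual identifier (two rows per person),
* ``side`` — 1 for the left knee, 2 for the right,
* ``outcome`` — the binary dependent variable (0/1),
* remaining columns — numeric covariates, identical schema for every row.

Person-level covariates simply repeat across a person's two rows; nothing in
the schema distinguishes them from knee-level ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import CohortValidationError

PERSON_COL = "person_id"
SIDE_COL = "side"
OUTCOME_COL = "outcome"
RESERVED_COLS = (PERSON_COL, SIDE_COL, OUTCOME_COL)


def covariate_columns(cohort: pd.DataFrame) -> list[str]:
    """Names of the covariate columns, in table order."""
    return [c for c in cohort.columns if c not in RESERVED_COLS]


def covariate_matrix(cohort: pd.DataFrame) -> np.ndarray:
    """Covariates as a float matrix, rows aligned with the table."""
    return cohort[covariate_columns(cohort)].to_numpy(dtype=float)


def validate_cohort(cohort: pd.DataFrame, require_pairs: bool = True) -> pd.DataFrame:
    """Check cohort invariants; return the table unchanged if valid.

    Raises
    ------
    CohortValidationError
        Missing schema columns, missing values, non-binary outcomes, sides
        outside {1, 2}, duplicated (person, side) rows, or (when
        ``require_pairs``) persons lacking exactly one row per side.
    """
    missing = [c for c in RESERVED_COLS if c not in cohort.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    if cohort.isna().any().any():
        bad = cohort.columns[cohort.isna().any()].tolist()
        raise CohortValidationError(f"missing values in columns: {bad}")
    outcome = cohort[OUTCOME_COL]
    if not outcome.isin([0, 1]).all():
        bad_vals = sorted(set(outcome) - {0, 1})
        raise CohortValidationError(
            f"column '{OUTCOME_COL}' must be binary 0/1; found {bad_vals}"
        )
    if not cohort[SIDE_COL].isin([1, 2]).all():
        raise CohortValidationError(f"column '{SIDE_COL}' must contain only 1 or 2")
    if cohort.duplicated([PERSON_COL, SIDE_COL]).any():
        raise CohortValidationError("duplicate (person_id, side) rows")
    if require_pairs:
        counts = cohort.groupby(PERSON_COL)[SIDE_COL].count()
        if (counts != 2).any():
            n_bad = int((counts != 2).sum())
            raise CohortValidationError(
                f"{n_bad} person(s) do not have exactly two rows (one per side)"
            )
    return cohort


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as UTF-8 comma-separated text with a header row."""
    validate_cohort(cohort).to_csv(path, index=False)
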