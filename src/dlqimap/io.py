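"""Cohort CSV parsing/writing and the in-memory cohort table schema.

A cohort is a :class:`pandas.DataFrame` with one row per subject and columns

    id, age, sex, dlqi1 .. dlqi10, eq5d_mo, eq5d_sc, eq5d_ua, eq5d_pd, eq5d_ad
    [, diagnosis, country]

EQ-5D columns are optional (a mapping-only cohort has none).  Empty cells are
missing values (NaN); within-questionnaire missing DLQI items are scored zero
at modelling time per the instrument rule, whereas missing age, sex or any
EQ-5D domain make a subject an incomplete case.

CSV dialect: comma-separated, ``.`` decimal, UTF-8, mandatory header.  Lines
starting with ``#`` are provenance comments and are skipped on read.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .instruments import (
    EQ5D_DOMAINS,
    N_ITEMS,
    DlqiResponse,
    Eq5dState,
    SubjectRecord,
)

ID_COL = "id"
AGE_COL = "age"
SEX_COL = "sex"
DLQI_COLS = tuple(f"dlqi{i}" for i in range(1, N_ITEMS + 1))
#: Map canonical domain name -> CSV column.
EQ5D_COLS = {
    "mobility": "eq5d_mo",
    "self_care": "eq5d_sc",
    "usual_activities": "eq5d_ua",
    "pain_discomfort": "eq5d_pd",
    "anxiety_depression": "eq5d_ad",
}
EQ5D_COL_ORDER = tuple(EQ5D_COLS[d] for d in EQ5D_DOMAINS)
REQUIRED_COLS = (ID_COL, AGE_COL, SEX_COL) + DLQI_COLS
OPTIONAL_COLS = EQ5D_COL_ORDER + ("diagnosis", "country")


class CohortSchemaError(ValueError):
    """Raised when a cohort file violates the schema."""


def has_eq5d(cohort: pd.DataFrame) -> bool:
    return all(c in cohort.columns for c in EQ5D_COL_ORDER)


def dlqi_item_matrix(cohort: pd.DataFrame) -> np.ndarray:
    """(n, 10) float item-score matrix with missing items scored zero."""
    return cohort.loc[:, list(DLQI_COLS)].to_numpy(dtype=float, na_value=0.0)


def dlqi_totals(cohort: pd.DataFrame) -> np.ndarray:
    """Total DLQI score per subject (missing items scored zero)."""
    return dlqi_item_matrix(cohort).sum(axis=1)


def eq5d_level_matrix(cohort: pd.DataFrame) -> np.ndarray:
    """(n, 5) observed EQ-5D levels in canonical domain order (NaN = missing)."""
    if not has_eq5d(cohort):
        raise CohortSchemaError("cohort has no EQ-5D columns")
    return cohort.loc[:, list(EQ5D_COL_ORDER)].to_numpy(dtype=float)


def _check_range(df: pd.DataFrame, col: str, valid: set, kind: str) -> None:
    values = df[col]
    bad = values.notna() & ~values.isin(valid)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortSchemaError(
            f"row {row + 1}, column {col}: {kind} value {values.iloc[row]!r} "
            f"outside {sorted(valid)}"
        )


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table in place and return it.

    Checks the header, value ranges and id uniqueness; row numbers in error
    messages are 1-based data rows (excluding the header).
    """
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort is missing required columns: {missing}")
    present_eq5d = [c for c in EQ5D_COL_ORDER if c in df.columns]
    if present_eq5d and len(present_eq5d) != 5:
        raise CohortSchemaError(
            f"cohort has a partial EQ-5D block: only {present_eq5d} present"
        )
    if df[ID_COL].isna().any():
        raise CohortSchemaError("empty subject id")
    dup = df[ID_COL][df[ID_COL].duplicated()]
    if len(dup):
        raise CohortSchemaError(f"duplicate subject id {dup.iloc[0]!r}")
    age = pd.to_numeric(df[AGE_COL], errors="coerce")
    bad_age = df[AGE_COL].notna() & (age < 0)
    if bad_age.any():
        row = int(np.flatnonzero(bad_age.to_numpy())[0])
        raise CohortSchemaError(f"row {row + 1}, column age: negative age")
    _check_range(df, SEX_COL, {0, 1}, "sex")
    for col in DLQI_COLS:
        _check_range(df, col, {0, 1, 2, 3}, "DLQI item")
    for col in present_eq5d:
        _check_range(df, col, {1, 2, 3}, "EQ-5D level")
    return df


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    df = pd.read_csv(path, comment="#", dtype={ID_COL: str})
    return validate_cohort(df)


def _provenance_comment(**meta) -> str:
    fields = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# dlqimap version={__version__} {fields}".rstrip() + "\n"


def write_cohort(cohort: pd.DataFrame, path, **provenance) -> None:
    """Write a cohort CSV with a leading provenance comment line."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_comment(**provenance))
        cohort.to_csv(fh, index=False)


def write_predictions(path, predictions, reps: Optional[int] = None, **provenance) -> None:
    """Write per-subject utility predictions to CSV.

    ``predictions`` is an iterable of :class:`dlqimap.prediction.UtilityPrediction`.
    Columns: id, mean_utility (full precision), mean_utility_4dp (display
    rounding), analytic_utility, then per-rep state/utility columns when more
    than one rep was requested.
    """
    predictions = list(predictions)
    rows = []
    for p in predictions:
        row = {
            "id": p.subject_id,
            "mean_utility": p.mean_utility,
            "mean_utility_4dp": round(p.mean_utility, 4),
            "analytic_utility": p.analytic_expected_utility,
        }
        n_reps = reps if reps is not None else len(p.utilities)
        if n_reps > 1:
            for r in range(len(p.utilities)):
                row[f"rep{r + 1}_state"] = "".join(str(l) for l in p.states[r])
                row[f"rep{r + 1}_utility"] = p.utilities[r]
        rows.append(row)
    base_cols = ["id", "mean_utility", "mean_utility_4dp", "analytic_utility"]
    df = pd.DataFrame(rows, columns=base_cols if not rows else None)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_comment(**provenance))
        df.to_csv(fh, index=False)


def cohort_to_records(cohort: pd.DataFrame) -> list[SubjectRecord]:
    """Convert complete-case cohort rows to typed subject records."""
    records = []
    eq5d_present = has_eq5d(cohort)
    for _, row in cohort.iterrows():
        raw = [None if pd.isna(row[c]) else int(row[c]) for c in DLQI_COLS]
        items = tuple(0 if v is None else v for v in raw)
        mask = tuple(v is None for v in raw)
        dlqi = DlqiResponse(items=items, missing_mask=mask)
        eq5d = None
        if eq5d_present and not any(pd.isna(row[c]) for c in EQ5D_COL_ORDER):
            eq5d = Eq5dState(*(int(row[EQ5D_COLS[d]]) for d in EQ5D_DOMAINS))
        records.append(
            SubjectRecord(
                id=str(row[ID_COL]),
                age=float(row[AGE_COL]),
                sex=int(row[SEX_COL]),
                dlqi=dlqi,
                eq5d=eq5d,
                diagnosis=row.get("diagnosis") if "diagnosis" in cohort.columns else None,
                country=row.get("country") if "country" in cohort.columns else None,
            )
        )
    return records
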