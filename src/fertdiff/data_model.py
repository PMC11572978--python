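"""Shared domain tables and validated CSV input/output.

Every table flowing through the pipeline is a tidy :class:`pandas.DataFrame`
with a named schema: one row per cell, keyed columns, and invariants that are
checked on every read and write.  The schemas are:

``fertility_surface``
    Education-age-specific period fertility rates (births per woman per
    year), keyed by (country, period, age_group, education).  Periods and
    age groups are labelled by the start year/age of their 5-year interval.
``cohort_cfr``
    Completed cohort fertility (children per woman) keyed by
    (country, cohort, education), with a provenance ``status`` flag:
    ``observed`` (summed from a complete diagonal), ``completed``
    (truncated cohort finished by rate extrapolation) or ``projected``.
``slamys``
    Cohort-indexed Skills in Literacy Adjusted Mean Years of Schooling,
    keyed by (region, cohort).  Region is a country code or ``AFRICA``.
``education_weights``
    Female cohort composition by education, keyed by
    (country, cohort, education); weights sum to one within a cohort.
``diffusion_rates``
    One fractional rate per education group: the change in cohort fertility
    per unit change in SLAMYS (e.g. -0.102 means -10.2% per schooling year).
``microdata``
    Survey-style woman-level records (stratum, cluster, education, stratum
    mean years of schooling, ideal family size, children ever born, age,
    urban flag) feeding the strata-level Poisson model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "EDUCATION_LEVELS",
    "AGE_GROUPS",
    "STATUS_LEVELS",
    "SCHEMAS",
    "SchemaError",
    "ValidationError",
    "read_table",
    "write_table",
    "validate_table",
]

#: The four attainment categories used throughout, lowest to highest.
EDUCATION_LEVELS = ("none", "primary", "secondary", "higher")

#: Education codes accepted in rate/CFR tables: the four groups plus the
#: all-education aggregate used for benchmark period-fertility series.
_EDUCATION_CODES = EDUCATION_LEVELS + ("total",)

#: Start ages of the 5-year age groups a fertility surface may carry.
#: Cohort summation uses 15..40 only; 45 is carried but never summed.
AGE_GROUPS = (15, 20, 25, 30, 35, 40, 45)

STATUS_LEVELS = ("observed", "completed", "projected")


class SchemaError(ValueError):
    """Header does not match the schema (missing or unexpected columns)."""


class ValidationError(ValueError):
    """Table content violates a schema invariant; message names row and rule."""


def _check_numeric(df: pd.DataFrame, col: str, problems: list[str],
                   lo: float | None = None, hi: float | None = None,
                   allow_na: bool = False) -> None:
    s = pd.to_numeric(df[col], errors="coerce")
    bad_na = (s.isna() & df[col].notna()) if allow_na else s.isna()
    for idx in df.index[bad_na][:5]:
        problems.append(f"row {idx}: column '{col}' is not numeric")
    if lo is not None:
        for idx in df.index[(s < lo).fillna(False)][:5]:
            problems.append(f"row {idx}: {col}={df.loc[idx, col]} violates {col} >= {lo}")
    if hi is not None:
        for idx in df.index[(s > hi).fillna(False)][:5]:
            problems.append(f"row {idx}: {col}={df.loc[idx, col]} violates {col} <= {hi}")


def _check_multiple_of_5(df: pd.DataFrame, col: str, problems: list[str]) -> None:
    bad = df.index[(df[col].astype(float) % 5) != 0]
    for idx in bad[:5]:
        problems.append(f"row {idx}: {col}={df.loc[idx, col]} is not a multiple of 5")


def _check_categories(df: pd.DataFrame, col: str, allowed: tuple, problems: list[str]) -> None:
    bad = df.index[~df[col].isin(allowed)]
    for idx in bad[:5]:
        problems.append(
            f"row {idx}: {col}='{df.loc[idx, col]}' not in {sorted(allowed)}")


def _check_unique_key(df: pd.DataFrame, key: tuple, problems: list[str]) -> None:
    dup = df.duplicated(subset=list(key), keep=False)
    if dup.any():
        first = df.loc[dup, list(key)].iloc[0].tolist()
        problems.append(
            f"duplicated key {tuple(key)}: first duplicate {first} "
            f"({int(dup.sum())} rows involved)")


def _check_counts(df: pd.DataFrame, col: str, problems: list[str],
                  allow_na: bool = False) -> None:
    s = pd.to_numeric(df[col], errors="coerce")
    mask = s.notna()
    nonint = mask & (s != np.floor(s))
    for idx in df.index[nonint][:5]:
        problems.append(f"row {idx}: {col}={df.loc[idx, col]} is not an integer count")
    neg = mask & (s < 0)
    for idx in df.index[neg][:5]:
        problems.append(f"row {idx}: {col}={df.loc[idx, col]} is negative")
    if not allow_na and (~mask).any():
        idx = df.index[~mask][0]
        problems.append(f"row {idx}: {col} is missing")


def _validate_fertility_surface(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    _check_numeric(df, "rate", problems, lo=0.0, hi=1.0)
    _check_multiple_of_5(df, "period", problems)
    _check_categories(df, "age_group", AGE_GROUPS, problems)
    _check_categories(df, "education", _EDUCATION_CODES, problems)
    _check_unique_key(df, ("country", "period", "age_group", "education"), problems)
    return problems


def _validate_cohort_cfr(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    _check_numeric(df, "cfr", problems, lo=0.0, hi=15.0)
    _check_multiple_of_5(df, "cohort", problems)
    _check_categories(df, "education", _EDUCATION_CODES, problems)
    _check_categories(df, "status", STATUS_LEVELS, problems)
    _check_unique_key(df, ("country", "cohort", "education"), problems)
    return problems


def _validate_slamys(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    _check_numeric(df, "slamys", problems, lo=0.0)
    _check_unique_key(df, ("region", "cohort"), problems)
    return problems


def _validate_weights(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    _check_numeric(df, "weight", problems, lo=0.0)
    _check_categories(df, "education", EDUCATION_LEVELS, problems)
    _check_unique_key(df, ("country", "cohort", "education"), problems)
    if not problems and len(df):
        sums = df.groupby(["country", "cohort"])["weight"].sum()
        off = sums[(sums - 1.0).abs() > 1e-9]
        for (country, cohort), s in off.head(5).items():
            problems.append(
                f"weights for ({country}, {cohort}) sum to {s!r}, not 1 (tol 1e-9)")
    return problems


def _validate_diffusion_rates(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    _check_categories(df, "education", EDUCATION_LEVELS, problems)
    _check_unique_key(df, ("education",), problems)
    s = pd.to_numeric(df["rate"], errors="coerce")
    for idx in df.index[~np.isfinite(s)][:5]:
        problems.append(f"row {idx}: rate={df.loc[idx, 'rate']} is not finite")
    return problems


def _validate_microdata(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    _check_categories(df, "education", EDUCATION_LEVELS, problems)
    _check_numeric(df, "stratum_mys", problems, lo=0.0)
    _check_counts(df, "ideal_family_size", problems)
    _check_counts(df, "children_ever_born", problems, allow_na=True)
    _check_numeric(df, "age", problems, lo=0)
    _check_unique_key(df, ("woman_id",), problems)
    # a sampling cluster belongs to exactly one stratum
    n_strata = df.groupby("cluster_id")["stratum_id"].nunique()
    for cluster in n_strata.index[n_strata > 1][:5]:
        problems.append(
            f"cluster_id {cluster} maps to {n_strata[cluster]} strata, expected 1")
    return problems


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple
    key: tuple
    validator: Callable[[pd.DataFrame], list[str]]
    dtypes: dict = field(default_factory=dict)


SCHEMAS: dict[str, TableSchema] = {
    "fertility_surface": TableSchema(
        "fertility_surface",
        ("country", "period", "age_group", "education", "rate"),
        ("country", "period", "age_group", "education"),
        _validate_fertility_surface,
        {"country": str, "period": np.int64, "age_group": np.int64,
         "education": str, "rate": np.float64},
    ),
    "cohort_cfr": TableSchema(
        "cohort_cfr",
        ("country", "cohort", "education", "cfr", "status"),
        ("country", "cohort", "education"),
        _validate_cohort_cfr,
        {"country": str, "cohort": np.int64, "education": str,
         "cfr": np.float64, "status": str},
    ),
    "slamys": TableSchema(
        "slamys",
        ("region", "cohort", "slamys"),
        ("region", "cohort"),
        _validate_slamys,
        {"region": str, "cohort": np.int64, "slamys": np.float64},
    ),
    "education_weights": TableSchema(
        "education_weights",
        ("country", "cohort", "education", "weight"),
        ("country", "cohort", "education"),
        _validate_weights,
        {"country": str, "cohort": np.int64, "education": str,
         "weight": np.float64},
    ),
    "diffusion_rates": TableSchema(
        "diffusion_rates",
        ("education", "rate"),
        ("education",),
        _validate_diffusion_rates,
        {"education": str, "rate": np.float64},
    ),
    "microdata": TableSchema(
        "microdata",
        ("woman_id", "stratum_id", "cluster_id", "education", "stratum_mys",
         "ideal_family_size", "children_ever_born", "age", "urban"),
        ("woman_id",),
        _validate_microdata,
        {"woman_id": np.int64, "stratum_id": np.int64, "cluster_id": np.int64,
         "education": str, "stratum_mys": np.float64,
         "ideal_family_size": np.int64, "children_ever_born": "Int64",
         "age": np.int64, "urban": np.bool_},
    ),
}

# education sorts low-to-high attainment, not alphabetically
_EDU_ORDER = {e: i for i, e in enumerate(_EDUCATION_CODES)}


def _canonical_sort(df: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    if not len(df):
        return df.reset_index(drop=True)
    work = df.copy()
    sort_cols = []
    for col in schema.key:
        if col == "education":
            work["_edu_rank"] = work["education"].map(_EDU_ORDER).fillna(99)
            sort_cols.append("_edu_rank")
        else:
            sort_cols.append(col)
    work = work.sort_values(sort_cols, kind="mergesort")
    return work[list(schema.columns)].reset_index(drop=True)


def _coerce(df: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    out = df.copy()
    for col, dtype in schema.dtypes.items():
        if col == "children_ever_born":
            out[col] = pd.array(pd.to_numeric(out[col], errors="coerce"),
                                dtype="Int64")
        elif dtype is np.bool_ and out[col].dtype == object:
            out[col] = out[col].map(
                {"True": True, "False": False, True: True, False: False})
        elif dtype is np.int64:
            # keep non-integral values as float so the validator can name
            # the offending row instead of truncating silently
            s = pd.to_numeric(out[col])
            out[col] = s.astype(np.int64) if (len(s) == 0 or
                                              (s == np.floor(s)).all()) else s
        else:
            out[col] = out[col].astype(dtype)
    return out


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Check ``df`` against the named schema; return a coerced, sorted copy.

    Raises
    ------
    SchemaError
        If the column set does not match the schema exactly.
    ValidationError
        If any invariant fails; the message names the row and the rule.
    """
    try:
        spec = SCHEMAS[schema]
    except KeyError:
        raise SchemaError(f"unknown schema '{schema}'; "
                          f"known: {sorted(SCHEMAS)}") from None
    missing = [c for c in spec.columns if c not in df.columns]
    extra = [c for c in df.columns if c not in spec.columns]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns {missing}")
        if extra:
            parts.append(f"unexpected columns {extra}")
        raise SchemaError(f"schema '{schema}': " + "; ".join(parts))
    try:
        df = _coerce(df[list(spec.columns)], spec)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"schema '{schema}': cannot coerce column "
                              f"types ({exc})") from exc
    problems = spec.validator(df)
    if problems:
        raise ValidationError(
            f"schema '{schema}': " + "; ".join(problems))
    return _canonical_sort(df, spec)


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV file and validate it against the named schema."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    spec = SCHEMAS[schema]
    # empty strings are missing values only where the schema allows them
    for col in df.columns:
        if col in spec.columns and col != "children_ever_born":
            if df[col].isna().any():
                idx = df.index[df[col].isna()][0]
                raise ValidationError(
                    f"schema '{schema}': row {idx}: column '{col}' is empty")
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Validate and write a table as canonical CSV (sorted by key).

    The written file round-trips: ``read_table(path, schema)`` reproduces the
    values exactly (floats are printed with shortest round-trip ``repr``).
    """
    out = validate_table(df, schema)
    out.to_csv(path, index=False)
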