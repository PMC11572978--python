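"""Period-to-cohort conversion of education-specific fertility rates.

A birth cohort labelled by start year *t* passes through age group 15-19 in
period *t*+15, 20-24 in *t*+20, ..., 40-44 in *t*+40 — its *cohort
diagonal*.  Completed cohort fertility (CFR, children per woman) is five
times the sum of the six annual age-specific rates along that diagonal;
rates for ages 45-49, when present, are carried in the surface but never
summed, as childbearing is treated as complete within 40-44.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .data_model import validate_table

__all__ = ["SUMMED_AGES", "IncompleteCohortError", "cohort_cells",
           "period_to_cohort_cfr", "convert_all"]

logger = logging.getLogger(__name__)

#: Start ages of the age groups entering the CFR sum (45-49 excluded).
SUMMED_AGES = (15, 20, 25, 30, 35, 40)


class IncompleteCohortError(LookupError):
    """A cohort diagonal has missing cells; lists the missing pairs."""

    def __init__(self, country: str, education: str, cohort: int,
                 missing: list):
        self.country = country
        self.education = education
        self.cohort = cohort
        self.missing = list(missing)
        super().__init__(
            f"cohort {cohort} ({country}, {education}) is incomplete: "
            f"missing (age_group, period) cells {self.missing}")


def cohort_cells(cohort: int) -> list[tuple[int, int]]:
    """The six (age_group, period) cells of a cohort's diagonal."""
    if cohort % 5 != 0:
        raise ValueError(f"cohort {cohort} is not a multiple of 5")
    return [(age, cohort + age) for age in SUMMED_AGES]


def period_to_cohort_cfr(surface: pd.DataFrame, country: str,
                         education: str, cohort: int) -> float:
    """Completed cohort fertility: 5 x the sum over the cohort diagonal.

    Raises :class:`IncompleteCohortError` listing the missing
    (age_group, period) pairs when any of the six cells is absent.
    """
    cells = cohort_cells(cohort)
    sub = surface[(surface["country"] == country)
                  & (surface["education"] == education)]
    lookup = {(a, p): r for a, p, r in
              zip(sub["age_group"], sub["period"], sub["rate"])}
    missing = [cell for cell in cells if cell not in lookup]
    if missing:
        raise IncompleteCohortError(country, education, cohort, missing)
    return 5.0 * sum(lookup[cell] for cell in cells)


def convert_all(surface: pd.DataFrame, cohorts: Sequence[int]
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert every complete (country, education, cohort) diagonal.

    Returns
    -------
    cfr_table : DataFrame (cohort_cfr schema)
        One ``status="observed"`` row per combination whose six cells are
        all present.
    incomplete : DataFrame
        Columns (country, education, cohort, missing): combinations that
        could not be summed and the cells they lack — reported, never
        silently dropped.  Truncated cohorts belong here and can be routed
        to Lee-Carter completion.
    """
    if not len(surface):
        logger.warning("empty fertility surface: nothing to convert")
    rows, incomplete = [], []
    pairs = (surface[["country", "education"]].drop_duplicates()
             .itertuples(index=False))
    for country, education in pairs:
        for cohort in cohorts:
            try:
                cfr = period_to_cohort_cfr(surface, country, education, cohort)
            except IncompleteCohortError as exc:
                incomplete.append((country, education, cohort, exc.missing))
                continue
            rows.append((country, cohort, education, cfr, "observed"))
    cfr_table = validate_table(
        pd.DataFrame(rows, columns=["country", "cohort", "education",
                                    "cfr", "status"]), "cohort_cfr")
    incomplete_df = pd.DataFrame(
        incomplete, columns=["country", "education", "cohort", "missing"])
    if len(incomplete_df):
        logger.info("%d (country, education, cohort) combinations incomplete",
                    len(incomplete_df))
    return cfr_table, incomplete_df
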