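"""Education-specific diffusion rates and the CFR projection recurrence.

The *diffusion rate* of education group *e* is the fractional change in its
completed cohort fertility per unit (year) change in the skills-adjusted
mean years of schooling (SLAMYS) of all women, measured between two
reference cohorts (defaults 1955 and 1985):

    rate_e = (CFR_e(end) - CFR_e(start)) / CFR_e(start)
             / (SLAMYS(end) - SLAMYS(start)).

Negative when fertility falls while schooling rises.  Projection iterates
the multiplicative recurrence

    CFR_e(t+5) = CFR_e(t) * (1 + rate_e * (SLAMYS(t+5) - SLAMYS(t))),

so rates estimated on a large aggregate (e.g. all of Africa) can be driven
by each country's own SLAMYS trajectory — the cross-level design used for
national forecasts.  Projected fertility is floored at zero.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .data_model import validate_table

__all__ = ["estimate_diffusion_rate", "estimate_all_rates",
           "project_cfr_step", "project_series",
           "rates_to_frame", "rates_from_frame"]

logger = logging.getLogger(__name__)


def estimate_diffusion_rate(cfr_start: float, cfr_end: float,
                            slamys_start: float, slamys_end: float) -> float:
    """Endpoint estimator of the diffusion rate (fraction per SLAMYS year)."""
    if cfr_start <= 0:
        raise ValueError(f"cfr_start must be positive, got {cfr_start}")
    d_slamys = slamys_end - slamys_start
    if d_slamys == 0:
        raise ZeroDivisionError(
            "SLAMYS unchanged between endpoint cohorts: rate undefined")
    return (cfr_end - cfr_start) / cfr_start / d_slamys


def _slamys_lookup(slamys: pd.DataFrame, region: str, cohort: int) -> float:
    hit = slamys[(slamys["region"] == region) & (slamys["cohort"] == cohort)]
    if not len(hit):
        raise LookupError(f"SLAMYS missing for region '{region}', "
                          f"cohort {cohort}")
    return float(hit["slamys"].iloc[0])


def estimate_all_rates(cfr_table: pd.DataFrame, slamys: pd.DataFrame,
                       start_cohort: int = 1955, end_cohort: int = 1985,
                       country: str = "AFRICA",
                       region: str = "AFRICA") -> dict[str, float]:
    """One diffusion rate per education group from endpoint cohorts.

    ``cfr_table`` supplies CFR_e at both cohorts for ``country`` (by default
    the continental aggregate); ``slamys`` supplies the aggregate schooling
    series for ``region``.
    """
    sub = cfr_table[cfr_table["country"] == country]
    s_start = _slamys_lookup(slamys, region, start_cohort)
    s_end = _slamys_lookup(slamys, region, end_cohort)
    rates: dict[str, float] = {}
    for education in sub["education"].unique():
        block = sub[sub["education"] == education].set_index("cohort")["cfr"]
        for cohort in (start_cohort, end_cohort):
            if cohort not in block.index:
                raise LookupError(
                    f"CFR missing for (education '{education}', "
                    f"cohort {cohort}) in country '{country}'")
        rates[education] = estimate_diffusion_rate(
            block[start_cohort], block[end_cohort], s_start, s_end)
    return rates


def project_cfr_step(cfr: float, rate: float, delta_slamys: float) -> float:
    """One recurrence step: ``cfr * (1 + rate * delta_slamys)``, floored at 0."""
    if cfr < 0:
        raise ValueError(f"cfr must be nonnegative, got {cfr}")
    out = cfr * (1.0 + rate * delta_slamys)
    if out < 0:
        logger.warning("projected CFR went negative (%.4f); floored at 0", out)
        return 0.0
    return out


def project_series(jumpoff: pd.DataFrame, rates: Mapping[str, float],
                   slamys: pd.DataFrame, cohorts: Sequence[int],
                   region: str | None = None) -> pd.DataFrame:
    """Iterate the recurrence from the jump-off cohort over ``cohorts``.

    ``jumpoff`` holds one cohort_cfr row per education group at a single
    cohort t0 for a single country; ``cohorts`` lists the target cohorts
    t0+5, t0+10, ... in order.  SLAMYS differences are taken on ``region``
    (defaults to the jump-off country), which is how continent-level rates
    are combined with country-specific schooling paths.
    """
    cohorts = [int(c) for c in cohorts]
    if not cohorts:
        return validate_table(pd.DataFrame(
            columns=["country", "cohort", "education", "cfr", "status"]),
            "cohort_cfr")
    countries = jumpoff["country"].unique()
    if len(countries) != 1:
        raise ValueError("jumpoff must cover exactly one country")
    country = countries[0]
    t0_values = jumpoff["cohort"].unique()
    if len(t0_values) != 1:
        raise ValueError("jumpoff must be a single cohort")
    t0 = int(t0_values[0])
    if region is None:
        region = country
    expected = [t0 + 5 * (i + 1) for i in range(len(cohorts))]
    if cohorts != expected:
        raise ValueError(f"cohorts must be consecutive 5-year steps from "
                         f"{t0}: expected {expected}, got {cohorts}")
    # all SLAMYS points must exist before any arithmetic
    slamys_vals = {c: _slamys_lookup(slamys, region, c)
                   for c in [t0] + cohorts}
    rows = []
    for _, row in jumpoff.iterrows():
        education = row["education"]
        if education not in rates:
            raise LookupError(f"no diffusion rate for education '{education}'")
        cfr = float(row["cfr"])
        prev = t0
        for c in cohorts:
            cfr = project_cfr_step(cfr, rates[education],
                                   slamys_vals[c] - slamys_vals[prev])
            rows.append((country, c, education, cfr, "projected"))
            prev = c
    return validate_table(
        pd.DataFrame(rows, columns=["country", "cohort", "education",
                                    "cfr", "status"]), "cohort_cfr")


def rates_to_frame(rates: Mapping[str, float]) -> pd.DataFrame:
    """Diffusion rates as a validated two-column table."""
    df = pd.DataFrame({"education": list(rates), "rate": list(rates.values())})
    return validate_table(df, "diffusion_rates")


def rates_from_frame(df: pd.DataFrame) -> dict[str, float]:
    df = validate_table(df, "diffusion_rates")
    return dict(zip(df["education"], df["rate"]))
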