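"""Lee-Carter completion of truncated birth cohorts.

The youngest cohorts in a 1970-2015 surface have not yet reached ages
40-44, so their diagonals are truncated.  Following the classic log-bilinear
model, per (country, education) block the log age-period rates are

    log m(x, t) = a_x + b_x * k_t + eps(x, t),

with a_x the age-specific mean of log rates and (b_x, k_t) the leading
singular pair of the centered log-rate matrix under the usual
identification sum(b_x) = 1, sum(k_t) = 0.  The time index is continued by
the central path of a random walk with drift,

    k_{T+h} = k_T + h * drift,   drift = (k_T - k_1) / (T - 1),

giving a deterministic point extrapolation of the missing periods; the
cohort diagonal is then assembled from observed and extrapolated cells and
summed as usual.  No stochastic prediction intervals are produced, and no
jump-off (second-stage) re-estimation of k_t is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import SUMMED_AGES, cohort_cells, period_to_cohort_cfr
from .data_model import validate_table

__all__ = ["ZERO_RATE_FLOOR", "LeeCarterFit", "fit_lee_carter",
           "extrapolate_rates", "complete_truncated_cohorts"]

logger = logging.getLogger(__name__)

#: Rates of exactly 0 are floored here before taking logs.
ZERO_RATE_FLOOR = 1e-6


@dataclass
class LeeCarterFit:
    """Fitted log-bilinear decomposition for one (country, education)."""

    country: str
    education: str
    ages: np.ndarray          # age-group start years, rows of the matrix
    periods: np.ndarray       # fitted period start years, columns
    ax: np.ndarray            # per-age mean log rate
    bx: np.ndarray            # per-age sensitivity, sums to 1
    kt: np.ndarray            # per-period index, sums to 0
    drift: float              # change in kt per 5-year step
    residual_sd: float        # sd of log-rate residuals

    def __post_init__(self) -> None:
        assert abs(self.bx.sum() - 1.0) <= 1e-9, "bx must sum to 1"
        assert abs(self.kt.sum()) <= 1e-9 * max(1.0, np.abs(self.kt).max()), \
            "kt must sum to 0"

    def fitted_log_rates(self) -> np.ndarray:
        return self.ax[:, None] + np.outer(self.bx, self.kt)


def fit_lee_carter(surface: pd.DataFrame, country: str, education: str,
                   periods: Sequence[int]) -> LeeCarterFit:
    """Rank-1 SVD fit of the centered log-rate matrix.

    Requires a complete age x period block of positive rates over the six
    summed age groups (zeros are floored at :data:`ZERO_RATE_FLOOR` with a
    warning) and at least 3 periods so the drift is meaningful.

    The sign of (b_x, k_t) is fixed by sum(b_x) > 0, so declining rates
    yield a declining k_t and hence drift <= 0.
    """
    periods = sorted(int(p) for p in periods)
    if len(periods) < 3:
        raise ValueError(f"need >= 3 periods to fit, got {len(periods)}")
    sub = surface[(surface["country"] == country)
                  & (surface["education"] == education)
                  & surface["period"].isin(periods)
                  & surface["age_group"].isin(SUMMED_AGES)]
    mat = sub.pivot(index="age_group", columns="period", values="rate")
    mat = mat.reindex(index=list(SUMMED_AGES), columns=periods)
    if mat.isna().any().any():
        missing = [(a, p) for a in mat.index for p in mat.columns
                   if pd.isna(mat.loc[a, p])]
        raise ValueError(
            f"incomplete age x period block for ({country}, {education}): "
            f"missing {missing[:8]}")
    rates = mat.to_numpy(dtype=float)
    if (rates < 0).any():
        raise ValueError("negative rates in fitting block")
    if (rates == 0).any():
        logger.warning("%d zero rates floored at %g before logging",
                       int((rates == 0).sum()), ZERO_RATE_FLOOR)
        rates = np.maximum(rates, ZERO_RATE_FLOOR)

    log_rates = np.log(rates)
    ax = log_rates.mean(axis=1)
    centered = log_rates - ax[:, None]
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u1, s1, v1 = u[:, 0], s[0], vt[0]
    scale = u1.sum()
    if scale == 0:
        raise ValueError("degenerate leading singular vector (sum bx = 0)")
    bx = u1 / scale
    kt = s1 * v1 * scale
    drift = (kt[-1] - kt[0]) / (len(periods) - 1)
    resid = centered - np.outer(bx, kt)
    residual_sd = float(np.sqrt(np.mean(resid ** 2)))
    return LeeCarterFit(country=country, education=education,
                        ages=np.array(SUMMED_AGES),
                        periods=np.array(periods, dtype=int),
                        ax=ax, bx=bx, kt=kt, drift=float(drift),
                        residual_sd=residual_sd)


def extrapolate_rates(fit: LeeCarterFit, horizon: int) -> pd.DataFrame:
    """Central random-walk-with-drift forecast of the next ``horizon`` periods.

    Returns a fertility-surface fragment covering periods
    ``last + 5, ..., last + 5*horizon`` with rates
    ``exp(a_x + b_x * (k_T + h * drift))``.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    last_period = int(fit.periods[-1])
    last_kt = fit.kt[-1]
    rows = []
    for h in range(1, horizon + 1):
        kt_h = last_kt + h * fit.drift
        rates = np.exp(fit.ax + fit.bx * kt_h)
        for age, rate in zip(fit.ages, rates):
            rows.append((fit.country, last_period + 5 * h, int(age),
                         fit.education, float(rate)))
    return validate_table(
        pd.DataFrame(rows, columns=["country", "period", "age_group",
                                    "education", "rate"]),
        "fertility_surface")


def complete_truncated_cohorts(surface: pd.DataFrame,
                               cohorts: Sequence[int],
                               last_observed_period: int | None = None
                               ) -> pd.DataFrame:
    """Complete cohorts whose late cells fall beyond the observed periods.

    Per (country, education): fit on the observed periods, extrapolate just
    far enough to cover every requested cohort's diagonal, then sum each
    diagonal mixing observed and extrapolated cells.  Rows carry
    ``status="completed"`` regardless of how many cells were extrapolated
    (provenance of the code path), so a cohort that needed no extrapolation
    still comes back "completed".

    A cohort with zero observed cells is refused: that would be pure
    projection, not completion.
    """
    cohorts = sorted(int(c) for c in cohorts)
    rows = []
    pairs = (surface[["country", "education"]].drop_duplicates()
             .itertuples(index=False))
    for country, education in pairs:
        sub = surface[(surface["country"] == country)
                      & (surface["education"] == education)]
        if last_observed_period is not None:
            sub = sub[sub["period"] <= last_observed_period]
        # fit only on periods with all six summed age groups present
        counts = (sub[sub["age_group"].isin(SUMMED_AGES)]
                  .groupby("period")["age_group"].nunique())
        observed_periods = sorted(counts.index[counts == len(SUMMED_AGES)])
        if not observed_periods:
            raise ValueError(f"no complete observed periods for "
                             f"({country}, {education})")
        last_obs = observed_periods[-1]
        needed_last = max(cohort_cells(c)[-1][1] for c in cohorts)
        for c in cohorts:
            first_needed = cohort_cells(c)[0][1]
            if first_needed > last_obs:
                raise ValueError(
                    f"cohort {c} ({country}, {education}) has no observed "
                    f"cells (first cell in period {first_needed}, last "
                    f"observed {last_obs}); completion requires at least one")
        horizon = (needed_last - last_obs) // 5
        if horizon > 0:
            fit = fit_lee_carter(surface=sub, country=country,
                                 education=education, periods=observed_periods)
            fragment = extrapolate_rates(fit, horizon)
            # observed cells win over extrapolated ones
            block = pd.concat([sub, fragment], ignore_index=True)
            block = block.drop_duplicates(
                subset=["country", "period", "age_group", "education"],
                keep="first")
        else:
            block = sub
        for c in cohorts:
            cfr = period_to_cohort_cfr(block, country, education, c)
            rows.append((country, c, education, cfr, "completed"))
    return validate_table(
        pd.DataFrame(rows, columns=["country", "cohort", "education",
                                    "cfr", "status"]), "cohort_cfr")
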