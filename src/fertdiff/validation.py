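"""Education-weighted aggregation and out-of-sample forecast validation.

The validation protocol mirrors the standard hold-back design for a cohort
forecasting model: diffusion rates are estimated on an initial window of
cohorts only (e.g. 1955-1965), the recurrence is projected over the
held-back cohorts (e.g. 1970-1985), and projected vs observed completed
fertility is scored per education group and for the weighted all-education
aggregate.  Estimation never sees the held-out rows: they are removed from
the table before rates are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .diffusion import estimate_all_rates, project_series

__all__ = ["ValidationReport", "aggregate_cfr", "out_of_sample"]


def aggregate_cfr(cfr_rows: Mapping[str, float],
                  weights: Mapping[str, float]) -> float:
    """Overall cohort fertility: weight-averaged over education groups.

    A convex combination — the result always lies within the range of the
    education-specific inputs.  Weights must cover exactly the education
    groups present and sum to 1 (tolerance 1e-6).
    """
    missing = [e for e in weights if e not in cfr_rows]
    if missing:
        raise LookupError(f"CFR missing for education groups {missing}")
    extra = [e for e in cfr_rows if e not in weights]
    if extra:
        raise LookupError(f"weights missing for education groups {extra}")
    total = float(sum(weights.values()))
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"weights sum to {total!r}, not 1 (tol 1e-6)")
    return float(sum(weights[e] * cfr_rows[e] for e in weights))


@dataclass
class ValidationReport:
    """Held-out comparison of projected vs observed cohort fertility.

    ``details`` has one row per (education, cohort) held-out cell — plus
    ``education="aggregate"`` rows for the weighted total — with columns
    projected, observed, error (projected - observed) and ape (absolute
    percentage error, in percent).  ``summary`` gives MAPE and RMSE per
    education group and for the aggregate.
    """

    details: pd.DataFrame
    summary: pd.DataFrame
    truncation_cohort: int

    def mape(self, education: str) -> float:
        row = self.summary[self.summary["education"] == education]
        if not len(row):
            raise LookupError(f"no summary for education '{education}'")
        return float(row["mape"].iloc[0])


def _weights_map(weights: pd.DataFrame, country: str,
                 cohort: int) -> dict[str, float]:
    sub = weights[(weights["country"] == country)
                  & (weights["cohort"] == cohort)]
    if not len(sub):
        raise LookupError(f"education weights missing for ({country}, {cohort})")
    return dict(zip(sub["education"], sub["weight"]))


def out_of_sample(cfr_table: pd.DataFrame, slamys: pd.DataFrame,
                  weights: pd.DataFrame, truncation_cohort: int,
                  horizon_cohort: int, country: str = "AFRICA",
                  region: str | None = None,
                  rates_region: str = "AFRICA") -> ValidationReport:
    """Hold-back validation of the diffusion projection.

    Rates are estimated from the window's endpoint cohorts (first observed
    cohort and ``truncation_cohort``), the recurrence is projected to
    ``horizon_cohort``, and errors are scored on the held-out cohorts.
    The aggregate series uses the *observed* education weights of the
    held-out cohorts, isolating fertility-forecast error from
    composition-forecast error.
    """
    if truncation_cohort >= horizon_cohort:
        raise ValueError("truncation_cohort must precede horizon_cohort")
    sub = cfr_table[cfr_table["country"] == country]
    observed_cohorts = sorted(sub["cohort"].unique())
    window = [c for c in observed_cohorts if c <= truncation_cohort]
    if len(window) < 2:
        raise ValueError(f"estimation window has {len(window)} cohorts, "
                         "need at least 2")
    # hard split: estimation only ever sees the window rows
    train = sub[sub["cohort"] <= truncation_cohort]
    rates = estimate_all_rates(train, slamys, start_cohort=window[0],
                               end_cohort=truncation_cohort,
                               country=country, region=rates_region)
    held_out = [c for c in observed_cohorts
                if truncation_cohort < c <= horizon_cohort]
    jumpoff = train[train["cohort"] == truncation_cohort]
    target_cohorts = [truncation_cohort + 5 * (i + 1)
                      for i in range((horizon_cohort - truncation_cohort) // 5)]
    projected = project_series(jumpoff, rates, slamys, target_cohorts,
                               region=region if region is not None else country)

    detail_rows = []
    for cohort in held_out:
        obs = sub[sub["cohort"] == cohort].set_index("education")["cfr"]
        proj = (projected[projected["cohort"] == cohort]
                .set_index("education")["cfr"])
        for education in obs.index:
            if education not in proj.index:
                raise LookupError(f"projection missing for ('{education}', "
                                  f"{cohort})")
            err = float(proj[education] - obs[education])
            ape = abs(err) / abs(obs[education]) * 100.0
            detail_rows.append((education, cohort, float(proj[education]),
                                float(obs[education]), err, ape))
        w = _weights_map(weights, country, cohort)
        agg_obs = aggregate_cfr(dict(obs), w)
        agg_proj = aggregate_cfr(dict(proj), w)
        err = agg_proj - agg_obs
        detail_rows.append(("aggregate", cohort, agg_proj, agg_obs, err,
                            abs(err) / abs(agg_obs) * 100.0))
    details = pd.DataFrame(detail_rows, columns=[
        "education", "cohort", "projected", "observed", "error", "ape"])

    summary_rows = []
    for education, grp in details.groupby("education", sort=False):
        summary_rows.append((education, float(grp["ape"].mean()),
                             float(np.sqrt(np.mean(grp["error"] ** 2)))))
    summary = pd.DataFrame(summary_rows, columns=["education", "mape", "rmse"])
    return ValidationReport(details=details, summary=summary,
                            truncation_cohort=truncation_cohort)
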