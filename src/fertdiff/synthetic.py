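"""Synthetic inputs with known generative parameters.

Everything the pipeline consumes — fertility surfaces, schooling (SLAMYS)
series, education composition weights and survey-style microdata — can be
generated here with ground truth in hand, so every downstream stage is
testable end to end without external data.

The surface generator is the exact generative inverse of the projection
model: completed cohort fertility evolves by the multiplicative recurrence

    CFR_e(t+5) = CFR_e(t) * (1 + rate_e * dSLAMYS),

and each cohort's CFR is laid down along its exact cohort diagonal
(period = cohort + age-group start), split over age groups by a fixed
schedule and divided by 5 to give annual rates.  In the noise-free case,
summing a cohort diagonal therefore recovers the recurrence to machine
precision — a closed-loop oracle for the whole pipeline.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import EDUCATION_LEVELS, validate_table

__all__ = [
    "SurfaceScenario",
    "ScenarioError",
    "generate_surface",
    "generate_slamys",
    "generate_microdata",
    "generate_weights",
    "scenario_cfr_table",
    "scenario_weights",
    "africa_scenario",
    "africa_inputs",
    "AFRICA_ENDPOINT_RATES",
    "AFRICA_ANCHOR_CFR",
    "default_education_mixer",
]

logger = logging.getLogger(__name__)

#: Age groups over which a cohort's fertility is distributed (start ages).
_SCHEDULE_AGES = (15, 20, 25, 30, 35, 40)


class ScenarioError(ValueError):
    """A scenario's parameters imply an invalid fertility path."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: adding a generator call never perturbs the others."""
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SurfaceScenario:
    """Generative parameters for an education-specific fertility surface.

    Parameters
    ----------
    countries : list of str
        Country codes (or ``"AFRICA"`` for the continental aggregate).
    cohorts : list of int
        Birth-cohort start years, consecutive multiples of 5.
    base_cfr : mapping education -> children per woman
        Completed cohort fertility of the first cohort.
    age_schedule : six proportions
        Share of lifetime fertility in each 5-year age group 15-19 .. 40-44;
        must sum to 1.
    true_diffusion_rates : mapping education -> fraction per schooling year
        The recurrence's rate (negative for fertility decline).
    slamys_path : list of float
        SLAMYS increments per 5-year cohort step; length ``len(cohorts)-1``.
    noise_sd : float
        Log-scale standard deviation of multiplicative cell noise (0 = exact).
    seed : int
        Base seed for all random substreams.
    """

    countries: Sequence[str]
    cohorts: Sequence[int]
    base_cfr: Mapping[str, float]
    age_schedule: Sequence[float]
    true_diffusion_rates: Mapping[str, float]
    slamys_path: Sequence[float]
    noise_sd: float = 0.0
    seed: int = 0
    slamys_start: float = 1.0

    def __post_init__(self) -> None:
        sched = np.asarray(self.age_schedule, dtype=float)
        if sched.shape != (6,) or (sched < 0).any():
            raise ScenarioError("age_schedule must be six nonnegative shares")
        if abs(sched.sum() - 1.0) > 1e-12:
            raise ScenarioError(
                f"age_schedule sums to {sched.sum()!r}, must be 1 +- 1e-12")
        if any(v <= 0 for v in self.base_cfr.values()):
            raise ScenarioError("base_cfr must be positive")
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be nonnegative")
        if len(self.slamys_path) != len(self.cohorts) - 1:
            raise ScenarioError(
                f"slamys_path has {len(self.slamys_path)} increments for "
                f"{len(self.cohorts)} cohorts; need len(cohorts)-1")

    @property
    def educations(self) -> tuple:
        return tuple(self.base_cfr)


def _cfr_path(scenario: SurfaceScenario, education: str) -> np.ndarray:
    """True CFR of each cohort under the recurrence (the ground truth)."""
    cfr = [float(scenario.base_cfr[education])]
    rate = float(scenario.true_diffusion_rates[education])
    for inc in scenario.slamys_path:
        nxt = cfr[-1] * (1.0 + rate * inc)
        if nxt < 0:
            raise ScenarioError(
                f"recurrence drives CFR below 0 for education '{education}' "
                f"(rate {rate}, increment {inc})")
        cfr.append(nxt)
    return np.asarray(cfr)


def scenario_cfr_table(scenario: SurfaceScenario) -> pd.DataFrame:
    """Ground-truth cohort fertility implied by the scenario's recurrence."""
    rows = []
    for country in scenario.countries:
        for education in scenario.educations:
            path = _cfr_path(scenario, education)
            for cohort, cfr in zip(scenario.cohorts, path):
                rows.append((country, cohort, education, cfr, "observed"))
    df = pd.DataFrame(rows, columns=["country", "cohort", "education",
                                     "cfr", "status"])
    return validate_table(df, "cohort_cfr")


def generate_surface(scenario: SurfaceScenario) -> pd.DataFrame:
    """Generate an education-age-specific period fertility surface.

    Each cohort's CFR is split over the six age groups by ``age_schedule``,
    divided by 5 (annual rates over a 5-year span) and placed on the cohort
    diagonal ``period = cohort + age``.  Optional multiplicative log-normal
    noise is applied cell-wise.  Deterministic given ``scenario.seed``.
    """
    sched = np.asarray(scenario.age_schedule, dtype=float)
    rows = []
    for country in scenario.countries:
        for education in scenario.educations:
            path = _cfr_path(scenario, education)
            for cohort, cfr in zip(scenario.cohorts, path):
                rates = cfr * sched / 5.0
                for age, rate in zip(_SCHEDULE_AGES, rates):
                    rows.append((country, cohort + age, age, education, rate))
    df = pd.DataFrame(rows, columns=["country", "period", "age_group",
                                     "education", "rate"])
    if scenario.noise_sd > 0:
        rng = _rng(scenario.seed, "generate_surface")
        noise = rng.normal(0.0, scenario.noise_sd, size=len(df))
        df["rate"] = df["rate"] * np.exp(noise)
    return validate_table(df, "fertility_surface")


def generate_slamys(region: str, start: float,
                    increments: Sequence[float],
                    cohorts: Sequence[int] | None = None) -> pd.DataFrame:
    """Cumulative SLAMYS series: ``[start, start+inc1, start+inc1+inc2, ...]``.

    ``cohorts`` labels the points (defaults to 1955, 1960, ...); its length
    must be ``len(increments) + 1``.
    """
    if start < 0:
        raise ValueError("SLAMYS start must be nonnegative")
    values = np.concatenate([[start], start + np.cumsum(increments)])
    if (values < 0).any():
        raise ValueError("SLAMYS path goes negative")
    if cohorts is None:
        cohorts = [1955 + 5 * i for i in range(len(values))]
    if len(cohorts) != len(values):
        raise ValueError(f"{len(cohorts)} cohort labels for {len(values)} points")
    df = pd.DataFrame({"region": region, "cohort": list(cohorts),
                       "slamys": values})
    return validate_table(df, "slamys")


def default_education_mixer(mys: float) -> np.ndarray:
    """Education-composition model: shares shift upward with stratum schooling.

    A simple softmax in attainment whose logits rise with mean years of
    schooling; at MYS 0 the stratum is dominated by women with no formal
    education, by MYS 10+ secondary/higher dominate.
    """
    logits = np.array([2.0 - 0.45 * mys,
                       1.0 - 0.05 * mys,
                       0.25 * mys - 1.0,
                       0.45 * mys - 3.5])
    p = np.exp(logits - logits.max())
    return p / p.sum()


def generate_microdata(n_strata: int,
                       women_per_stratum: int,
                       betas: Mapping,
                       mys_range: tuple = (0.0, 12.0),
                       education_mixer: Callable[[float], np.ndarray] | None = None,
                       seed: int = 0,
                       stratum_sd: float = 0.0,
                       clusters_per_stratum: int = 4) -> pd.DataFrame:
    """Simulate survey-style microdata from the strata Poisson model.

    The ideal family size of woman *i* in stratum *s* is Poisson with

        log mu = b0 + b1[educ] + b2*MYS_s + b3[educ]*MYS_s + U_s,

    where ``U_s ~ Normal(0, stratum_sd^2)`` and stratum mean years of
    schooling MYS_s is uniform on ``mys_range``.  Children ever born is
    drawn from the same law for women aged 40-49 and left missing otherwise.

    ``betas`` maps: ``beta0`` (float, log scale), ``beta1`` and ``beta3``
    (mapping education -> contrast, reference ``none`` implicitly 0),
    ``beta2`` (float).  Deterministic given ``seed``.
    """
    if n_strata < 2:
        raise ValueError("need at least 2 strata")
    if women_per_stratum < 1:
        raise ValueError("need at least 1 woman per stratum")
    mixer = education_mixer or default_education_mixer
    rng = _rng(seed, "generate_microdata")

    b0 = float(betas.get("beta0", 0.0))
    b1 = {e: float(betas.get("beta1", {}).get(e, 0.0)) for e in EDUCATION_LEVELS}
    b2 = float(betas.get("beta2", 0.0))
    b3 = {e: float(betas.get("beta3", {}).get(e, 0.0)) for e in EDUCATION_LEVELS}
    b1["none"] = 0.0
    b3["none"] = 0.0

    mys = rng.uniform(*mys_range, size=n_strata)
    u_s = (rng.normal(0.0, stratum_sd, size=n_strata)
           if stratum_sd > 0 else np.zeros(n_strata))

    seen_positive = np.zeros(4, dtype=bool)
    rows = []
    woman_id = 0
    for s in range(n_strata):
        probs = np.asarray(mixer(mys[s]), dtype=float)
        probs = probs / probs.sum()
        seen_positive |= probs > 0
        educ_idx = rng.choice(4, size=women_per_stratum, p=probs)
        ages = rng.integers(15, 50, size=women_per_stratum)
        urban_p = min(0.9, max(0.1, 0.15 + 0.06 * mys[s]))
        urban = rng.random(women_per_stratum) < urban_p
        clusters = rng.integers(0, clusters_per_stratum, size=women_per_stratum)
        for i in range(women_per_stratum):
            e = EDUCATION_LEVELS[educ_idx[i]]
            log_mu = b0 + b1[e] + (b2 + b3[e]) * mys[s] + u_s[s]
            ifs = rng.poisson(np.exp(log_mu))
            ceb = rng.poisson(np.exp(log_mu)) if ages[i] >= 40 else None
            rows.append((woman_id, s, s * clusters_per_stratum + clusters[i],
                         e, mys[s], ifs, ceb, ages[i], bool(urban[i])))
            woman_id += 1
    if not seen_positive.all():
        dead = [EDUCATION_LEVELS[j] for j in np.where(~seen_positive)[0]]
        logger.warning("education_mixer gives zero probability everywhere "
                       "for categories %s", dead)
    df = pd.DataFrame(rows, columns=[
        "woman_id", "stratum_id", "cluster_id", "education", "stratum_mys",
        "ideal_family_size", "children_ever_born", "age", "urban"])
    return validate_table(df, "microdata")


def generate_weights(country: str, cohorts: Sequence[int],
                     trajectory) -> pd.DataFrame:
    """Education composition weights per cohort.

    ``trajectory`` is either a single 4-vector of shares (constant over
    cohorts), a pair ``(start_shares, end_shares)`` interpolated linearly
    across the cohorts, or a mapping ``cohort -> shares``.  Shares are in
    the order none, primary, secondary, higher and must sum to 1.
    """
    def _as_shares(x) -> np.ndarray:
        arr = np.asarray(x, dtype=float)
        if arr.shape != (4,) or (arr < 0).any():
            raise ValueError("shares must be four nonnegative numbers")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"shares sum to {arr.sum()!r}, must be 1")
        return arr

    n = len(cohorts)
    if isinstance(trajectory, Mapping):
        per_cohort = [_as_shares(trajectory[c]) for c in cohorts]
    else:
        arr = np.asarray(trajectory, dtype=float)
        if arr.shape == (4,):
            per_cohort = [_as_shares(arr)] * n
        elif arr.shape == (2, 4):
            start, end = _as_shares(arr[0]), _as_shares(arr[1])
            frac = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
            per_cohort = [(1 - f) * start + f * end for f in frac]
        else:
            raise ValueError("trajectory must be shares, (start, end) or a "
                             "mapping cohort -> shares")
    rows = []
    for cohort, shares in zip(cohorts, per_cohort):
        for e, w in zip(EDUCATION_LEVELS, shares):
            rows.append((country, cohort, e, w))
    df = pd.DataFrame(rows, columns=["country", "cohort", "education", "weight"])
    return validate_table(df, "education_weights")


def scenario_weights(scenario: SurfaceScenario,
                     trajectory=None) -> pd.DataFrame:
    """Weights for every scenario country; default is an expanding-education
    path from a mostly-unschooled to a mostly-schooled composition."""
    if trajectory is None:
        trajectory = ([0.70, 0.20, 0.08, 0.02], [0.25, 0.30, 0.30, 0.15])
    frames = [generate_weights(c, scenario.cohorts, trajectory)
              for c in scenario.countries]
    return validate_table(pd.concat(frames, ignore_index=True),
                          "education_weights")


#: Published Africa-wide endpoint diffusion rates (fraction per SLAMYS
#: year between the 1955-1959 and 1985-1989 cohorts), lowest to highest
#: attainment.  The continental scenario is parameterized so these are its
#: ground truth.
AFRICA_ENDPOINT_RATES = {"none": -0.102, "primary": -0.1109,
                         "secondary": -0.1157, "higher": -0.1164}

#: Anchor completed cohort fertility for the 1955-1959 cohort (children per
#: woman), reflecting the observed ordering by education.
AFRICA_ANCHOR_CFR = {"none": 7.0, "primary": 6.5,
                     "secondary": 5.5, "higher": 4.2}


def africa_scenario(seed: int = 0, noise_sd: float = 0.0) -> SurfaceScenario:
    """Continental-aggregate scenario emulating the observed African series.

    Fifteen 5-year birth cohorts 1930-2000 with SLAMYS rising by 0.5 years
    per cohort step (3 years over the analytical 1955-1985 window, the
    order of the continent's schooling gain over those cohorts), so the
    generated surface covers the rectangular period window 1970-2015 for
    all six age groups — the shape of the published rate series.

    The constant per-step recurrence rates are chosen so that the
    *endpoint* diffusion rates between the 1955 and 1985 cohorts equal the
    published Africa-wide estimates (:data:`AFRICA_ENDPOINT_RATES`), and
    the CFR path is anchored at :data:`AFRICA_ANCHOR_CFR` for the 1955
    cohort.
    """
    d_step, n_steps = 0.5, 6
    total = d_step * n_steps
    per_step = {e: ((1.0 + r * total) ** (1.0 / n_steps) - 1.0) / d_step
                for e, r in AFRICA_ENDPOINT_RATES.items()}
    cohorts = [1930 + 5 * i for i in range(15)]      # 1930 .. 2000
    back_steps = (1955 - cohorts[0]) // 5
    base_cfr = {e: cfr / (1.0 + per_step[e] * d_step) ** back_steps
                for e, cfr in AFRICA_ANCHOR_CFR.items()}
    return SurfaceScenario(
        countries=["AFRICA"],
        cohorts=cohorts,
        base_cfr=base_cfr,
        age_schedule=[0.10, 0.25, 0.25, 0.20, 0.15, 0.05],
        true_diffusion_rates=per_step,
        slamys_path=[d_step] * (len(cohorts) - 1),
        noise_sd=noise_sd,
        seed=seed,
        slamys_start=0.0,
    )


def africa_inputs(seed: int = 0, noise_sd: float = 0.0,
                  first_period: int = 1970, last_period: int = 2015):
    """The continental scenario's pipeline inputs, shaped like the real data.

    Returns ``(scenario, surface, slamys, weights, truth)`` where the
    surface is cropped to the rectangular period window
    ``[first_period, last_period]`` (default 1970-2015, under which cohorts
    1955-1975 are fully observed and 1980/1985 are truncated), the SLAMYS
    series and education weights cover all scenario cohorts, and ``truth``
    is the recurrence's ground-truth cohort fertility table.
    """
    scenario = africa_scenario(seed=seed, noise_sd=noise_sd)
    surface = generate_surface(scenario)
    surface = surface[(surface["period"] >= first_period)
                      & (surface["period"] <= last_period)].reset_index(drop=True)
    slamys = generate_slamys(scenario.countries[0], scenario.slamys_start,
                             scenario.slamys_path, cohorts=scenario.cohorts)
    weights = scenario_weights(scenario)
    truth = scenario_cfr_table(scenario)
    return scenario, surface, slamys, weights, truth
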