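import numpy as np
import pandas as pd
import pytest

import fertdiff as fd

#: Coefficients used throughout for microdata generation: intercept on the
#: log scale (exp(1.7) ~ 5.5 ideal children in an unschooled stratum),
#: modest negative contrasts by own education and a negative slope and
#: interactions in stratum schooling.
BETAS = {
    "beta0": 1.7,
    "beta1": {"primary": -0.05, "secondary": -0.15, "higher": -0.25},
    "beta2": -0.04,
    "beta3": {"primary": -0.005, "secondary": -0.01, "higher": -0.012},
}


def closed_loop_scenario(noise_sd: float = 0.0, seed: int = 1,
                         country: str = "C") -> fd.SurfaceScenario:
    """Scenario whose SLAMYS path makes the hold-back protocol exact.

    The estimation window (cohorts 1955-1965) contains a single nonzero
    SLAMYS increment, so the endpoint rate estimator returns the per-step
    recurrence rate exactly and noise-free out-of-sample error is zero.
    """
    return fd.SurfaceScenario(
        countries=[country],
        cohorts=[1955 + 5 * i for i in range(7)],
        base_cfr={"none": 6.0, "primary": 5.5, "secondary": 4.5,
                  "higher": 3.5},
        age_schedule=[0.10, 0.25, 0.25, 0.20, 0.15, 0.05],
        true_diffusion_rates={"none": -0.10, "primary": -0.11,
                              "secondary": -0.115, "higher": -0.116},
        slamys_path=[1.0, 0.0, 0.5, 0.5, 0.5, 0.5],
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def africa():
    """Continental scenario inputs shaped like the observed series."""
    scenario, surface, slamys, weights, truth = fd.africa_inputs()
    return {"scenario": scenario, "surface": surface, "slamys": slamys,
            "weights": weights, "truth": truth}


@pytest.fixture(scope="session")
def demo():
    """Small noise-free scenario with exact closed-loop structure."""
    scenario = closed_loop_scenario()
    surface = fd.generate_surface(scenario)
    slamys = fd.generate_slamys("C", 1.0, scenario.slamys_path,
                                cohorts=scenario.cohorts)
    weights = fd.scenario_weights(scenario)
    truth = fd.scenario_cfr_table(scenario)
    return {"scenario": scenario, "surface": surface, "slamys": slamys,
            "weights": weights, "truth": truth}


@pytest.fixture(scope="session")
def microdata():
    """20,000 simulated women in 50 strata with known coefficients."""
    return fd.generate_microdata(50, 400, BETAS, seed=3, stratum_sd=0.1)


def tiny_surface(rates, country="C", education="none", cohort=1955):
    """Surface carrying one cohort diagonal with the given six rates."""
    rows = [(country, cohort + age, age, education, r)
            for age, r in zip(fd.SUMMED_AGES, rates)]
    return fd.validate_table(
        pd.DataFrame(rows, columns=["country", "period", "age_group",
                                    "education", "rate"]),
        "fertility_surface")


def rank1_surface(country="C", education="none", periods=None,
                  ax=None, bx=None, kt=None):
    """Exactly rank-1 log-rate surface exp(ax + bx*kt) with linear kt."""
    periods = periods if periods is not None else list(range(1970, 2020, 5))
    n_age, n_per = 6, len(periods)
    if ax is None:
        ax = np.log(np.array([0.05, 0.18, 0.20, 0.15, 0.08, 0.02]))
    if bx is None:
        bx = np.full(n_age, 1.0 / n_age)
    if kt is None:
        kt = np.linspace(1.5, -1.5, n_per) * 6   # linear, sums to 0
    log_rates = ax[:, None] + np.outer(bx, kt)
    rows = []
    for i, age in enumerate(fd.SUMMED_AGES):
        for j, p in enumerate(periods):
            rows.append((country, p, age, education,
                         float(np.exp(log_rates[i, j]))))
    surface = fd.validate_table(
        pd.DataFrame(rows, columns=["country", "period", "age_group",
                                    "education", "rate"]),
        "fertility_surface")
    return surface, (np.asarray(ax), np.asarray(bx), np.asarray(kt),
                     np.asarray(periods))
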