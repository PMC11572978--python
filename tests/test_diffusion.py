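"""Diffusion-rate estimation and the projection recurrence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fertdiff as fd


def _cfr_table(path, country="C", education="none", start=1955):
    rows = [(country, start + 5 * i, education, v, "observed")
            for i, v in enumerate(path)]
    return fd.validate_table(
        pd.DataFrame(rows, columns=["country", "cohort", "education",
                                    "cfr", "status"]), "cohort_cfr")


def _slamys(values, region="C", start=1955):
    return fd.validate_table(
        pd.DataFrame({"region": region,
                      "cohort": [start + 5 * i for i in range(len(values))],
                      "slamys": values}), "slamys")


class TestEstimateRate:
    def test_hand_arithmetic(self):
        assert fd.estimate_diffusion_rate(7.0, 4.9, 1.0, 4.0) \
            == pytest.approx(-0.10, abs=1e-12)

    def test_unchanged_cfr_gives_zero(self):
        assert fd.estimate_diffusion_rate(5.0, 5.0, 1.0, 9.0) == 0.0

    def test_negative_when_fertility_falls_as_schooling_rises(self):
        assert fd.estimate_diffusion_rate(6.0, 4.0, 1.0, 3.0) < 0

    def test_undefined_when_slamys_unchanged(self):
        with pytest.raises(ZeroDivisionError, match="unchanged"):
            fd.estimate_diffusion_rate(6.0, 5.0, 2.0, 2.0)

    def test_nonpositive_start_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fd.estimate_diffusion_rate(0.0, 1.0, 1.0, 2.0)


class TestEstimateAllRates:
    def test_one_step_identifiability(self):
        """A single recurrence step returns the true rate exactly."""
        r, ds = -0.08, 1.5
        table = _cfr_table([6.0, 6.0 * (1 + r * ds)])
        slamys = _slamys([1.0, 1.0 + ds])
        rates = fd.estimate_all_rates(table, slamys, 1955, 1960,
                                      country="C", region="C")
        assert rates["none"] == pytest.approx(r, abs=1e-12)

    def test_six_step_compounding_closed_form(self):
        """Endpoint estimate over k equal steps follows the compounding
        closed form ((1 + r*dS)^k - 1) / (k*dS)."""
        r, ds, k = -0.10, 0.5, 6
        path = [6.0 * (1 + r * ds) ** i for i in range(k + 1)]
        table = _cfr_table(path)
        slamys = _slamys([1.0 + ds * i for i in range(k + 1)])
        rates = fd.estimate_all_rates(table, slamys, 1955, 1985,
                                      country="C", region="C")
        closed_form = ((1 + r * ds) ** k - 1) / (k * ds)
        assert rates["none"] == pytest.approx(closed_form, abs=1e-12)

    def test_identical_series_identical_rates(self):
        frames = [_cfr_table([6.0, 5.4], education=e)
                  for e in fd.EDUCATION_LEVELS]
        table = fd.validate_table(pd.concat(frames, ignore_index=True),
                                  "cohort_cfr")
        rates = fd.estimate_all_rates(table, _slamys([1.0, 2.0]),
                                      1955, 1960, country="C", region="C")
        assert len(set(round(v, 14) for v in rates.values())) == 1

    def test_missing_endpoint_named(self):
        table = _cfr_table([6.0, 5.4])
        with pytest.raises(LookupError, match="'none', cohort 1965"):
            fd.estimate_all_rates(table, _slamys([1.0, 2.0, 3.0]),
                                  1955, 1965, country="C", region="C")


class TestProjectStep:
    def test_hand_arithmetic(self):
        assert fd.project_cfr_step(5.0, -0.10, 1.0) == pytest.approx(4.5)

    @pytest.mark.parametrize("rate,ds", [(0.0, 2.0), (-0.1, 0.0)])
    def test_identity_cases(self, rate, ds):
        assert fd.project_cfr_step(5.0, rate, ds) == 5.0

    def test_zero_is_absorbing(self):
        assert fd.project_cfr_step(0.0, -0.10, 1.0) == 0.0

    def test_negative_result_floored_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="fertdiff.diffusion"):
            out = fd.project_cfr_step(5.0, -0.10, 20.0)
        assert out == 0.0
        assert "floored" in caplog.text


class TestProjectSeries:
    def test_two_step_hand_chaining(self):
        jump = _cfr_table([5.0])
        slamys = _slamys([1.0, 2.0, 3.0])
        out = fd.project_series(jump, {"none": -0.10}, slamys,
                                [1960, 1965])
        assert out["cfr"].tolist() == pytest.approx([4.5, 4.05])
        assert (out["status"] == "projected").all()

    def test_generative_closed_loop(self, demo):
        """Projecting with the scenario's own per-step rates reproduces the
        generator's future cohorts to 1e-10."""
        scenario, truth = demo["scenario"], demo["truth"]
        jump = truth[truth.cohort == 1955]
        out = fd.project_series(jump, scenario.true_diffusion_rates,
                                demo["slamys"], scenario.cohorts[1:])
        merged = out.merge(truth, on=["country", "cohort", "education"],
                           suffixes=("", "_true"))
        assert len(merged) == len(out)
        assert (merged.cfr - merged.cfr_true).abs().max() <= 1e-10

    def test_empty_cohort_list(self):
        jump = _cfr_table([5.0])
        out = fd.project_series(jump, {"none": -0.1},
                                _slamys([1.0]), [])
        assert len(out) == 0

    def test_slamys_gap_names_missing_cohort(self):
        jump = _cfr_table([5.0])
        with pytest.raises(LookupError, match="cohort 1965"):
            fd.project_series(jump, {"none": -0.1}, _slamys([1.0, 2.0]),
                              [1960, 1965])

    def test_cross_level_rates_with_country_slamys(self):
        """Aggregate-level rates combine with a country's own SLAMYS path."""
        jump = _cfr_table([5.0], country="KEN")
        slamys = _slamys([2.0, 2.4], region="KEN")
        out = fd.project_series(jump, {"none": -0.102}, slamys, [1960],
                                region="KEN")
        assert out["cfr"].iloc[0] == pytest.approx(5.0 * (1 - 0.102 * 0.4))

    def test_monotone_decline_until_floor(self):
        jump = _cfr_table([6.0])
        slamys = _slamys([1.0, 2.0, 3.5, 4.0, 6.0])
        out = fd.project_series(jump, {"none": -0.11}, slamys,
                                [1960, 1965, 1970, 1975])
        cfrs = out.sort_values("cohort")["cfr"].to_numpy()
        assert (np.diff(cfrs) < 0).all()

    @given(c=st.floats(0.1, 2.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_scale_equivariance(self, c):
        slamys = _slamys([1.0, 2.0, 3.0])
        base = fd.project_series(_cfr_table([5.0]), {"none": -0.1},
                                 slamys, [1960, 1965])
        scaled = fd.project_series(_cfr_table([5.0 * c]), {"none": -0.1},
                                   slamys, [1960, 1965])
        assert np.allclose(scaled["cfr"], c * base["cfr"])
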