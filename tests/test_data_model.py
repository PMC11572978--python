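"""Validated table IO: round trips, schema checks, invariant enforcement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fertdiff as fd
from fertdiff.data_model import SCHEMAS


def _example(schema):
    if schema == "fertility_surface":
        return pd.DataFrame({
            "country": ["C", "C", "D"], "period": [1970, 1975, 1970],
            "age_group": [15, 20, 15], "education": ["none", "none", "higher"],
            "rate": [0.1, 0.123456789012345, 0.0]})
    if schema == "cohort_cfr":
        return pd.DataFrame({
            "country": ["C", "C"], "cohort": [1955, 1960],
            "education": ["none", "none"], "cfr": [6.5, 6.0],
            "status": ["observed", "completed"]})
    if schema == "slamys":
        return pd.DataFrame({"region": ["AFRICA", "AFRICA"],
                             "cohort": [1955, 1960], "slamys": [1.0, 1.5]})
    if schema == "education_weights":
        return pd.DataFrame({
            "country": ["C"] * 4, "cohort": [1955] * 4,
            "education": list(fd.EDUCATION_LEVELS),
            "weight": [0.4, 0.3, 0.2, 0.1]})
    if schema == "diffusion_rates":
        return pd.DataFrame({"education": list(fd.EDUCATION_LEVELS),
                             "rate": [-0.102, -0.1109, -0.1157, -0.1164]})
    if schema == "microdata":
        return pd.DataFrame({
            "woman_id": [0, 1], "stratum_id": [0, 1], "cluster_id": [0, 4],
            "education": ["none", "higher"], "stratum_mys": [2.0, 9.5],
            "ideal_family_size": [6, 2],
            "children_ever_born": [7, None],
            "age": [44, 23], "urban": [False, True]})
    raise AssertionError(schema)


@pytest.mark.parametrize("schema", sorted(SCHEMAS))
def test_write_read_round_trip_is_identity(schema, tmp_path):
    """Writing then reading reproduces every value and the canonical order."""
    df = fd.validate_table(_example(schema), schema)
    path = tmp_path / f"{schema}.csv"
    fd.write_table(df, path, schema)
    back = fd.read_table(path, schema)
    pd.testing.assert_frame_equal(back, df)


def test_round_trip_preserves_full_float_precision(tmp_path):
    """Rates printed at >= 12 significant digits survive a round trip."""
    df = _example("fertility_surface")
    path = tmp_path / "s.csv"
    fd.write_table(df, path, "fertility_surface")
    back = fd.read_table(path, "fertility_surface")
    target = back[(back.period == 1975)]["rate"].iloc[0]
    assert target == pytest.approx(0.123456789012345, abs=1e-15)


def test_empty_table_round_trips(tmp_path):
    df = _example("cohort_cfr").iloc[:0]
    path = tmp_path / "empty.csv"
    fd.write_table(df, path, "cohort_cfr")
    back = fd.read_table(path, "cohort_cfr")
    assert len(back) == 0
    assert list(back.columns) == list(SCHEMAS["cohort_cfr"].columns)


@pytest.mark.parametrize("drop,add", [("rate", None), (None, "bogus")])
def test_header_mismatch_names_the_column(drop, add):
    df = _example("fertility_surface")
    if drop:
        df = df.drop(columns=[drop])
    if add:
        df[add] = 1
    with pytest.raises(fd.SchemaError, match=drop or add):
        fd.validate_table(df, "fertility_surface")


def _corruptions():
    """(schema, mutation, expected message fragment) for every invariant."""
    def set_cell(col, idx, value):
        def mut(df):
            df[col] = df[col].astype(object)
            df.loc[idx, col] = value
            return df
        return mut

    def duplicate_row(df):
        return pd.concat([df, df.iloc[[0]]], ignore_index=True)

    return [
        ("fertility_surface", set_cell("rate", 0, -0.1), "rate"),
        ("fertility_surface", set_cell("rate", 0, 1.5), "rate"),
        ("fertility_surface", set_cell("period", 0, 1972), "multiple of 5"),
        ("fertility_surface", set_cell("age_group", 0, 17), "age_group"),
        ("fertility_surface", set_cell("education", 0, "phd"), "education"),
        ("fertility_surface", duplicate_row, "duplicated key"),
        ("cohort_cfr", set_cell("cfr", 0, -1.0), "cfr"),
        ("cohort_cfr", set_cell("cfr", 0, 20.0), "cfr"),
        ("cohort_cfr", set_cell("status", 0, "guessed"), "status"),
        ("cohort_cfr", duplicate_row, "duplicated key"),
        ("slamys", set_cell("slamys", 0, -2.0), "slamys"),
        ("slamys", duplicate_row, "duplicated key"),
        ("education_weights", set_cell("weight", 0, 0.5), "sum"),
        ("education_weights", duplicate_row, "duplicated key"),
        ("diffusion_rates", set_cell("rate", 0, np.inf), "finite"),
        ("microdata", set_cell("ideal_family_size", 0, -3), "negative"),
        ("microdata", set_cell("ideal_family_size", 0, 2.5), "integer"),
        ("microdata", set_cell("stratum_mys", 0, -1.0), "stratum_mys"),
    ]


@pytest.mark.parametrize("schema,mutate,fragment", _corruptions(),
                         ids=lambda v: v if isinstance(v, str) else "")
def test_every_invariant_violation_is_rejected(schema, mutate, fragment):
    """Each constructed corruption raises a validation error naming the rule."""
    df = mutate(_example(schema).copy())
    with pytest.raises(fd.ValidationError, match=fragment):
        fd.validate_table(df, schema)


def test_cluster_in_two_strata_detail():
    df = _example("microdata")
    df.loc[1, "cluster_id"] = 0   # cluster 0 now claimed by strata 0 and 1
    with pytest.raises(fd.ValidationError, match="cluster_id 0 maps to 2"):
        fd.validate_table(df, "microdata")


def test_missing_children_ever_born_is_not_zero(tmp_path):
    """An empty count field reads back as missing, never as 0."""
    path = tmp_path / "m.csv"
    fd.write_table(_example("microdata"), path, "microdata")
    text = path.read_text()
    assert ",,," not in text.splitlines()[0]
    back = fd.read_table(path, "microdata")
    young = back[back.age == 23]
    assert young["children_ever_born"].isna().all()


@settings(max_examples=50, derandomize=True, deadline=None)
@given(rates=st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                      max_size=12),
       seed=st.integers(0, 10_000))
def test_random_valid_surfaces_round_trip(rates, seed, tmp_path_factory):
    """Any valid surface survives write/read bit-identically."""
    rng = np.random.default_rng(seed)
    n = len(rates)
    cells = rng.choice(6 * 10, size=n, replace=False)
    df = pd.DataFrame({
        "country": "C",
        "period": [1970 + 5 * int(c % 10) for c in cells],
        "age_group": [15 + 5 * int(c // 10) for c in cells],
        "education": "none",
        "rate": rates})
    valid = fd.validate_table(df, "fertility_surface")
    path = tmp_path_factory.mktemp("rt") / "s.csv"
    fd.write_table(valid, path, "fertility_surface")
    pd.testing.assert_frame_equal(fd.read_table(path, "fertility_surface"),
                                  valid)
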