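"""Survey coding rules, index scoring, and tabular round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mminet as mm
from mminet.data_model import (
    CodingError,
    SchemaError,
    code_shc,
    dichotomize_outcome,
    dichotomized_view,
    load_cohort,
    save_cohort,
    score_mmi,
)


@pytest.mark.parametrize(
    "token, expected",
    [("present", 1), ("absent", 0), ("do_not_know", 0)],
)
def test_shc_coding_tokens(token, expected):
    """'do not know' answers count as not having the condition."""
    assert code_shc(token) == expected


def test_shc_coding_missing_and_unknown():
    assert np.isnan(code_shc("missing"))
    with pytest.raises(CodingError, match="weird"):
        code_shc("weird")


@pytest.mark.parametrize(
    "value, scale, expected",
    [
        (1, "lisat6", 0), (4, "lisat6", 0), (5, "lisat6", 1), (6, "lisat6", 1),
        (1, "qol5", 0), (3, "qol5", 0), (4, "qol5", 1), (5, "qol5", 1),
    ],
)
def test_dichotomization_cuts(value, scale, expected):
    """Satisfaction scales split at the top ratings: 5-6 of 6, 4-5 of 5."""
    assert dichotomize_outcome(value, scale) == expected


def test_dichotomization_range_and_scale_errors():
    with pytest.raises(CodingError):
        dichotomize_outcome(7, "lisat6")
    with pytest.raises(CodingError):
        dichotomize_outcome(0, "qol5")
    with pytest.raises(CodingError):
        dichotomize_outcome(3, "nope")


def _dataset_from_items(values: np.ndarray, names: list[str]) -> mm.SurveyDataset:
    specs = [mm.VariableSpec(n, "binary", "shc") for n in names]
    return mm.SurveyDataset(pd.DataFrame(values, columns=names), specs)


def test_mmi_score_range_and_missing():
    names = [f"S{i}" for i in range(30)]
    ds = _dataset_from_items(np.ones((2, 30)), names)
    full = mm.MMIDefinition(tuple(names))
    assert score_mmi(ds, full).tolist() == [30, 30]
    ds0 = _dataset_from_items(np.zeros((2, 30)), names)
    assert score_mmi(ds0, full).tolist() == [0, 0]
    reduced = mm.MMIDefinition(tuple(names[:25]))
    assert score_mmi(ds, reduced).tolist() == [25, 25]

    vals = np.ones((2, 30))
    vals[0, 3] = np.nan
    dsm = _dataset_from_items(vals, names)
    scores = score_mmi(dsm, full)
    assert np.isnan(scores.iloc[0]) and scores.iloc[1] == 30
    with pytest.raises(SchemaError):
        score_mmi(ds, mm.MMIDefinition(("S0", "nope")))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    items=st.lists(st.integers(0, 1), min_size=5, max_size=30),
    flip=st.integers(0, 29),
)
def test_mmi_score_monotone(items, flip):
    """Turning a condition present never decreases the index score."""
    flip = flip % len(items)
    names = [f"S{i}" for i in range(len(items))]
    index = mm.MMIDefinition(tuple(names))
    base = _dataset_from_items(np.array([items], dtype=float), names)
    bumped_vals = list(items)
    bumped_vals[flip] = 1
    bumped = _dataset_from_items(np.array([bumped_vals], dtype=float), names)
    assert score_mmi(bumped, index).iloc[0] >= score_mmi(base, index).iloc[0]


def test_variable_spec_invariants():
    with pytest.raises(SchemaError):
        mm.VariableSpec("X", "continuous", "shc")  # SHC must be binary
    with pytest.raises(SchemaError):
        mm.VariableSpec("X", "ordinal", "outcome", levels=(1, 3, 5))
    with pytest.raises(SchemaError):
        mm.VariableSpec("X", "binary", "shc", levels=(1, 2))


def test_dataset_schema_validation():
    specs = [mm.VariableSpec("A", "binary", "shc")]
    with pytest.raises(SchemaError, match="without a spec"):
        mm.SurveyDataset(pd.DataFrame({"A": [0, 1], "B": [1, 0]}), specs)
    with pytest.raises(SchemaError, match="outside levels"):
        mm.SurveyDataset(pd.DataFrame({"A": [0, 2]}), specs)
    with pytest.raises(SchemaError, match="duplicate participant"):
        mm.SurveyDataset(pd.DataFrame({"A": [0, 1]}, index=[1, 1]), specs)


@pytest.fixture
def token_csv(tmp_path):
    path = tmp_path / "cohort.csv"
    path.write_text(
        "participant_id,AD,BI,PCS\n"
        "p1,present,absent,31.5\n"
        "p2,do_not_know,present,40.0\n"
        "p3,missing,absent,28.1\n"
    )
    specs = [
        mm.VariableSpec("AD", "binary", "shc"),
        mm.VariableSpec("BI", "binary", "shc"),
        mm.VariableSpec("PCS", "continuous", "outcome"),
    ]
    return path, specs


def test_load_cohort_applies_coding(token_csv):
    path, specs = token_csv
    ds = load_cohort(path, specs)
    assert ds.values.loc["p2", "AD"] == 0  # do-not-know rule
    assert np.isnan(ds.values.loc["p3", "AD"])
    assert ds.values.shape == (3, 3)


def test_load_cohort_schema_contract(token_csv, tmp_path):
    path, specs = token_csv
    with pytest.raises(SchemaError, match="missing"):
        load_cohort(path, specs + [mm.VariableSpec("ZZ", "binary", "shc")])
    extra = tmp_path / "extra.csv"
    extra.write_text(path.read_text().replace(",PCS", ",PCS,junk")
                     .replace(",31.5", ",31.5,x").replace(",40.0", ",40.0,y")
                     .replace(",28.1", ",28.1,z"))
    with pytest.warns(UserWarning, match="junk"):
        ds = load_cohort(extra, specs)
    assert "junk" not in ds.values.columns
    bad = tmp_path / "bad.csv"
    bad.write_text("participant_id,AD,BI,PCS\np1,present,absent,oops\n")
    with pytest.raises(SchemaError, match="PCS"):
        load_cohort(bad, specs)


def test_cohort_roundtrip(tmp_path, small_cohort):
    """Writing a coded dataset and re-loading it reproduces the values."""
    dataset, _ = small_cohort
    out = tmp_path / "cohort.csv"
    save_cohort(dataset, out)
    back = load_cohort(out, dataset.specs, cohort_label=dataset.cohort_label)
    pd.testing.assert_frame_equal(
        back.values, dataset.values.set_axis(back.values.index), check_dtype=False
    )
    assert out.with_suffix(".json").exists()


def test_dichotomized_view(small_cohort):
    dataset, _ = small_cohort
    dv = dichotomized_view(dataset)
    for col in ("Satis", "QoL"):
        assert set(np.unique(dv.values[col].dropna())) <= {0, 1}
        assert dv.spec(col).kind == "binary"
    # already-binary outcome unchanged
    pd.testing.assert_series_equal(dv.values["Care"], dataset.values["Care"])
    # composition matches the scalar rule
    assert ((dataset.values["Satis"] >= 5).astype(int) == dv.values["Satis"]).all()
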