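"""Univariable screening, logistic regression and comparison-arm ROC."""

import numpy as np
import pandas as pd
import pytest

from sactex.clinical import (
    fit_logistic,
    model_probability_roc,
    screen_univariable,
)


def _cohort(rng, n=100, n_pos=40):
    labels = np.array(["expansion"] * n_pos + ["non_expansion"] * (n - n_pos))
    return pd.DataFrame({"id": np.arange(n), "label": labels})


def test_identical_groups_not_selected(rng):
    df = _cohort(rng)
    df["x"] = np.tile([1.0, 2.0, 3.0, 4.0], 25)
    (res,) = screen_univariable(df, {"x": "continuous"})
    assert res.p_value > 0.5
    assert not res.selected


def test_three_sd_shift_is_selected(rng):
    df = _cohort(rng, n=100, n_pos=50)
    x = rng.normal(0, 1, 100)
    x[:50] += 3.0
    df["x"] = x
    (res,) = screen_univariable(df, {"x": "continuous"})
    assert res.p_value < 0.1
    assert res.selected
    assert res.test == "welch_t"


def test_study_type1_contingency_screens_in():
    # type-I endoleak tally: 6 of 38 expanders vs 1 of 61 non-expanders
    labels = ["expansion"] * 38 + ["non_expansion"] * 61
    leak = (["type_I"] * 6 + ["none"] * 32) + (["type_I"] * 1 + ["none"] * 60)
    df = pd.DataFrame({"label": labels, "endoleak_t1": leak})
    (res,) = screen_univariable(df, {"endoleak_t1": "categorical"})
    assert res.test == "fisher_exact"  # expected cell < 5
    assert res.p_value < 0.1
    assert res.selected


def test_zero_variance_flagged_not_crashed(rng):
    df = _cohort(rng)
    df["x"] = 5.0
    (res,) = screen_univariable(df, {"x": "continuous"})
    assert np.isnan(res.p_value)
    assert not res.selected
    assert "zero variance" in res.note


def test_screening_p_invariant_to_affine_rescaling(rng):
    df = _cohort(rng)
    df["x"] = rng.normal(0, 1, len(df)) + (df["label"] == "expansion") * 0.8
    (a,) = screen_univariable(df, {"x": "continuous"})
    df["x"] = 37.0 * df["x"] - 11.0
    (b,) = screen_univariable(df, {"x": "continuous"})
    assert a.p_value == pytest.approx(b.p_value, rel=1e-9)


def test_forced_variable_selected_despite_null_p(rng):
    df = _cohort(rng)
    df["x"] = rng.normal(0, 1, len(df))
    (res,) = screen_univariable(df, {"x": "continuous"}, forced=("x",))
    assert res.selected


def test_univariable_or_equals_cross_product_ratio():
    # 2x2 counts: expansion/type_II 6, expansion/none 26, non/type_II 6, non/none 54
    labels = ["expansion"] * 32 + ["non_expansion"] * 60
    x = ([1.0] * 6 + [0.0] * 26) + ([1.0] * 6 + [0.0] * 54)
    df = pd.DataFrame({"label": labels, "t2": x})
    fit = fit_logistic(df, ["t2"])
    assert fit.odds_ratios["t2"] == pytest.approx((6 * 54) / (6 * 26), abs=1e-6)


def test_null_predictor_or_near_one(rng):
    n = 500
    labels = np.where(rng.random(n) < 0.4, "expansion", "non_expansion")
    df = pd.DataFrame({"label": labels, "x": rng.normal(0, 1, n)})
    fit = fit_logistic(df, ["x"])
    assert 0.8 <= fit.odds_ratios["x"] <= 1.25


def test_constant_outcome_raises_separation_diagnostic(rng):
    df = pd.DataFrame({"label": ["expansion"] * 10, "x": rng.normal(0, 1, 10)})
    with pytest.raises(ValueError, match="separation"):
        fit_logistic(df, ["x"])


def test_perfectly_separating_predictor_flagged(rng):
    df = _cohort(rng, n=40, n_pos=20)
    df["x"] = (df["label"] == "expansion").astype(float) + rng.normal(0, 1e-4, 40)
    with pytest.warns(UserWarning, match="separation"):
        fit = fit_logistic(df, ["x"])
    assert "separation" in fit.diagnostics


def test_endoleak_dummy_coding_uses_none_reference(rng):
    df = _cohort(rng, n=99, n_pos=38)
    leak = np.array(["none"] * 80 + ["type_I"] * 7 + ["type_II"] * 12)
    df["endoleak"] = rng.permutation(leak)
    fit = fit_logistic(df, ["endoleak"])
    assert "endoleak_type_I" in fit.params.index
    assert "endoleak_type_II" in fit.params.index
    assert "endoleak_none" not in fit.params.index


def test_oracle_predictor_arm_reaches_auc_one(rng):
    df = _cohort(rng, n=60, n_pos=25)
    df["x"] = (df["label"] == "expansion") * 1.0 + rng.normal(0, 0.01, 60)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # separation is the point here
        rocs = model_probability_roc(df, {"oracle": ["x"]})
    assert rocs["oracle"].auc == 1.0


def test_label_independent_covariates_give_null_auc(rng):
    n = 500
    labels = np.array(["expansion"] * 200 + ["non_expansion"] * 300)
    df = pd.DataFrame(
        {"label": labels, "a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)}
    )
    rocs = model_probability_roc(df, {"null": ["a", "b"]})
    assert 0.44 <= rocs["null"].auc <= 0.56


def test_nested_in_sample_auc_never_below_subset(rng):
    n = 300
    labels = np.array(["expansion"] * 120 + ["non_expansion"] * 180)
    sig = (labels == "expansion") * 0.8 + rng.normal(0, 1, n)
    df = pd.DataFrame({"label": labels, "imaging": sig, "extra": rng.normal(0, 1, n)})
    rocs = model_probability_roc(
        df, {"imaging": ["imaging"], "combined": ["imaging", "extra"]}
    )
    assert rocs["combined"].auc >= rocs["imaging"].auc - 1e-9
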