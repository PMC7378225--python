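"""Repeated stratified splits and MLP training/evaluation behaviour."""

import numpy as np
import pandas as pd
import pytest

from sactex.modeling import (
    MLPConfig,
    evaluate_feature_set,
    fit_scaler,
    make_splits,
    partition_sizes,
    train_mlp,
)

FAST = MLPConfig(max_epochs=150, patience=10)


def _feature_frame(rng, n=99, n_pos=38, n_feat=4, separation=0.0):
    y = np.r_[np.ones(n_pos, int), np.zeros(n - n_pos, int)]
    X = rng.normal(0, 1, (n, n_feat))
    X[:n_pos, 0] += separation
    df = pd.DataFrame(X, columns=[f"f{k}" for k in range(n_feat)])
    df["label_binary"] = y
    df["id"] = [f"p{k}" for k in range(n)]
    return df


def test_92_patients_partition_as_64_14_14():
    assert partition_sizes(92, (0.70, 0.15, 0.15)) == [64, 14, 14]


def test_splits_partition_stratify_and_reproduce():
    rng = np.random.default_rng(0)
    ids = np.array([f"p{k}" for k in range(92)])
    labels = np.r_[np.ones(32, int), np.zeros(60, int)]
    rng.shuffle(labels)
    a = make_splits(ids, labels, n_repeats=5, seed=42)
    b = make_splits(ids, labels, n_repeats=5, seed=42)
    frac = labels.mean()
    lab_of = dict(zip(ids, labels))
    for sa, sb in zip(a, b):
        assert (sa.train_ids, sa.val_ids, sa.test_ids) == (
            sb.train_ids, sb.val_ids, sb.test_ids,
        )
        parts = (sa.train_ids, sa.val_ids, sa.test_ids)
        assert sorted(sum(map(list, parts), [])) == sorted(ids)
        assert [len(p) for p in parts] == [64, 14, 14]
        for p in parts:
            n_pos = sum(lab_of[i] for i in p)
            assert abs(n_pos - frac * len(p)) <= 1.0  # within one patient
    # independent repeats differ
    assert a[0].train_ids != a[1].train_ids


def test_too_small_class_refused():
    ids = np.arange(30)
    labels = np.r_[np.ones(5, int), np.zeros(25, int)]
    with pytest.raises(ValueError, match="stratify"):
        make_splits(ids, labels, n_repeats=1, seed=0)


def test_linearly_separable_clusters_reach_high_auc(rng):
    df = _feature_frame(rng, n=200, n_pos=100, separation=6.0)
    res = evaluate_feature_set(df, ["f0", "f1", "f2", "f3"], n_repeats=10, seed=1,
                               config=FAST)
    assert res["auc_mean"] >= 0.99


def test_permuted_labels_give_null_auc(rng):
    df = _feature_frame(rng, separation=3.0)
    df["label_binary"] = rng.permutation(df["label_binary"].to_numpy())
    res = evaluate_feature_set(df, ["f0", "f1", "f2", "f3"], n_repeats=100, seed=2,
                               config=FAST)
    assert 0.40 <= res["auc_mean"] <= 0.60


def test_constant_features_predict_constant_auc_half(rng):
    df = _feature_frame(rng)
    for c in ("f0", "f1", "f2", "f3"):
        df[c] = 1.0
    res = evaluate_feature_set(df, ["f0", "f1"], n_repeats=3, seed=3, config=FAST)
    assert res["auc_mean"] == pytest.approx(0.5)


def test_nonfinite_feature_names_the_column(rng):
    df = _feature_frame(rng)
    df.loc[5, "f2"] = np.nan
    with pytest.raises(ValueError, match="f2"):
        evaluate_feature_set(df, ["f0", "f2"], n_repeats=2, seed=0, config=FAST)


def test_label_canary_detects_absence_of_leakage(rng):
    """Test AUC is ~1 only when the label itself is a training column."""
    df = _feature_frame(rng, separation=0.0)
    df["canary"] = df["label_binary"].astype(float)
    with_canary = evaluate_feature_set(df, ["f0", "canary"], n_repeats=5, seed=4,
                                       config=FAST)
    without = evaluate_feature_set(df, ["f0", "f1"], n_repeats=25, seed=4, config=FAST)
    assert with_canary["auc_mean"] >= 0.99
    assert without["auc_mean"] <= 0.65


def test_mean_auc_invariant_to_patient_ordering(rng):
    df = _feature_frame(rng, separation=2.0)
    res_a = evaluate_feature_set(df, ["f0", "f1"], n_repeats=5, seed=7, config=FAST)
    shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
    res_b = evaluate_feature_set(shuffled, ["f0", "f1"], n_repeats=5, seed=7,
                                 config=FAST)
    assert res_a["auc_mean"] == pytest.approx(res_b["auc_mean"], abs=1e-12)


def test_training_reproducible_from_seed(rng):
    df = _feature_frame(rng, separation=2.0)
    a = evaluate_feature_set(df, ["f0", "f1"], n_repeats=3, seed=9, config=FAST)
    b = evaluate_feature_set(df, ["f0", "f1"], n_repeats=3, seed=9, config=FAST)
    pd.testing.assert_frame_equal(a["per_repeat"], b["per_repeat"])


def test_early_stopping_restores_best_validation_state(rng):
    X = rng.normal(0, 1, (60, 2))
    y = (X[:, 0] > 0).astype(int)
    mean, sd = fit_scaler(X[:40])
    Z = (X - mean) / sd
    clf = train_mlp(Z[:40], y[:40], Z[40:], y[40:],
                    MLPConfig(max_epochs=100, patience=5), seed=0)
    prob = clf.predict_proba(Z[40:])[:, 1]
    assert prob.shape == (20,)
    assert ((prob > 0) & (prob < 1)).all()  # single sigmoid score


def test_pooled_aggregate_available(rng):
    df = _feature_frame(rng, separation=4.0)
    res = evaluate_feature_set(df, ["f0"], n_repeats=4, seed=5, config=FAST,
                               aggregate="pooled")
    assert 0.0 <= res["pooled_auc"] <= 1.0
    assert "pooled_metrics" in res
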