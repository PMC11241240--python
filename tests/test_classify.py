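import numpy as np
import pandas as pd
import pytest

from gifp.classify import (
    BINARY_CLASSES,
    FOUR_CLASSES,
    apply_preprocessing,
    confusion,
    fit_preprocessing,
    load_bundle,
    majority_vote,
    merge_active,
    metrics,
    predict,
    save_bundle,
    split,
    train,
    train_table,
)
from gifp.features import table_to_frame


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def _frame(n):
    return pd.DataFrame({"complex_id": range(n), "label": ["a"] * n, "x": range(n)})


def test_split_1820_gives_1365():
    train_f, test_f = split(_frame(1820), seed=3)
    assert (len(train_f), len(test_f)) == (1365, 455)


def test_split_tiny():
    train_f, test_f = split(_frame(4), seed=0)
    assert (len(train_f), len(test_f)) == (3, 1)


def test_split_deterministic_and_disjoint():
    a1, b1 = split(_frame(100), seed=42)
    a2, b2 = split(_frame(100), seed=42)
    assert list(a1.complex_id) == list(a2.complex_id)
    assert list(b1.complex_id) == list(b2.complex_id)
    assert not set(a1.complex_id) & set(b1.complex_id)
    assert set(a1.complex_id) | set(b1.complex_id) == set(range(100))


def test_split_rejects_single_row():
    with pytest.raises(ValueError):
        split(_frame(1))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _prep_frame():
    return pd.DataFrame(
        {
            "complex_id": ["a", "b", "c"],
            "label": ["agonist", "inactive", "agonist"],
            "is_modeled": [0, 1, 0],
            "3.32_sum": [1.0, np.nan, 3.0],
            "3.32_type1": ["Hbond", "NA", "Ionic"],
            "3.32_e1": [-1.0, np.nan, -3.0],
            "3.32_type2": ["None", "NA", "None"],
            "3.32_e2": [0.0, np.nan, 0.0],
        }
    )


def test_mean_imputation():
    frame = _prep_frame()
    prep = fit_preprocessing(frame)
    # [1, NA, 3] imputes to mean 2 before scaling
    assert prep.impute_means["3.32_sum"] == pytest.approx(2.0)


def test_standardized_columns_zero_mean_unit_var():
    frame = _prep_frame()
    prep = fit_preprocessing(frame)
    X = apply_preprocessing(prep, frame)
    assert np.abs(X.mean(axis=0)).max() < 1e-8
    stds = X.std(axis=0)
    for sd in stds:
        assert sd == pytest.approx(1.0, abs=1e-6) or sd == pytest.approx(0.0, abs=1e-9)


def test_unseen_category_reserved_code():
    frame = _prep_frame()
    prep = fit_preprocessing(frame)
    novel = frame.copy()
    novel.loc[0, "3.32_type1"] = "Metal"  # unseen at fit time
    X = apply_preprocessing(prep, novel)  # must not crash
    assert np.isfinite(X).all()
    assert prep.encode("3.32_type1", "Metal") == len(prep.encoders["3.32_type1"])


def test_categorical_na_is_own_category():
    prep = fit_preprocessing(_prep_frame())
    assert "NA" in prep.encoders["3.32_type1"]


def test_all_na_column_warns():
    frame = _prep_frame()
    frame["3.32_e2"] = np.nan
    with pytest.warns(UserWarning, match="entirely NA"):
        prep = fit_preprocessing(frame)
    assert prep.impute_means["3.32_e2"] == 0.0


# ---------------------------------------------------------------------------
# forest training and prediction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted(strong_dataset_module):
    frame, bundle, train_f, test_f = strong_dataset_module
    return frame, bundle, train_f, test_f


@pytest.fixture(scope="module")
def strong_dataset_module():
    from conftest import strong_signal_spec
    from gifp.synthetic import make_profile_dataset

    frame = table_to_frame(make_profile_dataset(strong_signal_spec(seed=11)))
    train_f, test_f = split(frame, seed=11)
    bundle = train_table(train_f, seed=11)
    return frame, bundle, train_f, test_f


def test_cv_score_high_on_planted_signal(fitted):
    _, bundle, _, _ = fitted
    assert bundle.cv_score >= 0.9


def test_chance_level_after_label_permutation(strong_dataset_module):
    frame, _, train_f, _ = strong_dataset_module
    rng = np.random.default_rng(0)
    permuted = train_f.copy()
    permuted["label"] = rng.permutation(permuted["label"].to_numpy())
    bundle = train_table(permuted, seed=0)
    assert bundle.cv_score == pytest.approx(0.25, abs=0.1)


def test_training_rows_interpolated(fitted):
    _, bundle, train_f, _ = fitted
    X = apply_preprocessing(bundle.preprocessing, train_f)
    preds = predict(bundle, X, true_labels=list(train_f["label"]))
    assert (preds["predicted"] == preds["true"]).mean() == 1.0


def test_heldout_accuracy(fitted):
    _, bundle, _, test_f = fitted
    X = apply_preprocessing(bundle.preprocessing, test_f)
    preds = predict(bundle, X, true_labels=list(test_f["label"]))
    assert (preds["predicted"] == preds["true"]).mean() >= 0.9


def test_probabilities_sum_to_one(fitted):
    _, bundle, _, test_f = fitted
    X = apply_preprocessing(bundle.preprocessing, test_f)
    preds = predict(bundle, X)
    probs = preds[[f"p_{c}" for c in bundle.classes]].to_numpy()
    assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-9


def test_predict_empty_matrix(fitted):
    _, bundle, _, _ = fitted
    n_feat = bundle.forest.n_features_in_
    preds = predict(bundle, np.empty((0, n_feat)))
    assert preds.empty


def test_predict_column_mismatch(fitted):
    _, bundle, _, _ = fitted
    with pytest.raises(ValueError, match="columns"):
        predict(bundle, np.zeros((2, 3)))


def test_single_class_training_rejected():
    X = np.zeros((20, 3))
    with pytest.raises(ValueError, match="single class"):
        train(X, ["agonist"] * 20, seed=0)


def test_determinism(fitted):
    frame, _, train_f, test_f = fitted
    b1 = train_table(train_f, seed=5)
    b2 = train_table(train_f, seed=5)
    X = apply_preprocessing(b1.preprocessing, test_f)
    p1 = predict(b1, X)
    p2 = predict(b2, X)
    assert list(p1["predicted"]) == list(p2["predicted"])


def test_bundle_round_trip(tmp_path, fitted):
    _, bundle, _, test_f = fitted
    save_bundle(bundle, tmp_path / "model")
    again = load_bundle(tmp_path / "model")
    X = apply_preprocessing(again.preprocessing, test_f)
    assert list(predict(again, X)["predicted"]) == list(
        predict(bundle, apply_preprocessing(bundle.preprocessing, test_f))["predicted"]
    )


# ---------------------------------------------------------------------------
# merge / vote
# ---------------------------------------------------------------------------

def test_merge_active_mapping():
    assert merge_active(["inverse_agonist"]) == ["active"]
    assert merge_active(["inactive"]) == ["inactive"]
    assert merge_active(["agonist", "antagonist"]) == ["active", "active"]
    with pytest.raises(ValueError):
        merge_active(["binder"])


def test_merged_accuracy_never_below_four_class():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(5, 60))
        true = rng.choice(FOUR_CLASSES, size=n)
        pred = rng.choice(FOUR_CLASSES, size=n)
        acc4 = float(np.mean(true == pred))
        acc2 = float(
            np.mean(np.array(merge_active(true)) == np.array(merge_active(pred)))
        )
        assert acc2 >= acc4


def _pose_frame(labels, probs=None, group="g1"):
    frame = pd.DataFrame(
        {
            "model_id": [group] * len(labels),
            "ligand_id": ["lig"] * len(labels),
            "predicted": labels,
            "true": ["agonist"] * len(labels),
        }
    )
    for c in FOUR_CLASSES:
        frame[f"p_{c}"] = 0.25
    if probs:
        for k, (lab, p) in enumerate(probs):
            frame.loc[k, f"p_{lab}"] = p
    return frame


def test_majority_vote_worked_example():
    frame = _pose_frame(["agonist", "agonist", "agonist", "inactive", "inactive"])
    voted = majority_vote(frame, ["model_id", "ligand_id"])
    assert list(voted["predicted"]) == ["agonist"]


def test_majority_vote_unanimous():
    frame = _pose_frame(["inactive"] * 5)
    voted = majority_vote(frame, ["model_id", "ligand_id"])
    assert list(voted["predicted"]) == ["inactive"]


def test_majority_vote_tie_breaks_on_probability():
    frame = _pose_frame(
        ["agonist", "inactive"],
        probs=[("agonist", 0.9), ("inactive", 0.3)],
    )
    with pytest.warns(UserWarning, match="even"):
        voted = majority_vote(frame, ["model_id", "ligand_id"])
    assert list(voted["predicted"]) == ["agonist"]


# ---------------------------------------------------------------------------
# confusion and metrics
# ---------------------------------------------------------------------------

def test_confusion_perfect_diagonal():
    cm = confusion(["agonist", "inactive"], ["agonist", "inactive"], list(FOUR_CLASSES))
    assert np.trace(cm.counts) == 2


def test_confusion_transpose_on_swap():
    true = ["agonist", "agonist", "inactive"]
    pred = ["inactive", "agonist", "agonist"]
    a = confusion(true, pred, list(FOUR_CLASSES))
    b = confusion(pred, true, list(FOUR_CLASSES))
    assert (a.counts == b.counts.T).all()


def test_confusion_rejects_unknown_label():
    with pytest.raises(ValueError, match="outside order"):
        confusion(["x"], ["agonist"], list(FOUR_CLASSES))


def _expand(counts, labels):
    true, pred = [], []
    for i, row in enumerate(counts):
        for j, n in enumerate(row):
            true += [labels[i]] * n
            pred += [labels[j]] * n
    return true, pred


def test_metrics_table7_values():
    true, pred = _expand([[269, 56], [13, 117]], list(BINARY_CLASSES))
    report = metrics(confusion(true, pred, list(BINARY_CLASSES)))
    assert round(report.hit_rate, 1) == 95.4
    assert round(report.accuracy, 2) == 0.85


def test_metrics_table10_values():
    true, pred = _expand([[19, 1], [4, 0]], list(BINARY_CLASSES))
    report = metrics(confusion(true, pred, list(BINARY_CLASSES)))
    assert round(report.hit_rate, 1) == 82.6
    assert round(report.accuracy, 2) == 0.79


def test_metrics_table5_accuracy():
    counts = [[94, 14, 0, 21], [16, 127, 1, 35], [1, 7, 9, 0], [9, 4, 0, 117]]
    true, pred = _expand(counts, list(FOUR_CLASSES))
    report = metrics(confusion(true, pred, list(FOUR_CLASSES)))
    assert round(report.accuracy, 2) == 0.76
    assert report.precision == report.recall == report.accuracy


def test_hit_rate_none_when_no_predicted_actives():
    true, pred = _expand([[0, 3], [0, 5]], list(BINARY_CLASSES))
    report = metrics(confusion(true, pred, list(BINARY_CLASSES)))
    assert report.hit_rate is None


def test_micro_identity_on_random_matrices():
    rng = np.random.default_rng(7)
    for _ in range(100):
        k = int(rng.integers(2, 5))
        counts = rng.integers(0, 30, size=(k, k))
        if counts.sum() == 0:
            counts[0, 0] = 1
        labels = [f"c{i}" for i in range(k)]
        true, pred = _expand(counts.tolist(), labels)
        report = metrics(confusion(true, pred, labels))
        assert report.precision == report.recall == report.accuracy


def test_metrics_empty_matrix_rejected():
    from gifp.classify import ConfusionMatrix

    cm = ConfusionMatrix(labels=["a", "b"], counts=np.zeros((2, 2), dtype=int))
    with pytest.raises(ValueError):
        metrics(cm)
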