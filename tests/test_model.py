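"""Classifier training protocol: splitting, feature selection, the margin
model and forest baseline, metrics, and applicability-domain scoring."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import acpdesign as a
from acpdesign.model import (
    ModelSchemaError,
    metrics_from_predictions,
    sequential_feature_elimination,
)

from conftest import toy_dataset


# ---------------------------------------------------------------------------
# stratified split


def test_split_class_counts_match_per_class_rounding():
    """339 positives + 680 negatives at fraction 1/3 -> 113 + 227 test."""
    labels = np.array([1] * 339 + [0] * 680)
    ds = toy_dataset(np.random.default_rng(0).normal(size=(1019, 3)), labels)
    train, test = a.stratified_split(ds, 1 / 3, seed=1)
    assert int(test.labels.sum()) == 113
    assert int((test.labels == 0).sum()) in (226, 227)
    assert len(train) + len(test) == 1019


def test_split_balanced_halves_and_determinism():
    ds = toy_dataset(np.arange(40).reshape(20, 2), [1] * 10 + [0] * 10)
    tr1, te1 = a.stratified_split(ds, 0.5, seed=3)
    tr2, te2 = a.stratified_split(ds, 0.5, seed=3)
    assert int(te1.labels.sum()) == 5 and len(te1) == 10
    assert list(te1.X.index) == list(te2.X.index)
    # train and test partition the input
    assert set(te1.X.index).isdisjoint(tr1.X.index)


def test_split_refuses_tiny_class():
    ds = toy_dataset(np.zeros((3, 2)), [1, 0, 0])
    with pytest.raises(ValueError, match="fewer than 2"):
        a.stratified_split(ds, 0.5, seed=0)


# ---------------------------------------------------------------------------
# covariance elimination


def test_identical_columns_keep_one():
    x = np.random.default_rng(0).normal(size=100)
    X = pd.DataFrame({"a": x, "b": x, "c": np.random.default_rng(1).normal(size=100)})
    assert a.covariance_elimination(X, 0.9) == ["a", "c"]


def test_orthogonalish_columns_all_survive():
    X = pd.DataFrame(
        np.random.default_rng(5).normal(size=(200, 8)),
        columns=[f"f{i}" for i in range(8)],
    )
    assert a.covariance_elimination(X, 0.9) == list(X.columns)


def test_zero_variance_dropped():
    X = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
    assert a.covariance_elimination(X, 0.9) == ["b"]


def test_planted_correlated_triplet_matches_greedy_oracle():
    rng = np.random.default_rng(11)
    base = rng.normal(size=300)
    X = pd.DataFrame({
        "f0": base,
        "f1": base + rng.normal(scale=0.01, size=300),   # |r| ~ 1 with f0
        "f2": rng.normal(size=300),
        "f3": -base + rng.normal(scale=0.01, size=300),  # |r| ~ 1 with f0
        "f4": rng.normal(size=300),
    })
    # oracle: full correlation matrix + greedy replay in column order
    corr = X.corr().abs().to_numpy()
    kept = []
    for j in range(X.shape[1]):
        if all(corr[j, k] <= 0.9 for k in kept):
            kept.append(j)
    assert a.covariance_elimination(X, 0.9) == [X.columns[j] for j in kept]
    assert a.covariance_elimination(X, 0.9) == ["f0", "f2", "f4"]


# ---------------------------------------------------------------------------
# sequential feature elimination


def _planted_signal(n=160, n_noise=8, seed=2):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2 + n_noise))
    X[:, 0] += 2.5 * y
    X[:, 1] -= 2.5 * y
    names = ["inf0", "inf1"] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=names), y


def test_sfe_recovers_informative_features():
    X, y = _planted_signal()
    selected, path = sequential_feature_elimination(X, y, cv_folds=3, seed=0)
    assert {"inf0", "inf1"} <= set(selected)
    assert len(path) == X.shape[1]  # initial subset + F-1 elimination steps


def test_sfe_single_candidate_returned_unchanged():
    X, y = _planted_signal()
    selected, path = sequential_feature_elimination(X, y, candidates=["inf0"])
    assert selected == ["inf0"]


def test_sfe_refuses_empty_candidates():
    X, y = _planted_signal()
    with pytest.raises(ValueError):
        sequential_feature_elimination(X, y, candidates=[])


# ---------------------------------------------------------------------------
# margin classifier and forest baseline


def test_separable_data_reaches_perfect_training_mcc():
    rng = np.random.default_rng(1)
    y = np.repeat([0, 1], 40)
    X = np.column_stack([
        y * 4.0 + rng.uniform(0, 1, size=80),  # disjoint class ranges
        rng.normal(size=80),
    ])
    ds = toy_dataset(X, y)
    res = a.AcpClassifier(ds, select_features=False, cv_folds=4, seed=0).fit()
    assert res.train_report.mcc == pytest.approx(1.0)
    assert "mcc" in res.summary()


def test_shuffled_labels_give_near_zero_cv_mcc():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(200, 5))
    y = rng.permutation(np.repeat([0, 1], 100))
    ds = toy_dataset(X, y)
    res = a.AcpClassifier(ds, select_features=False, cv_folds=5, seed=9).fit()
    assert abs(res.cv_report.mcc) < 0.3


def test_planted_signal_dominates_weight_ranking():
    rng = np.random.default_rng(4)
    y = np.repeat([0, 1], 100)
    X = rng.normal(size=(200, 4))
    X[:, 1] += 4.0 * y  # only feature f1 separates the classes
    ds = toy_dataset(X, y)
    res = a.AcpClassifier(ds, select_features=False, cv_folds=5, seed=4).fit()
    assert res.weights.abs().idxmax() == "f1"


def test_forest_baseline_separable_and_deterministic():
    X, y = _planted_signal(n=80, n_noise=0)
    ds = toy_dataset(X.to_numpy(), y, names=list(X.columns))
    res1 = a.AcpClassifier(ds, estimator="rf", select_features=False,
                           cv_folds=4, seed=0).fit()
    res2 = a.AcpClassifier(ds, estimator="rf", select_features=False,
                           cv_folds=4, seed=0).fit()
    assert res1.train_report.accuracy == pytest.approx(1.0)
    p1 = res1.predict_proba_matrix(X.to_numpy())
    p2 = res2.predict_proba_matrix(X.to_numpy())
    np.testing.assert_array_equal(p1, p2)
    assert res1.model_params == {"n_estimators": 500, "max_features": "sqrt"}


def test_forest_and_margin_agree_on_easy_data():
    X, y = _planted_signal(n=120, n_noise=2, seed=6)
    ds = toy_dataset(X.to_numpy(), y, names=list(X.columns))
    svm = a.AcpClassifier(ds, select_features=False, cv_folds=4, seed=6).fit()
    rf = a.AcpClassifier(ds, estimator="rf", select_features=False,
                         cv_folds=4, seed=6).fit()
    assert abs(svm.cv_report.mcc - rf.cv_report.mcc) < 0.1


def test_refuses_single_class_or_empty_grid(small_dataset):
    ds = toy_dataset(np.zeros((10, 2)), [1] * 10)
    with pytest.raises(ValueError):
        a.AcpClassifier(ds)
    with pytest.raises(ValueError):
        a.AcpClassifier(small_dataset, C_grid=())


# ---------------------------------------------------------------------------
# metrics


def test_printed_confusion_example():
    rep = a.metrics_from_counts(tp=4, fp=2, tn=6, fn=0)
    assert rep.accuracy == pytest.approx(10 / 12)
    assert rep.mcc == pytest.approx(24 / np.sqrt(1152))
    assert rep.n == 12


def test_perfect_predictions():
    rep = a.metrics_from_counts(tp=5, fp=0, tn=5, fn=0)
    assert (rep.mcc, rep.accuracy, rep.precision, rep.recall) == (1, 1, 1, 1)


def test_all_one_class_prediction_warns_and_reports_zero_mcc():
    with pytest.warns(UserWarning, match="degenerate"):
        rep = metrics_from_predictions([0, 1, 0, 1], [1, 1, 1, 1])
    assert rep.mcc == 0.0


def test_metrics_match_formula_on_random_confusions():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        tp, fp, tn, fn = rng.integers(1, 50, size=4)
        rep = a.metrics_from_counts(int(tp), int(fp), int(tn), int(fn))
        assert rep.mcc == pytest.approx(
            (tp * tn - fp * fn)
            / np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
        )
        assert rep.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
        assert rep.precision == pytest.approx(tp / (tp + fp))
        assert rep.recall == pytest.approx(tp / (tp + fn))


# ---------------------------------------------------------------------------
# similarity and design scores


def test_similarity_closed_forms(small_results):
    import copy

    res = copy.copy(small_results)
    assert res.centroids.shape[0] == 3
    # a point coincident with all three centroids has S = 1
    res.centroids = np.tile(small_results.centroids[0], (3, 1))
    x_raw = res.centroids[0] * res.scaler_std + res.scaler_mean
    assert res.similarity_matrix(x_raw[None, :])[0] == pytest.approx(1.0)
    # a point at mean distance 1 has S = 0.5
    direction = np.zeros(res.centroids.shape[1])
    direction[0] = 1.0
    x_raw = (res.centroids[0] + direction) * res.scaler_std + res.scaler_mean
    assert res.similarity_matrix(x_raw[None, :])[0] == pytest.approx(0.5)


def test_similarity_monotone_in_distance(small_results):
    res = small_results
    rng = np.random.default_rng(0)
    direction = rng.normal(size=res.centroids.shape[1])
    direction /= np.linalg.norm(direction)
    center_std = res.centroids.mean(axis=0)
    sims = []
    for radius in (0.0, 1.0, 3.0, 10.0):
        x_std = center_std + radius * direction
        x_raw = x_std * res.scaler_std + res.scaler_mean
        sims.append(res.similarity_matrix(x_raw[None, :])[0])
    assert all(s1 > s2 for s1, s2 in zip(sims, sims[1:]))
    assert all(0 < s <= 1 for s in sims)


def test_phi_printed_row_and_symmetry():
    phi_a, phi_n = a.phi_scores(1.0, 0.92)
    assert phi_a == pytest.approx(0.96)
    eq_a, eq_n = a.phi_scores(0.5, 0.3)
    assert eq_a == pytest.approx(eq_n)


@given(
    st.floats(min_value=0, max_value=1),
    st.floats(min_value=0, max_value=1),
)
def test_phi_identity(p, s):
    phi_a, phi_n = a.phi_scores(p, s)
    assert 0 <= phi_a <= 1 and 0 <= phi_n <= 1
    assert phi_a + phi_n == pytest.approx(0.5 + s, abs=1e-12)


# ---------------------------------------------------------------------------
# screening


def test_screen_columns_sorting_and_boundary(small_results):
    lib = ["KKKKKKKKKKKW", "ILILILILILIL", "KWKWKWKWKWKW"]
    table = small_results.screen(lib)
    assert list(table.columns) == [
        "id", "sequence", "P_ACP", "sim_score", "phi_acp", "phi_neg",
        "predicted_class",
    ]
    assert table["phi_acp"].is_monotonic_decreasing
    # classification threshold: P_ACP >= 0.5 is called active
    np.testing.assert_array_equal(
        table["predicted_class"].to_numpy(), (table["P_ACP"] >= 0.5).astype(int)
    )
    assert len(small_results.screen([])) == 0


def test_training_peptides_score_higher_similarity_than_remote(small_results,
                                                               small_dataset):
    train_sim = small_results.similarity_matrix(
        small_results._select(small_dataset.X)
    )
    rng = np.random.default_rng(99)
    remote = ["".join(rng.choice(list("CCCCMMMMWW"), size=25)) for _ in range(20)]
    remote_sim = small_results.similarity(remote)
    assert train_sim.mean() > remote_sim.mean()


def test_top_two_selection_shape(small_results):
    lib = a.generate_amphipathic_arc(a.LibrarySpec(count=20, seed=5))
    top_acp = small_results.screen(lib, sort_by="phi_acp").head(2)
    top_neg = small_results.screen(lib, sort_by="phi_neg").head(2)
    assert len(top_acp) == 2 and len(top_neg) == 2
    assert top_neg["phi_neg"].iloc[0] >= top_neg["phi_neg"].iloc[1]


# ---------------------------------------------------------------------------
# persistence


def test_model_json_round_trip(tmp_path, small_results, small_dataset):
    path = tmp_path / "model.json"
    small_results.save(path)
    loaded = a.AcpClassifierResults.load(path)
    X = small_dataset.X
    np.testing.assert_allclose(
        small_results.predict_proba_matrix(small_results._select(X)),
        loaded.predict_proba_matrix(loaded._select(X)),
    )
    np.testing.assert_allclose(
        small_results.similarity_matrix(small_results._select(X)),
        loaded.similarity_matrix(loaded._select(X)),
    )


def test_model_json_missing_block_raises_schema_error(tmp_path, small_results):
    import json

    path = tmp_path / "model.json"
    small_results.save(path)
    doc = json.loads(path.read_text())
    del doc["centroids"]
    path.write_text(json.dumps(doc))
    with pytest.raises(ModelSchemaError):
        a.AcpClassifierResults.load(path)
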