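"""Model lab: splits, training, metrics, selection, Fisher r-to-z."""

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, matthews_corrcoef, recall_score

import herbsig as hs


# --- stratified k-fold -----------------------------------------------------

def test_stratified_split_balanced_folds():
    y = np.array([0, 1] * 50)
    folds = hs.stratified_kfold_split(y, k=10, seed=0)
    for f in range(10):
        mask = folds == f
        assert mask.sum() == 10
        assert y[mask].sum() == 5


def test_stratified_split_deterministic_under_seed():
    y = np.array([0] * 70 + [1] * 30)
    a = hs.stratified_kfold_split(y, k=10, seed=5)
    b = hs.stratified_kfold_split(y, k=10, seed=5)
    c = hs.stratified_kfold_split(y, k=10, seed=6)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_stratified_split_study_scale_prevalence():
    """997 positives over 10 folds must land 99 or 100 per fold."""
    y = np.array([1] * 997 + [0] * 3516)
    folds = hs.stratified_kfold_split(y, k=10, seed=1)
    per_fold_pos = [int(y[folds == f].sum()) for f in range(10)]
    assert set(per_fold_pos) <= {99, 100}
    sizes = [int((folds == f).sum()) for f in range(10)]
    assert max(sizes) - min(sizes) <= 1


def test_stratified_split_errors():
    with pytest.raises(hs.DatasetError):
        hs.stratified_kfold_split([0] * 50 + [1] * 5, k=10, seed=0)
    with pytest.raises(hs.DatasetError):
        hs.stratified_kfold_split([1] * 50, k=5, seed=0)


# --- blind split -----------------------------------------------------------

def test_blind_split_sizes_and_disjointness():
    records = list(range(4513))
    train, test = hs.blind_split(records, fraction=0.10, seed=3)
    assert len(test) == 451
    assert len(train) + len(test) == 4513
    assert set(train) | set(test) == set(records)
    assert set(train) & set(test) == set()


def test_blind_split_small_n_and_errors():
    _, test = hs.blind_split(list(range(10)), fraction=0.10, seed=0)
    assert len(test) == 1
    with pytest.raises(hs.ContractError):
        hs.blind_split(list(range(3)), fraction=0.01, seed=0)
    with pytest.raises(hs.ContractError):
        hs.blind_split(list(range(10)), fraction=1.5, seed=0)


def test_blind_split_stratified_option():
    y = [1] * 20 + [0] * 80
    records = list(range(100))
    _, test = hs.blind_split(records, fraction=0.10, seed=0, stratify=y)
    n_pos = sum(1 for i in test if i < 20)
    assert n_pos == 2 and len(test) == 10


# --- training --------------------------------------------------------------

def _toy_separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = np.column_stack([y * 4.0 + rng.normal(0, 0.2, n), rng.normal(0, 1, n)])
    return X, y


def test_train_separable_toy_perfect_training_auc():
    X, y = _toy_separable()
    spec = hs.ModelSpec(task="classification", seed=0)
    est = hs.train_model(X, y, spec)
    scores = est.predict_proba(X)[:, 1]
    rep = hs.evaluate_classification(y, scores)
    assert rep.metrics["roc_auc"] == 1.0


def test_train_constant_regression_target():
    X = np.arange(20, dtype=float).reshape(-1, 1)
    y = np.full(20, 3.5)
    spec = hs.ModelSpec(task="regression", seed=0)
    est = hs.train_model(X, y, spec)
    assert np.allclose(est.predict(X), 3.5)


def test_train_deterministic_under_seed():
    X, y = _toy_separable(60, seed=1)
    spec = hs.ModelSpec(task="classification", seed=9)
    p1 = hs.train_model(X, y, spec).predict_proba(X)
    p2 = hs.train_model(X, y, spec).predict_proba(X)
    assert np.array_equal(p1, p2)


def test_train_single_class_is_contract_error():
    X = np.zeros((10, 2))
    with pytest.raises(hs.ContractError):
        hs.train_model(X, np.ones(10), hs.ModelSpec(task="classification"))


def test_model_spec_validates_task_and_algorithm():
    with pytest.raises(hs.ContractError):
        hs.ModelSpec(task="clustering")
    with pytest.raises(hs.ContractError):
        hs.ModelSpec(task="classification", algorithm="deep_net")


# --- classification metrics ------------------------------------------------

def test_perfect_scores_metrics():
    y = [0, 0, 1, 1]
    rep = hs.evaluate_classification(y, [0.0, 0.1, 0.9, 1.0])
    m = rep.metrics
    assert m["accuracy"] == 1 and m["mcc"] == 1 and m["roc_auc"] == 1


def test_all_positive_on_balanced_set():
    y = [0, 1] * 10
    rep = hs.evaluate_classification(y, [1.0] * 20)
    assert rep.metrics["accuracy"] == 0.5
    assert rep.metrics["mcc"] == 0.0


def test_mcc_formula_example():
    # confusion (TP=8, FN=2, FP=3, TN=7) at threshold 0.5
    y = [1] * 10 + [0] * 10
    s = [0.9] * 8 + [0.1] * 2 + [0.9] * 3 + [0.1] * 7
    rep = hs.evaluate_classification(y, s)
    expected = (8 * 7 - 3 * 2) / np.sqrt((8 + 3) * (8 + 2) * (7 + 3) * (7 + 2))
    assert rep.metrics["mcc"] == pytest.approx(expected)
    assert rep.metrics["sensitivity"] == pytest.approx(0.8)
    assert rep.metrics["specificity"] == pytest.approx(0.7)


def _auc_pair_oracle(y, s):
    """Exhaustive concordant-pair AUC with ties counted half."""
    y, s = np.asarray(y), np.asarray(s)
    pos = s[y == 1]
    neg = s[y == 0]
    total = len(pos) * len(neg)
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return conc / total


def test_roc_auc_equals_concordant_pair_statistic():
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = int(rng.integers(6, 50))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = np.round(rng.random(n), 2)  # rounding forces ties
        rep = hs.evaluate_classification(y, s)
        assert rep.metrics["roc_auc"] == pytest.approx(_auc_pair_oracle(y, s))


def test_threshold_metrics_match_sklearn_on_random_confusions():
    rng = np.random.default_rng(4)
    for _ in range(50):
        n = int(rng.integers(10, 80))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = rng.random(n)
        rep = hs.evaluate_classification(y, s)
        pred = (s >= 0.5).astype(int)
        assert rep.metrics["accuracy"] == pytest.approx(accuracy_score(y, pred))
        assert rep.metrics["mcc"] == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)
        assert rep.metrics["sensitivity"] == pytest.approx(recall_score(y, pred))
        assert rep.metrics["specificity"] == pytest.approx(
            recall_score(y, pred, pos_label=0)
        )


def test_one_class_auc_undefined():
    with pytest.raises(hs.DatasetError):
        hs.evaluate_classification([1, 1, 1], [0.5, 0.6, 0.7])


# --- regression metrics ----------------------------------------------------

def test_regression_identity_and_scaling():
    y = np.arange(10.0)
    rep = hs.evaluate_regression(y, y)
    assert rep.metrics["pearson_r"] == pytest.approx(1.0)
    assert rep.metrics["rmse"] == 0.0
    rep2 = hs.evaluate_regression(y, 2 * y)
    assert rep2.metrics["pearson_r"] == pytest.approx(1.0)
    assert rep2.metrics["rmse"] > 0


def test_trimmed_r_removes_exactly_ten_percent():
    rng = np.random.default_rng(0)
    y = rng.normal(size=20)
    p = y + rng.normal(0, 0.1, 20)
    rep = hs.evaluate_regression(y, p, trim_fraction=0.10)
    assert rep.metrics["n_trimmed"] == 2


def test_trimmed_r_never_worse_when_outliers_removed():
    rng = np.random.default_rng(1)
    y = np.linspace(0, 10, 20)
    p = y + rng.normal(0, 0.05, 20)
    p[3] += 8.0  # two gross outliers dominate the residuals
    p[15] -= 6.0
    rep = hs.evaluate_regression(y, p, trim_fraction=0.10)
    assert rep.metrics["trimmed_pearson_r"] >= rep.metrics["pearson_r"]


def test_regression_zero_variance_error():
    with pytest.raises(hs.DatasetError):
        hs.evaluate_regression([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


# --- Fisher r-to-z ---------------------------------------------------------

def test_fisher_equal_r_gives_zero():
    z, p = hs.fisher_r_to_z_compare(0.7, 100, 0.7, 200)
    assert z == 0.0 and p == pytest.approx(1.0)


def test_fisher_antisymmetry():
    z1, p1 = hs.fisher_r_to_z_compare(0.86, 554, 0.74, 554)
    z2, p2 = hs.fisher_r_to_z_compare(0.74, 554, 0.86, 554)
    assert z1 == pytest.approx(-z2)
    assert p1 == pytest.approx(p2)


def test_fisher_minnow_comparison_significant():
    """0.86 vs 0.74 at n=554 each is significant at P <= 0.05."""
    z, p = hs.fisher_r_to_z_compare(0.86, 554, 0.74, 554)
    expected_z = (np.arctanh(0.86) - np.arctanh(0.74)) / np.sqrt(2 / (554 - 3))
    assert z == pytest.approx(expected_z)
    assert p <= 0.05


def test_fisher_contract_errors():
    with pytest.raises(hs.ContractError):
        hs.fisher_r_to_z_compare(1.0, 100, 0.5, 100)
    with pytest.raises(hs.ContractError):
        hs.fisher_r_to_z_compare(0.5, 3, 0.5, 100)


# --- cross-validation ------------------------------------------------------

def test_each_sample_predicted_once_k2_and_loo():
    X, y = _toy_separable(24, seed=2)
    spec = hs.ModelSpec(
        task="classification", hyperparameters={"n_estimators": 20}, seed=0
    )
    for k in (2, 12):
        rep = hs.cross_validate(X, y, spec, k=k, seed=0)
        assert rep.n == 24
        assert len(rep.predictions) == 24
        assert not np.isnan(rep.predictions).any()


def test_cross_validate_regression_pools_all_points():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 3))
    y = X @ [1.0, -2.0, 0.5] + rng.normal(0, 0.1, 60)
    spec = hs.ModelSpec(
        task="regression", algorithm="ridge", hyperparameters={}, seed=0
    )
    rep = hs.cross_validate(X, y, spec, k=5, seed=0)
    assert rep.metrics["pearson_r"] > 0.95
    assert len(rep.per_fold) == 5


# --- greedy forward selection ----------------------------------------------

def _informative_noise(n=80, n_noise=8, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    informative = y + rng.normal(0, 0.3, n)
    X = np.column_stack([informative] + [rng.normal(size=n) for _ in range(n_noise)])
    return X, y


def test_greedy_selects_informative_feature_first():
    X, y = _informative_noise()
    spec = hs.ModelSpec(
        task="classification", algorithm="logistic_regression", hyperparameters={}
    )
    selected = hs.greedy_forward_selection(X, y, spec, k=3, seed=0)
    assert selected[0] == 0


def test_greedy_infinite_tolerance_single_feature():
    X, y = _informative_noise()
    spec = hs.ModelSpec(
        task="classification", algorithm="logistic_regression", hyperparameters={}
    )
    selected = hs.greedy_forward_selection(
        X, y, spec, tolerance=np.inf, k=3, seed=0
    )
    assert selected == [0]


def test_greedy_duplicate_columns_lower_index_wins():
    X, y = _informative_noise(n=60, n_noise=2)
    X = np.column_stack([X[:, 0], X[:, 0], X[:, 1], X[:, 2]])
    spec = hs.ModelSpec(
        task="classification", algorithm="logistic_regression", hyperparameters={}
    )
    selected = hs.greedy_forward_selection(X, y, spec, tolerance=np.inf, k=3, seed=0)
    assert selected == [0]


# --- persistence & profiles ------------------------------------------------

def test_save_load_roundtrip(tmp_path):
    X, y = _toy_separable()
    spec = hs.ModelSpec(
        task="classification", hyperparameters={"n_estimators": 25}, seed=2
    )
    est = hs.train_model(X, y, spec)
    path = tmp_path / "model.joblib"
    hs.save_model(path, est, spec, checksum="abc123")
    est2, spec2, meta = hs.load_model(path)
    assert spec2.hyperparameters == spec.hyperparameters
    assert meta["training_checksum"] == "abc123"
    assert np.array_equal(est.predict_proba(X), est2.predict_proba(X))


def test_predict_profile_empty_registry():
    records = [hs.MoleculeRecord("a", "CCO")]
    frame, _ = hs.predict_profile(records, {})
    assert list(frame.columns) == ["id", "smiles"]


def test_predict_profile_classification_and_regression_columns():
    rng = np.random.default_rng(0)
    records = [hs.MoleculeRecord("a", "CCO"), hs.MoleculeRecord("b", "c1ccccc1Cl")]
    X, _ = hs.featurize_dataset(
        [hs.MoleculeRecord(f"t{i}", s) for i, s in enumerate(
            ["CCO", "CCN", "c1ccccc1", "CCCC", "c1ccccc1Cl", "CC(=O)O"] * 4
        )]
    )
    y_cls = rng.integers(0, 2, len(X))
    y_cls[:2] = [0, 1]
    y_reg = rng.normal(size=len(X))
    cls_spec = hs.ModelSpec(
        task="classification", hyperparameters={"n_estimators": 15}, seed=0
    )
    reg_spec = hs.ModelSpec(
        task="regression", hyperparameters={"n_estimators": 15}, seed=0
    )
    registry = {
        "herbicide": hs.EndpointModel(
            "herbicide", cls_spec, hs.train_model(X, y_cls, cls_spec)
        ),
        "lc50": hs.EndpointModel("lc50", reg_spec, hs.train_model(X, y_reg, reg_spec)),
    }
    frame, rows = hs.predict_profile(records, registry)
    assert {"herbicide_class", "herbicide_prob", "lc50_value"} <= set(frame.columns)
    assert len(frame) == 2
    frame2, _ = hs.predict_profile(records, registry)
    assert frame.equals(frame2)
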