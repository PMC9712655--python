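"""Confusion metrics, splitting, training, GHOST and confidence tiers."""

import math

import numpy as np
import pandas as pd
import pytest

from steroidqsar.chemotypes import ChemotypeMatrix
from steroidqsar.errors import ConfigurationError, InputError
from steroidqsar.qsar import (
    BalancedRandomForestClassifier,
    ConfusionCounts,
    SplitPlan,
    TrainedModel,
    auc,
    compute_metrics,
    confusion_counts,
    cross_validate,
    ghost_threshold,
    mcc_from_labels,
    predict_with_confidence,
    split_train_test,
    train_classifier,
)
from steroidqsar.similarity import Fingerprint


def brute_force_metrics(tp, tn, fp, fn):
    n = tp + tn + fp + fn
    se = tp / (tp + fn) if tp + fn else math.nan
    sp = tn / (tn + fp) if tn + fp else math.nan
    acc = (tp + tn) / n
    bacc = (se + sp) / 2
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return se, sp, acc, bacc, mcc


def test_metrics_match_bruteforce_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(200):
        tp, tn, fp, fn = (int(v) for v in rng.integers(0, 60, size=4))
        if tp + tn + fp + fn == 0:
            continue
        report = compute_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        se, sp, acc, bacc, mcc = brute_force_metrics(tp, tn, fp, fn)
        for got, want in [(report.se, se), (report.sp, sp), (report.acc, acc),
                          (report.bacc, bacc), (report.mcc, mcc)]:
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)
        if not (math.isnan(report.se) or math.isnan(report.sp)):
            assert report.bacc == pytest.approx((report.se + report.sp) / 2, abs=1e-15)


def test_perfect_and_degenerate_classifiers():
    perfect = compute_metrics(ConfusionCounts(tp=10, tn=90, fp=0, fn=0))
    assert (perfect.se, perfect.sp, perfect.acc, perfect.bacc, perfect.mcc) == (1, 1, 1, 1, 1)
    # all-inactive predictor at 10% prevalence
    degenerate = compute_metrics(ConfusionCounts(tp=0, tn=90, fp=0, fn=10))
    assert degenerate.se == 0 and degenerate.sp == 1
    assert degenerate.bacc == 0.5 and degenerate.mcc == 0.0


def test_confusion_counts_inversion_swaps_cells():
    true = [1, 1, 0, 0, 0, 1]
    pred = [1, 0, 0, 1, 0, 1]
    c = confusion_counts(pred, true)
    inverted = confusion_counts([1 - p for p in pred], true)
    assert (c.tp, c.fn) == (inverted.fn, inverted.tp)
    assert (c.tn, c.fp) == (inverted.fp, inverted.tn)
    assert c.n == 6


def test_confusion_counts_input_validation():
    with pytest.raises(InputError):
        confusion_counts([], [])
    with pytest.raises(InputError):
        confusion_counts([2], [1])
    with pytest.raises(InputError):
        confusion_counts(["maybe"], ["active"])


def test_auc_trivial_rankings():
    labels = [0, 0, 1, 1]
    assert auc([0.1, 0.2, 0.8, 0.9], labels) == 1.0
    assert auc([0.5, 0.5, 0.5, 0.5], labels) == 0.5
    assert auc([0.9, 0.8, 0.2, 0.1], labels) == 0.0
    with pytest.raises(InputError):
        auc([0.5, 0.5], [1, 1])


def test_split_train_test_stratification():
    ids = [f"c{i}" for i in range(100)]
    labels = {i: "active" for i in ids[:10]} | {i: "inactive" for i in ids[10:]}
    plans = split_train_test(ids, labels, SplitPlan(seed=3))
    assert len(plans) == 5
    assert len({tuple(sorted(test)) for _, test in plans}) == 5  # distinct repeats
    for train, test in plans:
        assert len(test) == 15
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)
        n_active = sum(labels[i] == "active" for i in test)
        assert n_active in (1, 2)
    again = split_train_test(ids, labels, SplitPlan(seed=3))
    assert plans == again
    with pytest.raises(InputError):
        split_train_test(ids, {i: "inactive" for i in ids}, SplitPlan())


@pytest.fixture(scope="module")
def toy_training():
    """Separable two-class toy problem at 20% prevalence."""
    rng = np.random.default_rng(7)
    n = 200
    y = (rng.random(n) < 0.2).astype(int)
    x = rng.normal(size=(n, 8))
    x[:, 0] += 2.0 * y  # informative feature
    X = pd.DataFrame(x, index=[f"c{i}" for i in range(n)])
    return X, y


def test_train_classifier_single_point_grid(toy_training):
    X, y = toy_training
    model = train_classifier(
        X, y, learner="balanced_rf", hyper_grid={"n_estimators": [40]}, cv_folds=5, seed=0
    )
    assert model.best_params == {"n_estimators": 40}
    assert model.estimator.n_estimators == 40
    assert model.cv_mcc > 0  # learnable by construction
    with pytest.raises(ConfigurationError):
        train_classifier(X, y, hyper_grid={"n_estimators": []})


def test_shuffled_labels_give_chance_level_cv(toy_training):
    X, y = toy_training
    rng = np.random.default_rng(1)
    scores = []
    for _ in range(5):
        shuffled = rng.permutation(y)
        if shuffled.sum() < 5:
            continue
        model = train_classifier(
            X, shuffled, learner="balanced_rf",
            hyper_grid={"n_estimators": [40]}, cv_folds=5, seed=0,
        )
        scores.append(model.cv_mcc)
    assert abs(np.mean(scores)) < 0.1


def test_balanced_rf_requires_two_classes(toy_training):
    X, _ = toy_training
    clf = BalancedRandomForestClassifier(n_estimators=5, random_state=0)
    with pytest.raises(InputError):
        clf.fit(X.to_numpy(), np.zeros(len(X)))


def test_ghost_matches_exhaustive_scan(toy_training):
    X, y = toy_training
    model = train_classifier(
        X, y, learner="rf", hyper_grid={"n_estimators": [60]}, cv_folds=5, seed=0
    )
    candidates = (0.1, 0.2, 0.3, 0.4, 0.5)
    chosen = ghost_threshold(
        model, X, y, candidates=candidates, n_draws=1, subsample_fraction=1.0,
        seed=0, use_oob=False,
    )
    probs = model.probabilities(X)
    scores = {t: mcc_from_labels((probs >= t).astype(int), y) for t in candidates}
    best = max(scores.values())
    tied = [t for t, s in scores.items() if s == best]
    assert chosen == min(tied, key=lambda t: abs(t - 0.5))
    # definitional: no worse than the default cutoff on the tuning sample
    assert scores[chosen] >= scores[0.5]
    assert model.threshold == chosen


def test_ghost_on_separable_probabilities_stays_in_grid(toy_training):
    X, y = toy_training

    class Oracle:
        classes_ = np.array([0, 1])

        def predict_proba(self, arr):
            p = np.where(arr[:, 0] > 1.0, 0.9, 0.1)
            return np.column_stack([1 - p, p])

    oracle_y = (X.to_numpy()[:, 0] > 1.0).astype(int)
    model = TrainedModel(learner="stub", estimator=Oracle(), descriptor_names=list(X.columns))
    chosen = ghost_threshold(model, X, oracle_y, n_draws=5, seed=1)
    assert 0.1 < chosen <= 0.9
    assert chosen in set(np.round(np.arange(0.05, 0.51, 0.05), 2))


def test_cross_validate_pooled_counts_and_determinism(toy_training):
    X, y = toy_training
    result = cross_validate(
        X, y, learner=BalancedRandomForestClassifier(n_estimators=30), k=5, seed=2
    )
    assert result["pooled_counts"].n == len(X)
    fold_accs = [r.acc for r in result["per_fold"]]
    assert min(fold_accs) <= result["pooled"].acc <= max(fold_accs)
    repeat = cross_validate(
        X, y, learner=BalancedRandomForestClassifier(n_estimators=30), k=5, seed=2
    )
    assert repeat["pooled"].mcc == result["pooled"].mcc
    with pytest.raises(InputError):
        cross_validate(X, y, k=1000)


def test_leave_one_out_runs_on_tiny_set():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(12, 3)), index=[f"c{i}" for i in range(12)])
    y = np.array([1, 0] * 6)
    result = cross_validate(
        X, y, learner=BalancedRandomForestClassifier(n_estimators=10), k=12, seed=0
    )
    assert result["pooled_counts"].n == 12


class _FixedProbs:
    """Stub estimator emitting a preset active probability per row."""

    classes_ = np.array([0, 1])

    def __init__(self, probs):
        self._probs = np.asarray(probs, dtype=float)

    def predict_proba(self, arr):
        p = self._probs[: arr.shape[0]]
        return np.column_stack([1 - p, p])


def test_predict_with_confidence_tiers():
    ids = ["q_high", "q_medium", "q_inactive"]
    X = pd.DataFrame(np.zeros((3, 2)), index=ids, columns=["d1", "d2"])
    train_fp = Fingerprint("train", frozenset(range(1, 11)))
    model = TrainedModel(
        learner="stub",
        estimator=_FixedProbs([0.8, 0.8, 0.3]),
        threshold=0.5,
        descriptor_names=["d1", "d2"],
        training_fingerprints=[train_fp],
    )
    query_fps = [
        Fingerprint("q_high", frozenset(range(1, 11))),    # AD = 1.0
        Fingerprint("q_medium", frozenset(range(100, 106))),  # AD = 0.0
        Fingerprint("q_inactive", frozenset(range(1, 11))),
    ]
    chemotypes = ChemotypeMatrix(
        values=pd.DataFrame(1, index=ids, columns=[f"ct{i}" for i in range(5)])
    )
    enrichment = pd.DataFrame(
        {
            "chemotype": [f"ct{i}" for i in range(5)],
            "p_value": [1e-4] * 5,
            "untestable": [False] * 5,
        }
    )
    records = predict_with_confidence(model, X, query_fps, enrichment, chemotypes)
    by_id = {r.id: r for r in records}
    assert by_id["q_high"].confidence == "high"
    assert by_id["q_high"].significant_chemotype_count == 5
    assert by_id["q_medium"].confidence == "medium"  # probability + chemotypes, AD fails
    assert by_id["q_inactive"].predicted_label == "inactive"
    assert by_id["q_inactive"].confidence == "not_applicable"


def test_predict_with_confidence_validates_descriptors():
    model = TrainedModel(
        learner="stub",
        estimator=_FixedProbs([0.8]),
        descriptor_names=["d1", "d_missing"],
        training_fingerprints=[Fingerprint("t", frozenset({1}))],
    )
    X = pd.DataFrame(np.zeros((1, 1)), index=["q"], columns=["d1"])
    with pytest.raises(InputError, match="d_missing"):
        model.probabilities(X)


def test_trained_model_save_load_roundtrip(tmp_path, toy_training):
    X, y = toy_training
    model = train_classifier(
        X, y, learner="balanced_rf", hyper_grid={"n_estimators": [20]}, cv_folds=5,
        seed=0, training_fingerprints=[Fingerprint("t0", frozenset({1, 2}))],
    )
    model.threshold = 0.35
    model.save(tmp_path / "model")
    loaded = TrainedModel.load(tmp_path / "model")
    assert loaded.threshold == 0.35
    assert loaded.descriptor_names == model.descriptor_names
    assert loaded.training_fingerprints == model.training_fingerprints
    assert np.allclose(loaded.probabilities(X), model.probabilities(X))
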