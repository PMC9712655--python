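"""Imbalance-aware binary QSAR classification.

Reference learners are a random forest and a balanced random forest (each
tree grown on a class-balanced bootstrap, so the ~10:90 class imbalance does
not swamp the active class).  Model selection is a grid search scored by the
mean Matthews correlation coefficient (MCC) over stratified 10-fold
cross-validation.  After fitting, the decision threshold on the predicted
active probability is optimized with a generalized threshold-shifting
(GHOST) scan: candidate cutoffs 0.05..0.50 are scored on repeated stratified
subsamples of the training set and the cutoff with the best median score
wins (ties resolved toward 0.5).

Performance is summarized with the standard confusion-matrix suite —
sensitivity SE = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy,
balanced accuracy bAcc = (SE+SP)/2, MCC — plus the rank-based ROC AUC.

Predictions on new chemicals carry a confidence tier built from three
criteria: predicted active probability > 0.5, applicability-domain score
>= 0.75 (similarity to the nearest training chemical), and more than three
significant chemotypes present.  Predicted actives meeting all three are
high confidence, exactly two medium, otherwise low; the tier does not apply
to predicted inactives.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import (
    KFold,
    ParameterGrid,
    StratifiedKFold,
    StratifiedShuffleSplit,
)
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .chemotypes import ChemotypeMatrix
from .errors import ConfigurationError, InputError
from .similarity import Fingerprint, ad_score

GHOST_CANDIDATES = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2))

HIGH_CONFIDENCE_PROBABILITY = 0.5
HIGH_CONFIDENCE_AD = 0.75
HIGH_CONFIDENCE_CHEMOTYPES = 3  # strictly more than this many significant chemotypes


# ---------------------------------------------------------------------------
# confusion counts and metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    se: float
    sp: float
    acc: float
    bacc: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {"se": self.se, "sp": self.sp, "acc": self.acc, "bacc": self.bacc, "mcc": self.mcc}
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def _as_binary(labels: Iterable) -> np.ndarray:
    mapping = {"active": 1, "inactive": 0, 1: 1, 0: 0, True: 1, False: 0}
    out = []
    for value in labels:
        key = int(value) if isinstance(value, (np.integer, np.bool_)) else value
        if key not in mapping:
            raise InputError(f"label {value!r} is not one of active/inactive (1/0)")
        out.append(mapping[key])
    return np.asarray(out, dtype=int)


def confusion_counts(predicted: Iterable, true: Iterable) -> ConfusionCounts:
    """Exact TP/TN/FP/FN counts; labels must be active/inactive (or 1/0)."""
    pred = _as_binary(predicted)
    obs = _as_binary(true)
    if pred.size == 0:
        raise InputError("cannot compute confusion counts on empty input")
    if pred.shape != obs.shape:
        raise InputError("predicted and true label vectors differ in length")
    return ConfusionCounts(
        tp=int(((pred == 1) & (obs == 1)).sum()),
        tn=int(((pred == 0) & (obs == 0)).sum()),
        fp=int(((pred == 1) & (obs == 0)).sum()),
        fn=int(((pred == 0) & (obs == 1)).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """SE, SP, Acc, bAcc and MCC from confusion counts.

    An undefined SE or SP (no positives / no negatives observed) is reported
    as NaN; an MCC with a zero denominator is reported as 0, matching the
    convention that a degenerate all-one-class predictor has no correlation.
    """
    if c.n == 0:
        raise InputError("metrics need at least one evaluated chemical")
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else math.nan
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else math.nan
    acc = (c.tp + c.tn) / c.n
    bacc = (se + sp) / 2.0
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(se=se, sp=sp, acc=acc, bacc=bacc, mcc=mcc)


def mcc_from_labels(predicted: Iterable, true: Iterable) -> float:
    return compute_metrics(confusion_counts(predicted, true)).mcc


def auc(probabilities: Iterable[float], labels: Iterable) -> float:
    """Rank-based (Mann-Whitney) ROC AUC; ties receive half credit."""
    y = _as_binary(labels)
    if len(set(y)) < 2:
        raise InputError("AUC requires both classes to be present")
    return float(roc_auc_score(y, np.asarray(list(probabilities), dtype=float)))


# ---------------------------------------------------------------------------
# learners


class BalancedRandomForestClassifier(BaseEstimator, ClassifierMixin):
    """Random forest in which each tree sees a class-balanced bootstrap.

    For every tree, ``n_minority`` chemicals are drawn with replacement from
    each class before growing an unpruned decision tree on the balanced
    sample; predicted probabilities are averaged over trees.  This keeps the
    per-tree prior at 50:50 so the minority (active) class is not swamped.
    """

    def __init__(
        self,
        n_estimators: int = 200,
        max_features: str | int | float = "sqrt",
        min_samples_leaf: int = 1,
        max_depth: int | None = None,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise InputError("balanced random forest requires exactly two classes")
        rng = np.random.default_rng(self.random_state)
        by_class = [np.flatnonzero(y_idx == k) for k in range(2)]
        n_draw = min(len(idx) for idx in by_class)
        if n_draw == 0:
            raise InputError("each class needs at least one training chemical")
        self.estimators_ = []
        self._bootstrap_masks = []
        for _ in range(self.n_estimators):
            sample = np.concatenate(
                [rng.choice(idx, size=n_draw, replace=True) for idx in by_class]
            )
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                min_samples_leaf=self.min_samples_leaf,
                max_depth=self.max_depth,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[sample], y_idx[sample])
            self.estimators_.append(tree)
            mask = np.zeros(len(y_idx), dtype=bool)
            mask[sample] = True
            self._bootstrap_masks.append(mask)
        self._train_X = X
        self.oob_decision_function_ = self._oob_decision_function()
        return self

    def _oob_decision_function(self) -> np.ndarray:
        """Per-training-sample class probabilities from trees whose bootstrap
        did not contain the sample (NaN rows where no such tree exists)."""
        n = self._train_X.shape[0]
        acc = np.zeros((n, 2))
        counts = np.zeros(n)
        for tree, mask in zip(self.estimators_, self._bootstrap_masks):
            oob = ~mask
            if not oob.any():
                continue
            proba = tree.predict_proba(self._train_X[oob])
            for local, cls in enumerate(tree.classes_):
                acc[oob, int(cls)] += proba[:, local]
            counts[oob] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            out = acc / counts[:, None]
        return out

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        acc = np.zeros((X.shape[0], 2))
        for tree in self.estimators_:
            proba = tree.predict_proba(X)
            for local, cls in enumerate(tree.classes_):
                acc[:, int(cls)] += proba[:, local]
        return acc / len(self.estimators_)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def _make_learner(kind: str | BaseEstimator, seed: int) -> BaseEstimator:
    if isinstance(kind, BaseEstimator):
        est = clone(kind)
        if "random_state" in est.get_params():
            est.set_params(random_state=seed)
        return est
    if kind == "rf":
        return RandomForestClassifier(n_estimators=200, oob_score=True, random_state=seed)
    if kind == "balanced_rf":
        return BalancedRandomForestClassifier(n_estimators=200, random_state=seed)
    raise ConfigurationError(
        f"unknown learner kind {kind!r}; use 'rf', 'balanced_rf' or pass an estimator"
    )


DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {"min_samples_leaf": [1]},
    "balanced_rf": {"min_samples_leaf": [1]},
}


# ---------------------------------------------------------------------------
# splitting, training, threshold shifting


@dataclass
class SplitPlan:
    """Repeated stratified train/test splitting plan."""

    test_fraction: float = 0.15
    n_repeats: int = 5
    stratified: bool = True
    seed: int = 0


def split_train_test(
    ids: Sequence[str], labels: Mapping[str, str] | Sequence, plan: SplitPlan | None = None
) -> list[tuple[list[str], list[str]]]:
    """Stratified train/test splits preserving the class ratio.

    Returns ``plan.n_repeats`` disjoint (train ids, test ids) pairs,
    deterministic given ``plan.seed``.
    """
    plan = plan or SplitPlan()
    ids = list(ids)
    y = _as_binary(labels[i] for i in ids) if isinstance(labels, Mapping) else _as_binary(labels)
    if len(set(y)) < 2 or min(np.bincount(y)) < 2:
        raise InputError("splitting requires at least 2 chemicals in each class")
    splitter = StratifiedShuffleSplit(
        n_splits=plan.n_repeats, test_size=plan.test_fraction, random_state=plan.seed
    )
    out = []
    for train_idx, test_idx in splitter.split(np.zeros(len(ids)), y):
        out.append(([ids[i] for i in train_idx], [ids[i] for i in test_idx]))
    return out


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it honestly."""

    learner: str
    estimator: BaseEstimator
    threshold: float = 0.5
    descriptor_names: list[str] = field(default_factory=list)
    training_fingerprints: list[Fingerprint] = field(default_factory=list)
    seed: int = 0
    cv_mcc: float | None = None
    best_params: dict = field(default_factory=dict)

    def probabilities(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.descriptor_names if c not in X.columns]
        if missing:
            raise InputError(f"query matrix misses training descriptors: {missing}")
        proba = self.estimator.predict_proba(X[self.descriptor_names].to_numpy(dtype=float))
        active_col = list(self.estimator.classes_).index(1)
        return proba[:, active_col]

    def predict_labels(self, X: pd.DataFrame) -> np.ndarray:
        return (self.probabilities(X) >= self.threshold).astype(int)

    def save(self, directory: str | Path) -> None:
        path = Path(directory)
        path.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.estimator, path / "estimator.joblib")
        config = {
            "learner": self.learner,
            "threshold": self.threshold,
            "descriptor_names": self.descriptor_names,
            "seed": self.seed,
            "cv_mcc": self.cv_mcc,
            "best_params": self.best_params,
            "training_fingerprints": {
                fp.id: sorted(fp.bits) for fp in self.training_fingerprints
            },
        }
        with open(path / "model.json", "w") as handle:
            json.dump(config, handle, indent=1)

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        path = Path(directory)
        estimator = joblib.load(path / "estimator.joblib")
        with open(path / "model.json") as handle:
            config = json.load(handle)
        fps = [
            Fingerprint(id=i, bits=frozenset(bits))
            for i, bits in config.pop("training_fingerprints").items()
        ]
        return cls(estimator=estimator, training_fingerprints=fps, **config)


def train_classifier(
    X: pd.DataFrame,
    labels: Mapping[str, str] | Sequence,
    learner: str | BaseEstimator = "balanced_rf",
    hyper_grid: Mapping[str, list] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    training_fingerprints: Sequence[Fingerprint] = (),
) -> TrainedModel:
    """Grid-search a learner by stratified CV MCC and refit on the full set.

    ``X`` is the (selected) descriptor matrix of the training chemicals;
    ``labels`` maps ids to active/inactive (or is an aligned sequence).
    Every grid point is scored by the mean MCC over ``cv_folds`` stratified
    folds; the best configuration is refit on the full training set.
    """
    ids = list(X.index)
    y = _as_binary(labels[i] for i in ids) if isinstance(labels, Mapping) else _as_binary(labels)
    if len(set(y)) < 2:
        raise InputError("training requires both classes")
    kind = learner if isinstance(learner, str) else getattr(learner, "__class__").__name__
    grid = hyper_grid if hyper_grid is not None else DEFAULT_GRIDS.get(kind, {})
    try:
        grid_points = list(ParameterGrid(grid))
    except ValueError as exc:
        raise ConfigurationError(f"degenerate hyperparameter grid: {exc}") from exc
    if not grid_points:
        raise ConfigurationError("hyperparameter grid is degenerate (no configurations)")

    x_arr = X.to_numpy(dtype=float)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best_score, best_params = -np.inf, None
    for params in grid_points:
        fold_scores = []
        for train_idx, test_idx in cv.split(x_arr, y):
            est = _make_learner(learner, seed)
            est.set_params(**params)
            est.fit(x_arr[train_idx], y[train_idx])
            pred = est.predict(x_arr[test_idx])
            fold_scores.append(mcc_from_labels(pred, y[test_idx]))
        score = float(np.mean(fold_scores))
        if score > best_score:
            best_score, best_params = score, params

    final = _make_learner(learner, seed)
    final.set_params(**best_params)
    final.fit(x_arr, y)
    return TrainedModel(
        learner=kind,
        estimator=final,
        descriptor_names=list(X.columns),
        training_fingerprints=list(training_fingerprints),
        seed=seed,
        cv_mcc=best_score,
        best_params=best_params,
    )


def _tuning_probabilities(model: TrainedModel, X: pd.DataFrame, use_oob: bool) -> np.ndarray:
    oob = getattr(model.estimator, "oob_decision_function_", None)
    if use_oob and oob is not None and oob.shape[0] == len(X):
        active_col = list(model.estimator.classes_).index(1)
        probs = oob[:, active_col].copy()
        fallback = ~np.isfinite(probs)
        if fallback.any():  # samples never out of bag
            probs[fallback] = model.probabilities(X.iloc[fallback])
        return probs
    return model.probabilities(X)


def _threshold_metric(pred: np.ndarray, y: np.ndarray, metric: str) -> float:
    if metric == "mcc":
        return mcc_from_labels(pred, y)
    if metric == "kappa":
        return float(cohen_kappa_score(y, pred))
    raise ConfigurationError(f"unknown GHOST metric {metric!r}; use 'mcc' or 'kappa'")


def ghost_threshold(
    model: TrainedModel,
    X: pd.DataFrame,
    labels: Mapping[str, str] | Sequence,
    candidates: Sequence[float] = GHOST_CANDIDATES,
    metric: str = "mcc",
    n_draws: int = 50,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    use_oob: bool = True,
) -> float:
    """Generalized threshold-shifting scan on the training set.

    Scores every candidate probability cutoff on ``n_draws`` stratified
    subsamples of the training chemicals and returns the cutoff with the
    highest median score; ties are broken toward 0.5.  The returned value is
    also stored on ``model.threshold``.

    When ``X`` is the matrix the forest was fitted on and the estimator
    exposes out-of-bag probabilities, those are scanned instead of
    resubstitution probabilities (``use_oob=True``, the default): fully
    grown forests memorize their training chemicals, which saturates
    resubstitution probabilities and makes every low cutoff tie.
    """
    ids = list(X.index)
    y = _as_binary(labels[i] for i in ids) if isinstance(labels, Mapping) else _as_binary(labels)
    probs = _tuning_probabilities(model, X, use_oob)
    rng = np.random.default_rng(seed)
    by_class = [np.flatnonzero(y == k) for k in (0, 1)]
    scores = np.zeros((n_draws, len(candidates)))
    for d in range(n_draws):
        sample = np.concatenate(
            [
                rng.choice(idx, size=max(1, int(round(subsample_fraction * len(idx)))), replace=False)
                for idx in by_class
            ]
        )
        for j, threshold in enumerate(candidates):
            pred = (probs[sample] >= threshold).astype(int)
            scores[d, j] = _threshold_metric(pred, y[sample], metric)
    medians = np.median(scores, axis=0)
    best = medians.max()
    # ties broken toward 0.5
    tied = [t for t, m in zip(candidates, medians) if m == best]
    chosen = min(tied, key=lambda t: (abs(t - 0.5), -t))
    model.threshold = float(chosen)
    return float(chosen)


def cross_validate(
    X: pd.DataFrame,
    labels: Mapping[str, str] | Sequence,
    learner: str | BaseEstimator = "balanced_rf",
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict:
    """Stratified k-fold cross-validation with per-fold and pooled metrics.

    Pooled metrics are computed from the summed confusion counts; pooled AUC
    from the concatenated out-of-fold probabilities.
    """
    ids = list(X.index)
    y = _as_binary(labels[i] for i in ids) if isinstance(labels, Mapping) else _as_binary(labels)
    if k > len(ids):
        raise InputError(f"k={k} exceeds the number of chemicals ({len(ids)})")
    # stratify whenever every fold can hold both classes; otherwise fall back
    # to plain k-fold (e.g. leave-one-out)
    if k <= int(np.bincount(y).min()):
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        cv = KFold(n_splits=k, shuffle=True, random_state=seed)
    x_arr = X.to_numpy(dtype=float)
    per_fold, all_probs, all_true = [], [], []
    total = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for train_idx, test_idx in cv.split(x_arr, y):
        est = _make_learner(learner, seed)
        est.fit(x_arr[train_idx], y[train_idx])
        proba = est.predict_proba(x_arr[test_idx])
        active_col = list(est.classes_).index(1)
        probs = proba[:, active_col]
        pred = (probs >= threshold).astype(int)
        counts = confusion_counts(pred, y[test_idx])
        report = compute_metrics(counts)
        per_fold.append(report)
        for key in total:
            total[key] += getattr(counts, key)
        all_probs.append(probs)
        all_true.append(y[test_idx])
    pooled_counts = ConfusionCounts(**total)
    pooled = compute_metrics(pooled_counts)
    pooled.auc = auc(np.concatenate(all_probs), np.concatenate(all_true))
    return {"per_fold": per_fold, "pooled": pooled, "pooled_counts": pooled_counts}


# ---------------------------------------------------------------------------
# confidence-tiered prediction


@dataclass
class PredictionRecord:
    id: str
    probability: float
    predicted_label: str
    ad_score: float
    significant_chemotype_count: int
    confidence: str  # high / medium / low / not_applicable


def predict_with_confidence(
    model: TrainedModel,
    query_descriptors: pd.DataFrame,
    query_fingerprints: Sequence[Fingerprint],
    enrichment: pd.DataFrame,
    query_chemotypes: ChemotypeMatrix,
    significance_cutoff: float = 0.05,
) -> list[PredictionRecord]:
    """Predict new chemicals with an AD- and chemotype-aware confidence tier.

    For each query chemical: the active probability, the label at the
    model's decision threshold, the AD score against the training
    fingerprints, and the number of chemotypes present that are significant
    (p < ``significance_cutoff``) in the training enrichment.  Predicted
    actives are tiered high (probability > 0.5, AD >= 0.75, more than three
    significant chemotypes), medium (exactly two criteria) or low; predicted
    inactives get ``not_applicable``.
    """
    if not model.training_fingerprints:
        raise InputError("model carries no training fingerprints for AD scoring")
    probs = model.probabilities(query_descriptors)
    fp_by_id = {fp.id: fp for fp in query_fingerprints}
    significant = set(
        enrichment.loc[
            (~enrichment["untestable"]) & (enrichment["p_value"] < significance_cutoff),
            "chemotype",
        ]
    )
    sig_cols = [c for c in query_chemotypes.names if c in significant]
    records = []
    for i, cid in enumerate(query_descriptors.index):
        if cid not in fp_by_id:
            raise InputError(f"no fingerprint supplied for query chemical {cid!r}")
        if cid not in query_chemotypes.values.index:
            raise InputError(f"no chemotype row for query chemical {cid!r}")
        domain = ad_score(fp_by_id[cid], model.training_fingerprints)
        count = int(query_chemotypes.values.loc[cid, sig_cols].sum()) if sig_cols else 0
        probability = float(probs[i])
        is_active = probability >= model.threshold
        if not is_active:
            confidence = "not_applicable"
        else:
            met = sum(
                [
                    probability > HIGH_CONFIDENCE_PROBABILITY,
                    domain >= HIGH_CONFIDENCE_AD,
                    count > HIGH_CONFIDENCE_CHEMOTYPES,
                ]
            )
            confidence = {3: "high", 2: "medium"}.get(met, "low")
        records.append(
            PredictionRecord(
                id=str(cid),
                probability=probability,
                predicted_label="active" if is_active else "inactive",
                ad_score=domain,
                significant_chemotype_count=count,
                confidence=confidence,
            )
        )
    return records


def predictions_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records]).set_index("id")
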