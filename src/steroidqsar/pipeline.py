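"""End-to-end experiment helpers: library -> curation -> descriptors ->
selection -> split -> train -> threshold shift -> external evaluation.

These glue the module-level operations into the standard experiment layout:
a stratified 85/15 train/test split, grid-searched learner with GHOST
threshold shifting on the training set, and external metrics on the held-out
test set.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .curation import curate_library
from .descriptors import compute_descriptor_matrix, select_descriptors
from .errors import PipelineError
from .qsar import (
    MetricsReport,
    SplitPlan,
    TrainedModel,
    auc,
    compute_metrics,
    confusion_counts,
    ghost_threshold,
    split_train_test,
    train_classifier,
)
from .records import ChemicalRecord
from .similarity import maccs_fingerprint
from .synthetic import SyntheticConfig, SyntheticLibrary, generate_library


@dataclass
class ExperimentData:
    """Prepared inputs for one train/test experiment (shareable between
    learners): selected descriptor matrix, labels, split and train-set
    fingerprints."""

    x_train: pd.DataFrame
    x_test: pd.DataFrame
    labels: dict[str, str]
    train_ids: list[str]
    test_ids: list[str]
    train_fingerprints: list


@dataclass
class ExperimentResult:
    model: TrainedModel
    external: MetricsReport
    train_ids: list[str]
    test_ids: list[str]


def prepare_experiment(
    records: list[ChemicalRecord],
    endpoint: str,
    seed: int = 0,
) -> ExperimentData:
    """Curate, describe, select and split a labeled library once.

    Chemicals labeled ``excluded`` for the endpoint are set aside before the
    stratified 85/15 split.
    """
    curated, rejections = curate_library(records)
    if not curated:
        raise PipelineError(f"no QSAR-ready structures (rejections: {rejections})")
    labels = {
        rec.id: rec.labels[endpoint]
        for rec in records
        if rec.labels.get(endpoint) in ("active", "inactive")
    }
    usable = [c for c in curated if c.id in labels]

    matrix = compute_descriptor_matrix(usable)
    selected, _ = select_descriptors(matrix, seed=seed)

    ids = selected.values.index.tolist()
    (train_ids, test_ids), *_ = split_train_test(
        ids, {i: labels[i] for i in ids}, SplitPlan(n_repeats=1, seed=seed)
    )
    by_id = {c.id: c for c in usable}
    return ExperimentData(
        x_train=selected.values.loc[train_ids],
        x_test=selected.values.loc[test_ids],
        labels=labels,
        train_ids=train_ids,
        test_ids=test_ids,
        train_fingerprints=[maccs_fingerprint(by_id[i]) for i in train_ids],
    )


def evaluate_learner(
    data: ExperimentData,
    learner: str = "balanced_rf",
    seed: int = 0,
    apply_ghost: bool = True,
    cv_folds: int = 10,
) -> ExperimentResult:
    """Grid-search, fit, GHOST-shift and externally validate one learner on
    prepared experiment data (external SE/SP/Acc/bAcc/MCC at the shifted
    threshold, plus AUC)."""
    train_labels = {i: data.labels[i] for i in data.train_ids}
    model = train_classifier(
        data.x_train,
        train_labels,
        learner=learner,
        cv_folds=cv_folds,
        seed=seed,
        training_fingerprints=data.train_fingerprints,
    )
    if apply_ghost:
        ghost_threshold(model, data.x_train, train_labels, seed=seed)

    probs = model.probabilities(data.x_test)
    pred = (probs >= model.threshold).astype(int)
    y_test = [data.labels[i] for i in data.test_ids]
    external = compute_metrics(confusion_counts(pred, y_test))
    try:
        external.auc = auc(probs, y_test)
    except Exception:
        external.auc = None
    return ExperimentResult(
        model=model, external=external, train_ids=data.train_ids, test_ids=data.test_ids
    )


def run_qsar_experiment(
    records: list[ChemicalRecord],
    endpoint: str,
    learner: str = "balanced_rf",
    seed: int = 0,
    apply_ghost: bool = True,
    cv_folds: int = 10,
) -> ExperimentResult:
    """Train and externally validate one QSAR model on a labeled library."""
    data = prepare_experiment(records, endpoint, seed=seed)
    return evaluate_learner(
        data, learner=learner, seed=seed, apply_ghost=apply_ghost, cv_folds=cv_folds
    )


def run_synthetic_experiment(
    config: SyntheticConfig,
    learner: str = "balanced_rf",
    apply_ghost: bool = True,
) -> tuple[SyntheticLibrary, ExperimentResult]:
    """Generate a synthetic library and run the QSAR experiment on it."""
    library = generate_library(config)
    result = run_qsar_experiment(
        library.records,
        endpoint=config.endpoint,
        learner=learner,
        seed=config.seed,
        apply_ghost=apply_ghost,
    )
    return library, result
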