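"""Fivefold cross-validation and the model x patch-size experiment matrix.

Splits are stratified at patch level: within each class the shuffled
indices are dealt to folds cyclically, with the deal pointer carried
across classes so overall fold sizes differ by at most one while each
fold's class mix tracks the global ratio within one item per class.  For
each fold the classifier is trained on the other four and scores the
held-out fold, so every patch is scored exactly once per experiment.
Per-fold metric reports are aggregated by unweighted mean; metrics on the
pooled out-of-fold predictions are also reported for audit.

Splitting at patch level means marks from one patient can appear in both
train and test folds; results carry that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .architectures import MODEL_NAMES, PATCH_SIZES
from .estimator import CNNPatchClassifier, TrainHistory
from .metrics import MetricReport, metric_report

__all__ = [
    "TrainConfig",
    "FoldAssignment",
    "CVResult",
    "make_folds",
    "train_model",
    "run_cv",
    "run_experiment_matrix",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser settings; the published baseline is the default."""

    learning_rate: float = 1e-4
    momentum: float = 0.9
    epochs: int = 50          # 120 is the published optimum for M2
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.epochs < 0 or self.batch_size <= 0:
            raise ValueError("epochs must be >= 0 and batch_size positive")


@dataclass(frozen=True)
class FoldAssignment:
    """Mapping of each patch index to one of k disjoint folds."""

    k: int
    fold_of: np.ndarray

    def indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_of == fold)[0]


def make_folds(labels, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified, seed-reproducible k-fold assignment.

    Folds are disjoint and exhaustive, overall sizes differ by at most
    one, and per-class counts across folds differ by at most one.
    """
    y = np.asarray(labels)
    n = y.size
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} items")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    pointer = rng.integers(k)  # carried across classes
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        for i in idx:
            fold_of[i] = pointer % k
            pointer += 1
    return FoldAssignment(k=k, fold_of=fold_of)


def train_model(spec_or_name, X, y, config: TrainConfig,
                input_size: int | None = None
                ) -> tuple[CNNPatchClassifier, TrainHistory]:
    """Train one architecture under a :class:`TrainConfig`.

    ``spec_or_name`` is a model name ("M1"/"M2"/"M3") or an
    ArchitectureSpec, whose name/input size are then used.
    """
    if hasattr(spec_or_name, "layers"):
        name, input_size = spec_or_name.name, spec_or_name.input_size
    else:
        name = str(spec_or_name)
    clf = CNNPatchClassifier(
        model=name, input_size=input_size,
        learning_rate=config.learning_rate, momentum=config.momentum,
        epochs=config.epochs, batch_size=config.batch_size,
        random_state=config.seed,
    )
    clf.fit(X, y)
    return clf, clf.history_


@dataclass
class CVResult:
    """Per-fold and aggregate evaluation of one (model, size) cell."""

    model: str
    patch_size: int
    per_fold: list[MetricReport]
    aggregate: MetricReport          # unweighted mean over folds
    pooled: MetricReport             # metrics on pooled o.o.f. predictions
    fold_assignment: FoldAssignment
    oof_scores: np.ndarray = field(repr=False, default=None)

    def as_row(self) -> dict:
        row = {"Model": self.model, "Patch size": f"{self.patch_size} x {self.patch_size}"}
        row.update(self.aggregate.as_percent_row())
        return row


def _mean_report(reports: list[MetricReport]) -> MetricReport:
    return MetricReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        f_score=float(np.mean([r.f_score for r in reports])),
        sensitivity=float(np.mean([r.sensitivity for r in reports])),
        auc=float(np.mean([r.auc for r in reports])),
    )


def run_cv(estimator, X, y, k: int = 5, seed: int = 0,
           model: str = "?", patch_size: int = 0) -> CVResult:
    """k-fold cross-validation of a classifier on a patch dataset.

    ``estimator`` must follow the sklearn contract (cloneable, fit,
    predict_proba).  Every patch is scored exactly once, by the fold model
    that did not see it.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("empty dataset")
    folds = make_folds(y, k=k, seed=seed)
    oof = np.full(len(y), np.nan)
    reports = []
    for fold in range(k):
        test_idx = folds.indices(fold)
        train_idx = np.nonzero(folds.fold_of != fold)[0]
        clf = clone(estimator)
        try:
            clf.fit(X[train_idx], y[train_idx])
            scores = np.asarray(clf.predict_proba(X[test_idx]))[:, 1]
        except Exception as exc:
            raise RuntimeError(f"fold {fold} failed: {exc}") from exc
        oof[test_idx] = scores
        reports.append(metric_report(y[test_idx], scores))
    assert not np.isnan(oof).any(), "some patches were never scored"
    name = model if model != "?" else getattr(estimator, "model", "?")
    size = patch_size or (X.shape[1] if X.ndim == 3 else 0)
    return CVResult(
        model=name, patch_size=size, per_fold=reports,
        aggregate=_mean_report(reports), pooled=metric_report(y, oof),
        fold_assignment=folds, oof_scores=oof,
    )


def run_experiment_matrix(
    datasets: dict[int, tuple[np.ndarray, np.ndarray]],
    models=MODEL_NAMES,
    sizes=PATCH_SIZES,
    config: TrainConfig = TrainConfig(),
    k: int = 5,
    estimator_factory=None,
) -> tuple[pd.DataFrame, list[CVResult], list[str]]:
    """Cross-validate every requested model at every requested patch size.

    ``datasets`` maps patch size to (X, y).  Missing sizes are listed and
    the remaining cells still run.  Returns the results table (one row per
    cell, percentage columns), the CVResult list, and the missing-cell
    log.  ``estimator_factory(model, size, config)`` may inject a
    different classifier (e.g. a stub in tests).
    """
    if estimator_factory is None:
        def estimator_factory(model, size, cfg):
            return CNNPatchClassifier(
                model=model, input_size=size,
                learning_rate=cfg.learning_rate, momentum=cfg.momentum,
                epochs=cfg.epochs, batch_size=cfg.batch_size,
                random_state=cfg.seed,
            )
    results: list[CVResult] = []
    missing: list[str] = []
    for model in models:
        for size in sizes:
            if size not in datasets:
                missing.append(f"{model} @ {size}: no patch store for size {size}")
                continue
            X, y = datasets[size]
            est = estimator_factory(model, size, config)
            results.append(run_cv(est, X, y, k=k, seed=config.seed,
                                  model=model, patch_size=size))
    table = pd.DataFrame([r.as_row() for r in results])
    return table, results, missing
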