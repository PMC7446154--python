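"""Confidence-weighted gradient-boosted-tree classifier.

Training minimizes a sample-weighted logistic loss with XGBoost;
hyperparameters are chosen by seeded randomized search under stratified
cross-validation with per-fold early stopping; the operating point is a
decision threshold selected to hit a target recall band (default
0.94–0.96) by scanning an ascending threshold grid over [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .evaluation import compute_auc
from .preprocessing import FeatureMatrix, FeatureSchema
from .variants import SchemaMismatchError

logger = logging.getLogger(__name__)

#: reference operating point published for pre-trained score files; never
#: used by select_threshold, which always derives the threshold from data.
REFERENCE_SCORE_THRESHOLD = 0.02

#: desk-scale analogue of the tuned optimum (lr 0.1, depth 15, 422 trees);
#: shallower/smaller because the synthetic sets are ~100x smaller.
DEFAULT_PARAMS = {"learning_rate": 0.1, "max_depth": 3, "n_estimators": 200}


@dataclass
class HyperparameterSpace:
    n_estimators_range: tuple[int, int] = (100, 600)
    max_depth_range: tuple[int, int] = (3, 20)
    learning_rate_choices: tuple[float, ...] = (0.01, 0.05, 0.1, 0.3)
    n_search_iterations: int = 10
    cv_folds: int = 5
    early_stopping_rounds: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for lo, hi in (self.n_estimators_range, self.max_depth_range):
            if hi < lo:
                raise ValueError("empty hyperparameter range")
        if not self.learning_rate_choices:
            raise ValueError("learning_rate_choices must be non-empty")


@dataclass
class ThresholdPolicy:
    """Recall band and grid for threshold selection."""

    recall_low: float = 0.94
    recall_high: float = 0.96
    grid_step: float = 0.001
    fallback: str = "closest_recall"  # or "error"

    def __post_init__(self) -> None:
        if not 0.0 < self.recall_low < self.recall_high <= 1.0:
            raise ValueError("need 0 < recall_low < recall_high <= 1")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")


@dataclass
class ThresholdResult:
    threshold: float
    recall: float
    in_band: bool


@dataclass
class TrainedModel:
    """Fitted ensemble plus everything needed to apply it: the feature
    schema, the winning hyperparameters, the selected decision threshold
    and training metadata (seed, fold AUCs)."""

    ensemble: XGBClassifier
    schema: FeatureSchema | None = None
    best_params: dict = field(default_factory=dict)
    threshold: float | None = None
    training_metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        return joblib.load(path)


def _new_classifier(params: dict, seed: int, early_stopping_rounds: int | None = None):
    kwargs = dict(
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **params,
    )
    if early_stopping_rounds is not None:
        kwargs["early_stopping_rounds"] = early_stopping_rounds
    return XGBClassifier(**kwargs)


@dataclass
class TuningResult:
    best_params: dict
    trace: list[dict]


def tune_hyperparameters(
    matrix: FeatureMatrix, space: HyperparameterSpace
) -> TuningResult:
    """Randomized hyperparameter search under stratified K-fold CV.

    ``n_search_iterations`` candidates are sampled uniformly from the space;
    each is scored by mean validation AUC across folds, fitting with sample
    weights and early stopping on the fold's validation set. The first
    candidate attaining the maximum mean AUC wins. Deterministic per seed.
    """
    if matrix.labels is None:
        raise ValueError("matrix must carry labels for tuning")
    y = matrix.labels
    X = matrix.values
    w = matrix.weights if matrix.weights is not None else np.ones(len(y))
    for cls in (0, 1):
        if (y == cls).sum() < space.cv_folds:
            raise ValueError(f"need >= {space.cv_folds} examples of class {cls}")

    rng = np.random.default_rng(space.seed)
    candidates = []
    for _ in range(space.n_search_iterations):
        candidates.append(
            {
                "n_estimators": int(
                    rng.integers(space.n_estimators_range[0], space.n_estimators_range[1] + 1)
                ),
                "max_depth": int(
                    rng.integers(space.max_depth_range[0], space.max_depth_range[1] + 1)
                ),
                "learning_rate": float(rng.choice(space.learning_rate_choices)),
            }
        )

    skf = StratifiedKFold(n_splits=space.cv_folds, shuffle=True, random_state=space.seed)
    folds = list(skf.split(X, y))
    trace: list[dict] = []
    for params in candidates:
        fold_aucs: list[float] = []
        for tr, va in folds:
            if len(set(y[tr])) < 2 or len(set(y[va])) < 2:
                warnings.warn("skipping degenerate CV fold with a single class")
                continue
            clf = _new_classifier(params, space.seed, space.early_stopping_rounds)
            clf.fit(
                X[tr], y[tr],
                sample_weight=w[tr],
                eval_set=[(X[va], y[va])],
                verbose=False,
            )
            fold_aucs.append(compute_auc(clf.predict_proba(X[va])[:, 1], y[va]))
        trace.append(
            {
                "params": params,
                "fold_aucs": fold_aucs,
                "mean_auc": float(np.mean(fold_aucs)) if fold_aucs else float("nan"),
            }
        )
    if all(not t["fold_aucs"] for t in trace):
        raise ValueError("all cross-validation folds were degenerate")
    best = max(
        (t for t in trace if t["fold_aucs"]),
        key=lambda t: t["mean_auc"],
    )
    return TuningResult(best_params=dict(best["params"]), trace=trace)


def train_model(
    matrix: FeatureMatrix,
    params: dict | None = None,
    schema: FeatureSchema | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the boosted-tree classifier with sample weights.

    Rows with weight 0 are removed before fitting, making a zero weight
    exactly equivalent to excluding the variant from training.
    """
    if matrix.labels is None:
        raise ValueError("matrix must carry labels for training")
    params = dict(params or DEFAULT_PARAMS)
    y = matrix.labels
    X = matrix.values
    w = matrix.weights if matrix.weights is not None else np.ones(len(y), dtype=float)
    if (w < 0).any():
        raise ValueError("sample weights must be non-negative")
    mask = w > 0
    X, y, w = X[mask], y[mask], w[mask]
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = _new_classifier(params, seed)
    clf.fit(X, y, sample_weight=w)
    return TrainedModel(
        ensemble=clf,
        schema=schema,
        best_params=params,
        training_metadata={
            "seed": seed,
            "n_rows_fit": int(mask.sum()),
            "n_rows_zero_weight": int((~mask).sum()),
        },
    )


def predict(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Pathogenicity scores in [0, 1]; higher = more pathogenic."""
    if model.schema is not None and matrix.columns != model.schema.feature_order:
        raise SchemaMismatchError("matrix columns do not match the model's schema")
    if matrix.n_rows == 0:
        return np.empty(0, dtype=float)
    if matrix.values.shape[1] != model.ensemble.n_features_in_:
        raise SchemaMismatchError(
            f"matrix has {matrix.values.shape[1]} columns; model expects "
            f"{model.ensemble.n_features_in_}"
        )
    return model.ensemble.predict_proba(matrix.values)[:, 1]


def threshold_grid(grid_step: float) -> np.ndarray:
    """Ascending grid {0, step, 2·step, …} covering [0, 1] inclusive."""
    n = int(np.ceil(round(1.0 / grid_step, 9)))
    grid = np.round(np.arange(n + 1) * grid_step, 12)
    grid = grid[grid <= 1.0]
    if grid[-1] < 1.0:
        grid = np.append(grid, 1.0)
    return grid


def recall_at(scores: np.ndarray, labels: np.ndarray, t: float) -> float:
    """Fraction of pathogenic rows scoring >= t (ties count as detected)."""
    pos = scores[labels == 1]
    return float((pos >= t).mean())


def select_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    policy: ThresholdPolicy | None = None,
) -> ThresholdResult:
    """First grid threshold whose recall over pathogenic rows falls inside
    the policy band; scans t ascending so the exhaustive-scan guarantee
    holds whenever any grid point achieves the band.

    If no grid point does, the ``closest_recall`` fallback returns the grid
    point whose recall is nearest the band midpoint (smallest t on ties).
    """
    policy = policy or ThresholdPolicy()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = np.sort(scores[labels == 1])
    if pos.size == 0:
        raise ValueError("threshold selection needs at least one pathogenic row")
    grid = threshold_grid(policy.grid_step)
    # recall(t) = #(pos >= t) / n_pos, vectorized over the grid
    recalls = (pos.size - np.searchsorted(pos, grid, side="left")) / pos.size
    in_band = (recalls >= policy.recall_low) & (recalls <= policy.recall_high)
    if in_band.any():
        i = int(np.argmax(in_band))
        return ThresholdResult(float(grid[i]), float(recalls[i]), True)
    if policy.fallback == "error":
        raise ValueError("no grid threshold attains the recall band")
    mid = (policy.recall_low + policy.recall_high) / 2.0
    i = int(np.argmin(np.abs(recalls - mid)))
    logger.warning(
        "no grid threshold in recall band [%g, %g]; falling back to t=%g (recall %g)",
        policy.recall_low, policy.recall_high, grid[i], recalls[i],
    )
    return ThresholdResult(float(grid[i]), float(recalls[i]), False)
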