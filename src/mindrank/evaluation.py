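"""Cross-validated evaluation: ROC/AUC and model-vs-baseline comparisons.

Predictive performance is measured by the area under the ROC curve, computed
with midrank tie handling (equivalently the Mann-Whitney probability
P(score+ > score-) + P(tie)/2).  Ten-fold stratified cross-validation keeps
both classes in every fold; all fitted statistics (imputation model,
rebalancing, network weights) are derived from the training folds only, so
the held-out scores are leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .missing_data import ImputationModel, fit_bpca, impute
from .rebalance import LabeledDataset, rose_balance
from .scorer import ScorerModel, TrainConfig, forward, train, train_logistic
from .variant_features import FeatureMatrix


@dataclass
class ROCResult:
    """A thresholded ROC curve with its trapezoidal area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC with midrank ties; requires both classes present."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Full ROC curve over all distinct thresholds, plus trapezoidal AUC."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC undefined: only one class present")
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=float))
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=area)


@dataclass
class PipelineSpec:
    """What to (re)fit inside each training fold.

    ``impute_with_bpca`` fits the bPCA model on the training folds and
    applies it to both partitions; ``balance`` redraws a class-balanced
    training set by smoothed bootstrap; ``trainer`` is ``"deep"`` or
    ``"logistic"``.
    """

    train_config: TrainConfig = field(default_factory=TrainConfig)
    hidden_sizes: tuple[int, ...] = (64, 32, 16, 8)
    trainer: str = "deep"
    impute_with_bpca: bool = True
    bpca_components: int | None = None
    balance: bool = True
    balance_shrink: float = 1.0

    def fit(self, train_set: LabeledDataset, seed: int) -> tuple[ScorerModel, ImputationModel | None]:
        imp_model = None
        feats = train_set.features
        if self.impute_with_bpca and feats.mask.any():
            imp_model = fit_bpca(feats, k=self.bpca_components, seed=seed)
            feats = impute(feats, imp_model)
        d = LabeledDataset(feats, train_set.labels)
        if self.balance:
            d = rose_balance(d, shrink=self.balance_shrink, seed=seed)
        cfg = TrainConfig(**{**self.train_config.__dict__, "seed": seed})
        if self.trainer == "deep":
            model = train(d, cfg, hidden_sizes=self.hidden_sizes)
        elif self.trainer == "logistic":
            model = train_logistic(d, cfg)
        else:
            raise ValueError(f"unknown trainer {self.trainer!r}")
        return model, imp_model

    def score(
        self, model: ScorerModel, imp_model: ImputationModel | None, feats: FeatureMatrix
    ) -> np.ndarray:
        if imp_model is not None:
            feats = impute(feats, imp_model)
        elif feats.mask.any():
            raise ValueError("feature matrix has missing cells but no imputation model")
        return forward(model, feats.values)


@dataclass
class CVResult:
    """Per-fold ROC results plus pooled out-of-fold predictions."""

    fold_rocs: list[ROCResult]
    fold_assignment: np.ndarray
    pooled_scores: np.ndarray

    @property
    def fold_aucs(self) -> np.ndarray:
        return np.array([r.auc for r in self.fold_rocs])

    @property
    def mean_auc(self) -> float:
        return float(self.fold_aucs.mean())

    @property
    def std_auc(self) -> float:
        return float(self.fold_aucs.std(ddof=1)) if len(self.fold_rocs) > 1 else 0.0


def cross_validate(
    d: LabeledDataset,
    pipeline: PipelineSpec,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the full training pipeline.

    Each fold refits imputation, rebalancing and the model on the other
    k - 1 folds and scores the held-out fold.  Fold sizes differ by at most
    one; folds are disjoint and cover every row (asserted).
    """
    n = len(d)
    if n < k:
        raise ValueError(f"need at least k={k} rows, have {n}")
    y = d.labels
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.full(n, -1, dtype=int)
    pooled = np.full(n, np.nan)
    fold_rocs: list[ROCResult] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
        assignment[test_idx] = fold
        train_set = LabeledDataset(_subset(d.features, train_idx), y[train_idx])
        model, imp_model = pipeline.fit(train_set, seed=seed + fold)
        scores = pipeline.score(model, imp_model, _subset(d.features, test_idx))
        pooled[test_idx] = scores
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError(f"fold {fold} contains a single class")
        fold_rocs.append(roc(scores, y[test_idx]))
    assert (assignment >= 0).all(), "folds must cover every row"
    return CVResult(fold_rocs=fold_rocs, fold_assignment=assignment, pooled_scores=pooled)


def _subset(m: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        [m.keys[i] for i in idx], list(m.columns), m.values[idx].copy(), m.mask[idx].copy()
    )


def compare_single_scores(
    d: LabeledDataset,
    model_scores: dict[str, np.ndarray],
) -> pd.DataFrame:
    """AUC table: each trained model vs every feature column used alone.

    A raw feature column is used directly as a score over the rows where it
    is observed, with its orientation auto-flipped so the reported AUC is
    >= 0.5; a constant column is reported as AUC 0.5 with
    ``constant = True``.
    """
    y = d.labels
    rows = []
    for name, scores in model_scores.items():
        rows.append({"score": name, "auc": auc(scores, y), "flipped": False, "constant": False})
    feats = d.features
    for j, col in enumerate(feats.columns):
        obs = ~feats.mask[:, j]
        x, y_obs = feats.values[obs, j], d.labels[obs]
        if np.all(x == x[0]):
            rows.append({"score": col, "auc": 0.5, "flipped": False, "constant": True})
            continue
        a = auc(x, y_obs)
        rows.append({"score": col, "auc": max(a, 1.0 - a), "flipped": a < 0.5, "constant": False})
    return pd.DataFrame(rows)
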