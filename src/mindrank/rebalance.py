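"""Class rebalancing by smoothed-bootstrap over/under-sampling.

Training sets for variant prioritization are heavily imbalanced (a few
hundred causal variants against tens of thousands of background SNPs).  The
random-over-sampling-examples scheme redraws a balanced dataset of synthetic
rows: each output row picks a class with probability 1/2, picks a seed row of
that class uniformly, and perturbs every feature with Gaussian noise whose
standard deviation is ``shrink`` times the per-class per-feature
asymptotically optimal kernel bandwidth

    h_j = (4 / ((p + 2) m))^(1 / (p + 4)) * sigma_j

with p the number of features, m the class size and sigma_j the class
standard deviation of feature j.  ``shrink = 0`` degenerates to a plain
bootstrap (every output row duplicates an input row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variant_features import FeatureMatrix


@dataclass
class LabeledDataset:
    """A complete (post-imputation) feature matrix with binary labels."""

    features: FeatureMatrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("label count differs from row count")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        self.labels = self.labels.astype(int)

    def __len__(self) -> int:
        return len(self.labels)


def kernel_bandwidths(X: np.ndarray, shrink: float = 1.0) -> np.ndarray:
    """Per-feature smoothing bandwidths for one class's feature block."""
    m, p = X.shape
    sigma = X.std(axis=0, ddof=1) if m > 1 else np.zeros(p)
    h = (4.0 / ((p + 2.0) * m)) ** (1.0 / (p + 4.0)) * sigma
    return shrink * h


def rose_balance(
    d: LabeledDataset,
    n_out: int | None = None,
    shrink: float = 1.0,
    seed: int = 0,
    clamp01_columns: list[str] | None = None,
) -> LabeledDataset:
    """Draw a class-balanced smoothed-bootstrap dataset.

    Parameters
    ----------
    d
        Complete labeled dataset; both classes must have >= 2 rows.
    n_out
        Total output size (default: same as input).
    shrink
        Bandwidth multiplier; 0 gives exact resampling of input rows.
    seed
        Seeds the resampling; output is bitwise reproducible.
    clamp01_columns
        Columns clamped back to [0, 1] after smoothing (rule-based
        indicator/probability features whose semantics would otherwise
        break).  Default: columns whose input values all lie in [0, 1].
    """
    if shrink < 0:
        raise ValueError("shrink must be >= 0")
    if n_out is None:
        n_out = len(d)
    X, y = d.features.values, d.labels
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls} has fewer than 2 rows")

    cols = d.features.columns
    if clamp01_columns is None:
        in01 = (X >= 0).all(axis=0) & (X <= 1).all(axis=0)
        clamp01_columns = [c for c, ok in zip(cols, in01) if ok]
    clamp_idx = [cols.index(c) for c in clamp01_columns]

    rng = np.random.default_rng(seed)
    class_rows = {cls: np.flatnonzero(y == cls) for cls in (0, 1)}
    class_h = {cls: kernel_bandwidths(X[rows], shrink) for cls, rows in class_rows.items()}

    out_y = rng.integers(0, 2, size=n_out)
    out_X = np.empty((n_out, X.shape[1]))
    for cls in (0, 1):
        sel = out_y == cls
        n_cls = int(sel.sum())
        picks = rng.choice(class_rows[cls], size=n_cls, replace=True)
        noise = rng.standard_normal((n_cls, X.shape[1])) * class_h[cls]
        out_X[sel] = X[picks] + noise
    if clamp_idx:
        out_X[:, clamp_idx] = np.clip(out_X[:, clamp_idx], 0.0, 1.0)

    fm = FeatureMatrix(list(range(n_out)), list(cols), out_X)
    return LabeledDataset(fm, out_y)
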