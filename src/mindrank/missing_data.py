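"""Missing-value handling: Bayesian-PCA imputation and EMR-style fills.

The five functional predictor scores and the population allele frequency are
continuous and mutually correlated, so absent entries are imputed jointly by
Bayesian principal component analysis (bPCA): a probabilistic PCA model

    z_i = W x_i + mu + eps,   x_i ~ N(0, I_k),  eps ~ N(0, sigma^2 I)

fitted by EM over the observed cells only, with an automatic-relevance-
determination (ARD) prior on each of the k components so that superfluous
components are shrunk away.  Masked cells are replaced by their posterior
reconstruction; observed cells are never altered.

Gene-level features use simpler per-equation fill rules; the "estimate of
missing rate" (EMR) fill is the training-set missing fraction of a feature,
used directly as the fill value.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .variant_features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class ImputationModel:
    """A fitted bPCA model plus the column standardization it was trained with."""

    columns: list[str]
    k: int
    W: np.ndarray            # d x k component matrix (standardized space)
    mean: np.ndarray         # length-d mean in standardized space
    sigma2: float            # residual noise variance
    alpha: np.ndarray        # length-k ARD precisions
    col_center: np.ndarray   # per-column center (observed-cell mean)
    col_scale: np.ndarray    # per-column scale (observed-cell s.d., 1 if constant)
    tol: float = 1e-5
    max_iter: int = 500
    n_iter: int = 0
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "columns": self.columns,
            "k": self.k,
            "W": self.W.tolist(),
            "mean": self.mean.tolist(),
            "sigma2": self.sigma2,
            "alpha": self.alpha.tolist(),
            "col_center": self.col_center.tolist(),
            "col_scale": self.col_scale.tolist(),
            "tol": self.tol,
            "max_iter": self.max_iter,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ImputationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            columns=d["columns"],
            k=d["k"],
            W=np.asarray(d["W"]),
            mean=np.asarray(d["mean"]),
            sigma2=d["sigma2"],
            alpha=np.asarray(d["alpha"]),
            col_center=np.asarray(d["col_center"]),
            col_scale=np.asarray(d["col_scale"]),
            tol=d["tol"],
            max_iter=d["max_iter"],
            n_iter=d["n_iter"],
            seed=d["seed"],
        )


def _pattern_groups(mask: np.ndarray) -> dict[bytes, np.ndarray]:
    """Group row indices by missingness pattern (rows sharing a pattern share
    the same posterior covariance, so the E-step vectorizes per group)."""
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(mask):
        groups.setdefault(row.tobytes(), []).append(i)
    return {key: np.asarray(idx) for key, idx in groups.items()}


def _posterior_latents(
    Z: np.ndarray, mask: np.ndarray, W: np.ndarray, mean: np.ndarray, sigma2: float
):
    """E-step: posterior mean of x_i per row and posterior second moments
    accumulated per missingness-pattern group."""
    n, d = Z.shape
    k = W.shape[1]
    Xm = np.zeros((n, k))
    group_cov: list[tuple[np.ndarray, np.ndarray]] = []  # (rows, sigma2 * A^-1)
    for key, rows in _pattern_groups(mask).items():
        obs = ~np.frombuffer(key, dtype=bool)
        if not obs.any():
            group_cov.append((rows, np.eye(k)))  # fully missing row: prior
            continue
        Wo = W[obs]
        A = Wo.T @ Wo + sigma2 * np.eye(k)
        Ainv = np.linalg.inv(A)
        resid = Z[np.ix_(rows, obs)] - mean[obs]
        Xm[rows] = resid @ Wo @ Ainv
        group_cov.append((rows, sigma2 * Ainv))
    return Xm, group_cov


def fit_bpca(
    m: FeatureMatrix,
    k: int | None = None,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> ImputationModel:
    """Fit the bPCA imputation model on a (partially observed) feature matrix.

    Parameters
    ----------
    m
        FeatureMatrix with its missingness mask; columns are standardized
        internally on observed cells only.
    k
        Number of latent components; default ``min(#columns - 1, 4)``.
    seed
        Seeds the component initialization; the fit is deterministic given
        the seed.

    Raises
    ------
    ValueError
        If any column is entirely missing (nothing to standardize against).
    """
    values, mask = m.values, m.mask
    n, d = values.shape
    if k is None:
        k = min(d - 1, 4)
    if not 0 < k < d:
        raise ValueError(f"k must be in [1, {d - 1}], got {k}")
    all_missing = [c for j, c in enumerate(m.columns) if mask[:, j].all()]
    if all_missing:
        raise ValueError(f"columns entirely missing: {all_missing}")
    n_obs_rows = (~mask).any(axis=1).sum()
    if n_obs_rows < k + 1:
        raise ValueError(f"need at least k+1={k + 1} rows with observations, have {n_obs_rows}")

    obs = ~mask
    center = np.array([values[obs[:, j], j].mean() for j in range(d)])
    scale = np.array([values[obs[:, j], j].std(ddof=0) for j in range(d)])
    scale[scale == 0] = 1.0
    Z = (values - center) / scale
    Z[mask] = 0.0  # placeholder; masked cells never enter the likelihood

    rng = np.random.default_rng(seed)
    # init from the SVD of the zero-filled matrix, with a small seeded jitter
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    W = (Vt[:k].T * (S[:k] / np.sqrt(n))) + 0.01 * rng.standard_normal((d, k))
    mean = np.zeros(d)
    sigma2 = max(float(np.mean(Z[obs] ** 2)) * 0.5, 1e-6)
    alpha = np.ones(k)

    prev_recon = None
    n_iter = 0
    n_obs_cells = int(obs.sum())
    for n_iter in range(1, max_iter + 1):
        Xm, group_cov = _posterior_latents(Z, mask, W, mean, sigma2)

        # M-step: mean, recomputed in standardized space each pass
        pred = Xm @ W.T
        mean = np.array(
            [np.mean(Z[obs[:, j], j] - pred[obs[:, j], j]) for j in range(d)]
        )

        # M-step: W, column by column over the rows where that column is
        # observed.  All rows in a pattern group share an observed set, so a
        # group either contributes fully to column j or not at all.
        sumXX_per_group = [
            (rows, len(rows) * cov + Xm[rows].T @ Xm[rows]) for rows, cov in group_cov
        ]
        new_W = np.zeros_like(W)
        reg = sigma2 * np.diag(alpha)
        for j in range(d):
            rows_j = obs[:, j]
            Sxx = reg.copy()
            for rows, sxx in sumXX_per_group:
                if rows_j[rows[0]]:
                    Sxx += sxx
            b = Xm[rows_j].T @ (Z[rows_j, j] - mean[j])
            new_W[j] = np.linalg.solve(Sxx, b)
        W = new_W

        # M-step: sigma2 over observed cells
        pred = mean + Xm @ W.T
        resid2 = float(np.sum((Z[obs] - pred[obs]) ** 2))
        trace_term = 0.0
        for rows, cov in group_cov:
            obs_cols = obs[rows[0]]
            Wo = W[obs_cols]
            trace_term += len(rows) * float(np.trace(Wo @ cov @ Wo.T))
        sigma2 = max((resid2 + trace_term) / n_obs_cells, 1e-9)

        # ARD update: prune components with tiny loadings
        alpha = d / (np.sum(W**2, axis=0) + 1e-12)
        alpha = np.minimum(alpha, 1e12)

        recon = pred[obs]
        if prev_recon is not None:
            denom = np.linalg.norm(prev_recon) + 1e-12
            if np.linalg.norm(recon - prev_recon) / denom < tol:
                break
        prev_recon = recon

    logger.info("bPCA converged in %d iterations (sigma2=%.4g)", n_iter, sigma2)
    return ImputationModel(
        columns=list(m.columns),
        k=k,
        W=W,
        mean=mean,
        sigma2=sigma2,
        alpha=alpha,
        col_center=center,
        col_scale=scale,
        tol=tol,
        max_iter=max_iter,
        n_iter=n_iter,
        seed=seed,
    )


def impute(m: FeatureMatrix, model: ImputationModel) -> FeatureMatrix:
    """Replace masked cells by their bPCA posterior reconstruction.

    Observed cells pass through bit-for-bit; the returned matrix has an
    all-false mask.  Rows with no observed cell at all fall back to the
    model's column means.
    """
    if list(m.columns) != list(model.columns):
        raise ValueError(
            f"column mismatch: matrix has {m.columns}, model expects {model.columns}"
        )
    out = m.copy()
    if m.shape[0] == 0 or not m.mask.any():
        out.mask = np.zeros(m.values.shape, dtype=bool)
        return out

    Z = (m.values - model.col_center) / model.col_scale
    Z[m.mask] = 0.0
    Xm, _ = _posterior_latents(Z, m.mask, model.W, model.mean, model.sigma2)
    recon_std = model.mean + Xm @ model.W.T
    recon = recon_std * model.col_scale + model.col_center
    out.values[m.mask] = recon[m.mask]
    out.mask = np.zeros(m.values.shape, dtype=bool)
    return out


@dataclass
class EmrConfig:
    """Per-feature EMR fill values learned on training data.

    EMR("estimate of missing rate") for a feature is the fraction of training
    entries that were missing; that number itself is used as the fill for
    absent entries, per the fill rule the gene features specify.
    """

    emr: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.emr.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"EMR for {name} outside [0, 1]: {v}")


def compute_emr(mask: np.ndarray) -> float:
    """Missing fraction of a training column (EMR)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return 0.0
    return float(mask.mean())


def emr_fill(values: np.ndarray, mask: np.ndarray, emr_value: float) -> np.ndarray:
    """Fill masked entries of a gene-feature column with the EMR value."""
    values = np.asarray(values, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    if mask.all() and mask.size:
        warnings.warn("all entries missing; column filled entirely with EMR value")
    values[mask] = emr_value
    return values
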