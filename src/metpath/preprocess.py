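"""Normalization and missing-value imputation for intensity matrices.

Three normalizations are provided, mirroring common metabolomics
practice:

``standard``
    per-feature autoscaling (z-score, n-1 denominator);
``quantile``
    classical quantile normalization across samples: every sample's
    sorted values are replaced by the cross-sample rank means, so all
    samples end with an identical value distribution;
``medianfold``
    median-fold-change (probabilistic quotient) normalization: each
    sample is divided by the median of its fold changes against the
    per-feature median reference spectrum.

Imputation follows the expression-array k-nearest-neighbour convention:
features are points in sample space, and a missing entry is filled with
the unweighted mean of the k nearest features observed at that sample.
The pipeline order is fixed as impute -> normalize.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import MetaboliteMatrix

logger = logging.getLogger(__name__)

NORMALIZATION_METHODS = ("standard", "quantile", "medianfold")

__all__ = ["normalize", "impute_knn", "NORMALIZATION_METHODS"]


def _check_complete(matrix: MetaboliteMatrix, op: str) -> np.ndarray:
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(f"{op} requires a complete matrix; impute missing values first")
    if not np.isfinite(X).all():
        raise ValueError(f"{op}: non-finite intensities")
    return X


def _standard(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    out = np.zeros_like(X)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("standard normalization: %d zero-variance features set to 0", zero_var.sum())
    nz = ~zero_var
    out[:, nz] = (X[:, nz] - mean[nz]) / sd[nz]
    return out


def _quantile(X: np.ndarray) -> np.ndarray:
    # rank means: mean across samples of the r-th smallest value
    order = np.argsort(X, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(X, order, axis=1)
    rank_means = sorted_vals.mean(axis=0)
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        row = X[i]
        # average rank means over tied positions so ties stay tied
        ranks = pd.Series(row).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[i] = (rank_means[lo] + rank_means[hi]) / 2.0
    return out


def _medianfold(X: np.ndarray) -> np.ndarray:
    if np.any(X <= 0):
        raise ValueError("median-fold normalization requires strictly positive intensities")
    reference = np.median(X, axis=0)
    folds = X / reference
    factors = np.median(folds, axis=1)
    return X / factors[:, None]


def normalize(matrix: MetaboliteMatrix, method: str = "medianfold") -> MetaboliteMatrix:
    """Normalize a complete intensity matrix.

    Parameters
    ----------
    matrix : MetaboliteMatrix
        Complete (imputed) matrix.
    method : {'standard', 'quantile', 'medianfold'}
        Default is median-fold normalization.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    X = _check_complete(matrix, f"{method} normalization")
    if method == "standard":
        out = _standard(X)
    elif method == "quantile":
        out = _quantile(X)
    else:
        out = _medianfold(X)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return MetaboliteMatrix(values, matrix.labels)


def impute_knn(
    matrix: MetaboliteMatrix, k: int = 10, max_missing_frac: float = 0.5
) -> MetaboliteMatrix:
    """Impute missing entries by k-nearest-neighbour features.

    For each feature with missing values, distances to candidate
    neighbour features are Euclidean over the samples where both
    features are observed.  Each missing entry becomes the unweighted
    mean of the k nearest features that are observed at that sample.
    Features missing in more than ``max_missing_frac`` of samples fall
    back to the per-sample mean of observed features.

    Observed entries are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = matrix.values.to_numpy(dtype=float)
    mask = np.isnan(X)
    if not mask.any():
        return matrix.copy()
    n, p = X.shape
    miss_frac = mask.mean(axis=0)
    if not (miss_frac <= max_missing_frac).any():
        raise ValueError(
            "knn imputation requires at least one feature usable as a neighbour "
            f"(missing fraction <= {max_missing_frac})"
        )
    row_mean = np.nanmean(X, axis=1)
    out = X.copy()

    high_missing = miss_frac > max_missing_frac
    if high_missing.any():
        logger.warning(
            "impute_knn: %d features missing in >%.0f%% of samples fall back to sample means",
            int(high_missing.sum()), 100 * max_missing_frac,
        )
    for j in np.where(high_missing)[0]:
        rows = mask[:, j]
        out[rows, j] = row_mean[rows]

    knn_targets = np.where(mask.any(axis=0) & ~high_missing)[0]
    for j in knn_targets:
        candidates = np.array([g for g in range(p) if g != j and not high_missing[g]])
        if k > len(candidates):
            raise ValueError(
                f"k={k} exceeds the number of candidate neighbour features ({len(candidates)})"
            )
        # distance over mutually observed samples
        dists = np.full(len(candidates), np.inf)
        for ci, g in enumerate(candidates):
            both = ~mask[:, j] & ~mask[:, g]
            if both.any():
                diff = X[both, j] - X[both, g]
                dists[ci] = float(np.sqrt(np.sum(diff * diff)))
        for i in np.where(mask[:, j])[0]:
            usable = ~mask[i, candidates] & np.isfinite(dists)
            cand = candidates[usable]
            if len(cand) == 0:
                out[i, j] = row_mean[i]
                continue
            order = np.argsort(dists[usable], kind="stable")[:k]
            out[i, j] = float(X[i, cand[order]].mean())

    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return MetaboliteMatrix(values, matrix.labels)
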