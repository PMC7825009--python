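"""Pathway dysregulation scores (PDS) via principal curves.

For each pathway, the member-metabolite columns are z-scored against
the control samples, reduced to the leading principal components, and a
principal curve is fitted through the reduced cloud.  Each sample's
score is the arc-length distance from the start of the curve to the
sample's projection, oriented so the control median sits at the near
end, and divided by the maximum sample distance so scores lie in
[0, 1].  A larger score means a larger deviation from the controls for
that pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import fit_principal_curve
from .io import FeatureMapping, MetaboliteMatrix

logger = logging.getLogger(__name__)

__all__ = ["PDSMatrix", "compute_pds"]


@dataclass
class PDSMatrix:
    """Samples x pathways matrix of dysregulation scores in [0, 1]."""

    scores: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.scores.index]

    @property
    def pathway_ids(self) -> list[str]:
        return [str(p) for p in self.scores.columns]


def _reduce_dims(Z: np.ndarray, var_frac: float, max_dims: int) -> np.ndarray:
    """Project on the fewest PCs explaining >= var_frac of variance (capped)."""
    Zc = Z - Z.mean(axis=0)
    _, s, vt = np.linalg.svd(Zc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        return Zc[:, :1]
    frac = np.cumsum(var) / total
    n_keep = int(np.searchsorted(frac, var_frac) + 1)
    n_keep = min(n_keep, max_dims)
    return Zc @ vt[:n_keep].T


def _pathway_distances(scores: np.ndarray, seed: int) -> np.ndarray:
    """Arc-length distance from the curve start for each sample."""
    if scores.shape[1] == 1:
        # the principal curve of 1-D data is the line itself
        x = scores[:, 0]
        return x - x.min()
    curve = fit_principal_curve(scores)
    lam, _ = curve.project(scores)
    return lam


def compute_pds(
    matrix: MetaboliteMatrix,
    mapping: FeatureMapping,
    controls: set[str] | list[str],
    var_frac: float = 0.85,
    max_dims: int = 5,
    seed: int = 0,
) -> PDSMatrix:
    """Compute the samples x pathways dysregulation-score matrix.

    Parameters
    ----------
    matrix : MetaboliteMatrix
        Imputed/normalized intensity matrix.
    mapping : FeatureMapping
        Pathway cover as produced by :func:`metpath.io.map_features`.
    controls : set of sample IDs
        Normal samples defining the reference: member metabolites are
        z-scored with the control mean/sd, and the curve is oriented so
        the control median projects near arc length 0.
    var_frac : float
        Fraction of variance the retained principal components must
        explain before curve fitting (capped at ``max_dims`` and at
        n-1 / p).
    seed : int
        Reserved for stochastic smoother details; fitting is
        deterministic with the default smoother.
    """
    controls = set(controls)
    if not controls:
        raise ValueError("controls must be non-empty")
    missing = controls - set(matrix.sample_ids)
    if missing:
        raise ValueError(f"controls not in matrix: {sorted(missing)}")
    X = matrix.values
    if X.isna().any().any():
        raise ValueError("PDS requires a complete matrix; impute first")
    ctrl_mask = np.array([s in controls for s in matrix.sample_ids])
    n = matrix.n_samples

    cols: dict[str, np.ndarray] = {}
    for pid, feats in mapping.pathway_cover.items():
        sub = X[feats].to_numpy(dtype=float)
        if np.allclose(sub.var(axis=0), 0):
            logger.warning("pathway %s skipped: member columns have zero variance", pid)
            continue
        mu = sub[ctrl_mask].mean(axis=0)
        sd = sub[ctrl_mask].std(axis=0, ddof=1)
        zero_sd = sd == 0
        if zero_sd.any():
            logger.warning(
                "pathway %s: %d metabolites with zero control sd centered only",
                pid, int(zero_sd.sum()),
            )
        sd = np.where(zero_sd, 1.0, sd)
        Z = (sub - mu) / sd
        cap = max(1, min(n - 1, Z.shape[1], max_dims))
        reduced = _reduce_dims(Z, var_frac, cap)
        if np.allclose(reduced.var(axis=0), 0):
            logger.warning("pathway %s skipped: degenerate after reduction", pid)
            continue
        dist = _pathway_distances(reduced, seed)
        total = dist.max()
        if total <= 0:
            logger.warning("pathway %s skipped: all samples project to one point", pid)
            continue
        # orient: control median at the near end of the curve
        if np.median(dist[ctrl_mask]) > total / 2:
            dist = total - dist
        scores = dist / dist.max()
        cols[pid] = scores
    if not cols:
        raise ValueError("no pathway produced a dysregulation score")
    frame = pd.DataFrame(cols, index=X.index)
    return PDSMatrix(frame)
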