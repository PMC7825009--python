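"""Unsupervised embeddings and source-of-variation (SOV) screening.

PCA and t-SNE give 2-D views of the sample cloud.  SOV screens clinical
covariates for confounding: every metabolite is regressed on all listed
factors, a Type-II ANOVA F statistic is computed per factor, and the
per-metabolite F values are averaged into one score per factor.  The
residual ("Error") row has F = 1 by definition; a factor whose mean F
exceeds 1 explains more variance per degree of freedom than noise and
is flagged as a confounder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .io import MetaboliteMatrix

__all__ = ["Embedding", "pca_embed", "tsne_embed", "sov_analysis"]


@dataclass
class Embedding:
    """2-D sample embedding with optional per-component explained variance."""

    sample_ids: list[str]
    coords: np.ndarray
    method: str
    explained_variance: tuple[float, ...] | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{self.method}_1", f"{self.method}_2"][: self.coords.shape[1]]
        return pd.DataFrame(self.coords, index=self.sample_ids, columns=cols)


def pca_embed(matrix: MetaboliteMatrix, n_components: int = 2) -> Embedding:
    """Project samples on the top principal components of the centered matrix."""
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete matrix")
    if matrix.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_features)={min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return Embedding(
        matrix.sample_ids,
        coords,
        "pca",
        tuple(float(v) for v in pca.explained_variance_ratio_),
    )


def tsne_embed(
    matrix: MetaboliteMatrix, perplexity: float = 30.0, seed: int = 0
) -> Embedding:
    """2-D t-SNE embedding; identical seed and input give identical output."""
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("t-SNE requires a complete matrix")
    n = X.shape[0]
    if perplexity >= (n - 1) / 3:
        raise ValueError(
            f"perplexity={perplexity} too large for n={n}; needs perplexity < (n-1)/3"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        n_jobs=1,
    )
    coords = tsne.fit_transform(X)
    return Embedding(matrix.sample_ids, np.asarray(coords, dtype=float), "tsne")


def sov_analysis(
    matrix: MetaboliteMatrix,
    metadata: pd.DataFrame,
    factors: list[str],
) -> pd.DataFrame:
    """Source-of-variation table: mean Type-II ANOVA F per clinical factor.

    Returns a frame with columns ``factor``, ``F_score``,
    ``is_confounder`` and a final ``Error`` row with F = 1.  Categorical
    (non-numeric) factors enter the per-metabolite linear model as
    treatment-coded terms; numeric covariates enter untransformed.
    """
    for f in factors:
        if f not in metadata.columns:
            raise ValueError(f"factor {f!r} not in metadata")
    meta = metadata.reindex(matrix.values.index)
    terms = []
    for f in factors:
        col = meta[f]
        if pd.api.types.is_numeric_dtype(col):
            terms.append(f"Q('{f}')")
        else:
            if col.nunique(dropna=True) < 2:
                raise ValueError(f"factor {f!r} has a single level; confounded with intercept")
            terms.append(f"C(Q('{f}'))")
    rhs = " + ".join(terms)
    term_order = list(terms)  # align ANOVA rows back to the factor list

    f_sums = np.zeros(len(factors))
    n_used = 0
    data = meta.copy()
    for feat in matrix.values.columns:
        data["_y"] = matrix.values[feat].to_numpy(dtype=float)
        model = smf.ols(f"_y ~ {rhs}", data=data).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        fvals = anova["F"].reindex(term_order)
        f_sums += fvals.to_numpy(dtype=float)
        n_used += 1
    mean_f = f_sums / n_used

    rows = [
        {"factor": f, "F_score": float(v), "is_confounder": bool(v > 1.0)}
        for f, v in zip(factors, mean_f)
    ]
    rows.append({"factor": "Error", "F_score": 1.0, "is_confounder": False})
    return pd.DataFrame(rows)
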