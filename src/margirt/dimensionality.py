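"""Dimensionality screening: explained covariance and parallel analysis.

The first-stage question is how large the first principal component of the
polychoric correlation matrix is relative to the rest; the second stage is
Horn-style parallel analysis, comparing observed eigenvalues against
eigenvalues of null data built by independently permuting each item's
column (which preserves every ordinal margin exactly and destroys all
inter-item association).  Both are run on pretreatment responses and on
item change scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .polychoric import polychoric_matrix
from .types import ResponseMatrix


@dataclass
class VarianceDecomposition:
    eigenvalues: np.ndarray
    pct_explained: np.ndarray
    ratio_first_to_second: float

    def scree_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(1, self.eigenvalues.size + 1),
            "eigenvalue": self.eigenvalues,
            "pct_explained": self.pct_explained,
        })


@dataclass
class ParallelAnalysisResult:
    n_factors: int
    observed_eigenvalues: np.ndarray
    null_thresholds: np.ndarray
    criterion: str
    n_random: int


def explained_covariance(R: np.ndarray) -> VarianceDecomposition:
    """Eigendecomposition of a correlation matrix as % covariance explained."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    ev = np.sort(np.linalg.eigvalsh(R))[::-1]
    pct = 100.0 * ev / ev.sum()
    return VarianceDecomposition(
        eigenvalues=ev,
        pct_explained=pct,
        ratio_first_to_second=float(pct[0] / pct[1]),
    )


def change_scores(pre: ResponseMatrix, post: ResponseMatrix) -> pd.DataFrame:
    """Posttreatment minus pretreatment item scores for completers."""
    shared = post.data.index.intersection(pre.data.index)
    if shared.empty:
        raise ValueError("no persons present in both waves")
    if list(pre.data.columns) != list(post.data.columns):
        raise ValueError("pre and post must share item columns")
    return post.data.loc[shared] - pre.data.loc[shared]


def _permuted_columns(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = rng.permutation(X[:, j])
    return out


def _polychoric_eigs(X: np.ndarray, items) -> np.ndarray:
    mat = ResponseMatrix(
        pd.DataFrame(X, columns=[it.item_id for it in items]), list(items)
    )
    R = polychoric_matrix(mat).matrix()
    return np.sort(np.linalg.eigvalsh(R))[::-1]


def _pearson_eigs(X: np.ndarray) -> np.ndarray:
    R = pd.DataFrame(X).corr(min_periods=2).to_numpy()
    return np.sort(np.linalg.eigvalsh(R))[::-1]


def parallel_analysis(
    data: ResponseMatrix | pd.DataFrame,
    n_random: int = 100,
    criterion: str = "mean",
    seed: int = 0,
    method: str = "polychoric",
) -> ParallelAnalysisResult:
    """Suggested number of factors by column-permutation parallel analysis.

    ``method='polychoric'`` (for raw ordinal responses) estimates a
    polychoric matrix per replicate; ``method='pearson'`` treats the
    columns as numeric — the convention used for change scores, whose up
    to 2K-1 levels are differences, not ordinal scales of the original
    kind.  The suggested count is the number of leading observed
    eigenvalues strictly above the null criterion (mean or 95th
    percentile of the replicate eigenvalues, component-wise).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if criterion not in ("mean", "p95"):
        raise ValueError("criterion must be 'mean' or 'p95'")
    if isinstance(data, ResponseMatrix):
        X = data.values()
        items = data.items
    else:
        X = np.asarray(data, dtype=float)
        items = None
        if method == "polychoric":
            raise ValueError("polychoric parallel analysis needs a ResponseMatrix")
    n, p = X.shape
    if n < p:
        warnings.warn("fewer persons than items; parallel analysis proceeds")

    eig = (lambda M: _polychoric_eigs(M, items)) if method == "polychoric" else _pearson_eigs
    observed = eig(X)
    rng = np.random.default_rng(seed)
    null_eigs = np.empty((n_random, p))
    for r in range(n_random):
        null_eigs[r] = eig(_permuted_columns(X, rng))
    thresholds = (
        null_eigs.mean(axis=0) if criterion == "mean"
        else np.percentile(null_eigs, 95, axis=0)
    )
    above = observed > thresholds
    n_factors = int(np.argmin(above)) if not above.all() else p
    return ParallelAnalysisResult(
        n_factors=n_factors,
        observed_eigenvalues=observed,
        null_thresholds=thresholds,
        criterion=criterion,
        n_random=n_random,
    )
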