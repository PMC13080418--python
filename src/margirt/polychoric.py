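"""Polychoric correlations by two-step maximum likelihood.

Thresholds come from the univariate margins (inverse-normal of cumulative
proportions); the correlation then maximizes the bivariate-normal
rectangle-probability likelihood of the pairwise-complete contingency
table.  Sparse top categories are merged downward before estimation, the
convention applied to inventory items whose extreme category is almost
never endorsed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtri

from ._bvn import make_rectangle_prob_fn, rectangle_probs
from .types import PolychoricResult, ResponseMatrix

RHO_BOUND = 0.999
_PROB_FLOOR = 1e-300


def truncate_sparse_categories(x: np.ndarray, min_count: int = 3) -> np.ndarray:
    """Merge a sparse top category into the one below, repeatedly.

    While the highest observed category holds fewer than ``min_count``
    non-missing observations, its values are recoded one step down.
    Categories are then renumbered contiguously from 0.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    x = np.asarray(x, dtype=float).copy()
    obs = x[~np.isnan(x)]
    if obs.size == 0:
        raise ValueError("all-missing vector")
    while True:
        obs = x[~np.isnan(x)]
        levels = np.unique(obs)
        if levels.size <= 2:
            break
        top = levels[-1]
        if np.sum(obs == top) >= min_count:
            break
        x[x == top] = levels[-2]
    # renumber contiguously
    levels = np.unique(x[~np.isnan(x)])
    lookup = {v: i for i, v in enumerate(levels)}
    out = x.copy()
    mask = ~np.isnan(x)
    out[mask] = [lookup[v] for v in x[mask]]
    return out


def estimate_thresholds(x: np.ndarray) -> np.ndarray:
    """Normal-quantile thresholds from the cumulative category proportions."""
    x = np.asarray(x, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size == 0:
        raise ValueError("all-missing vector")
    levels, counts = np.unique(obs, return_counts=True)
    if levels.size < 2:
        raise ValueError("threshold undefined: single observed category")
    cum = np.cumsum(counts)[:-1] / obs.size
    return ndtri(cum)


def _pair_table(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contingency table on pairwise-complete cases, with observed levels."""
    mask = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[mask], y[mask]
    if xs.size == 0:
        raise ValueError("empty pairwise-complete set")
    lx, ix = np.unique(xs, return_inverse=True)
    ly, iy = np.unique(ys, return_inverse=True)
    table = np.zeros((lx.size, ly.size))
    np.add.at(table, (ix, iy), 1.0)
    return table, lx, ly


def _table_thresholds(table: np.ndarray, axis: int) -> np.ndarray:
    margin = table.sum(axis=1 - axis)
    cum = np.cumsum(margin)[:-1] / margin.sum()
    return ndtri(cum)


def _neg_loglik(rho: float, table: np.ndarray, tau_x: np.ndarray, tau_y: np.ndarray) -> float:
    probs = rectangle_probs(tau_x, tau_y, rho)
    return -float(np.sum(table * np.log(np.maximum(probs, _PROB_FLOOR))))


def polychoric_from_table(table: np.ndarray) -> float:
    """Two-step ML polychoric correlation from a contingency table."""
    table = np.asarray(table, dtype=float)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 categories on each margin")
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    table = table[rows][:, cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate table: fewer than 2 observed categories")
    tau_x = _table_thresholds(table, axis=0)
    tau_y = _table_thresholds(table, axis=1)
    prob_fn = make_rectangle_prob_fn(tau_x, tau_y)

    def nll(rho: float) -> float:
        return -float(np.sum(table * np.log(np.maximum(prob_fn(rho), _PROB_FLOOR))))

    res = minimize_scalar(
        nll,
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def polychoric_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Polychoric correlation of two ordinal vectors (pairwise complete)."""
    table, _, _ = _pair_table(np.asarray(x, float), np.asarray(y, float))
    return polychoric_from_table(table)


def _nearest_psd(R: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at a small floor and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    vals = np.maximum(vals, eig_floor)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def polychoric_matrix(
    data: ResponseMatrix,
    min_count: int = 3,
    psd_tol: float = 1e-6,
) -> PolychoricResult:
    """Pairwise-complete polychoric correlation matrix with thresholds.

    Each item is first passed through :func:`truncate_sparse_categories`.
    If the assembled matrix has an eigenvalue below ``psd_tol`` it is
    repaired by eigenvalue clipping and rescaled to unit diagonal
    (``smoothed`` is set on the result).
    """
    ids = data.item_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 items")
    X = data.values()
    cols = {}
    thresholds = {}
    for j, item_id in enumerate(ids):
        col = truncate_sparse_categories(X[:, j], min_count=min_count)
        n_levels = np.unique(col[~np.isnan(col)]).size
        if n_levels < 2:
            raise ValueError(f"item {item_id}: fewer than 2 observed categories")
        cols[item_id] = col
        thresholds[item_id] = estimate_thresholds(col)

    p = len(ids)
    R = np.eye(p)
    N = np.zeros((p, p), dtype=int)
    warn: list[str] = []
    for i in range(p):
        N[i, i] = int(np.sum(~np.isnan(cols[ids[i]])))
        for j in range(i + 1, p):
            xi, xj = cols[ids[i]], cols[ids[j]]
            mask = ~(np.isnan(xi) | np.isnan(xj))
            N[i, j] = N[j, i] = int(mask.sum())
            try:
                rho = polychoric_pair(xi, xj)
            except ValueError as exc:
                warn.append(f"{ids[i]}-{ids[j]}: {exc}")
                rho = 0.0
            R[i, j] = R[j, i] = rho

    smoothed = False
    if np.linalg.eigvalsh(R).min() < psd_tol:
        R = _nearest_psd(R, eig_floor=psd_tol)
        smoothed = True
        warnings.warn("polychoric matrix was not positive semi-definite; smoothed")

    return PolychoricResult(
        thresholds=thresholds,
        corr=pd.DataFrame(R, index=ids, columns=ids),
        pair_n=pd.DataFrame(N, index=ids, columns=ids),
        smoothed=smoothed,
        warnings=warn,
    )
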