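"""Exploratory bifactor analysis: minres extraction and bi-geomin rotation.

Extraction is ordinary least squares on the off-diagonal of the polychoric
correlation matrix (minres).  Rotation minimizes the bifactor-geomin
criterion by gradient projection: the geomin complexity penalty is applied
to the specific columns only, leaving one column free to absorb the dense
general dimension.  Rotation is oblique by default and restarted from
random orthonormal positions because geomin-type criteria have local
minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .types import BifactorSolution, Inventory, ItemSpec

_COMMUNALITY_CAP = 0.995


# ---------------------------------------------------------------------------
# extraction

def _loadings_given_uniqueness(R: np.ndarray, psi: np.ndarray, k: int):
    Rr = R.copy()
    np.fill_diagonal(Rr, 1.0 - psi)
    vals, vecs = np.linalg.eigh(Rr)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.maximum(vals[order], 0.0)
    return vecs[:, order] * np.sqrt(vals_k)[None, :]


def extract_factors(R: np.ndarray, k: int, max_iter: int = 2000,
                    tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Minimum-residual extraction of ``k`` factors.

    Minimizes the sum of squared off-diagonal residuals of
    ``R - L L'`` over the uniquenesses, with the loadings profiled out via
    the eigendecomposition of the reduced matrix.  Returns
    ``(loadings, uniqueness, converged)``; communalities are capped at
    0.995 (Heywood protection) with a warning.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= p:
        raise ValueError("k must be smaller than the number of items")
    mask = ~np.eye(p, dtype=bool)

    def objective(psi):
        L = _loadings_given_uniqueness(R, psi, k)
        resid = (R - L @ L.T)[mask]
        return float(resid @ resid)

    # start from squared multiple correlations
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 1.0 - _COMMUNALITY_CAP, 1.0)
    res = minimize(
        objective, psi0, method="L-BFGS-B",
        bounds=[(1.0 - _COMMUNALITY_CAP, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    psi = res.x
    if np.any(psi <= 1.0 - _COMMUNALITY_CAP + 1e-12):
        warnings.warn("Heywood case: communality capped at 0.995")
    L = _loadings_given_uniqueness(R, psi, k)
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"minres did not converge: {res.message}")
    return L, psi, converged


# ---------------------------------------------------------------------------
# bi-geomin rotation by gradient projection

def _bigeomin_criterion(L: np.ndarray, epsilon: float):
    """Value and gradient of geomin complexity on columns 1..k-1."""
    Ls = L[:, 1:]
    m = Ls.shape[1]
    L2 = Ls * Ls + epsilon
    logs = np.log(L2)
    q = np.exp(logs.mean(axis=1))
    f = float(q.sum())
    G = np.zeros_like(L)
    G[:, 1:] = (2.0 / m) * q[:, None] * Ls / L2
    return f, G


def _random_orthonormal(k: int, rng: np.random.Generator) -> np.ndarray:
    Q, Rm = np.linalg.qr(rng.standard_normal((k, k)))
    return Q * np.sign(np.diag(Rm))[None, :]


def _gpf_oblique(A: np.ndarray, T0: np.ndarray, epsilon: float,
                 max_iter: int = 1000, tol: float = 1e-6):
    """Oblique gradient-projection rotation for the bi-geomin criterion.

    Follows the standard GPA scheme: loadings L = A (T')^{-1}, gradient
    pulled back to T, projected onto the unit-column-norm manifold, with
    step halving; the criterion is non-increasing across iterations.
    """
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _bigeomin_criterion(L, epsilon)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)[None, :]
        s = np.sqrt((Gp * Gp).sum())
        if s < tol:
            converged = True
            break
        al *= 2.0
        improved = False
        for _half in range(40):
            X = T - al * Gp
            X = X / np.sqrt((X * X).sum(axis=0))[None, :]
            Ti_t = np.linalg.inv(X)
            Lt = A @ Ti_t.T
            ft, Gq_t = _bigeomin_criterion(Lt, epsilon)
            if ft < f - 0.5 * s * s * al:
                improved = True
                break
            al /= 2.0
        if not improved:
            # step collapsed: no descent direction left at this accuracy
            converged = s < 1e-4
            break
        T, Ti, L, f, Gq = X, Ti_t, Lt, ft, Gq_t
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi, f, converged


def rotate_bigeomin(
    L: np.ndarray,
    epsilon: float = 0.01,
    n_starts: int = 30,
    seed: int = 0,
    oblique: bool = True,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Best-of-``n_starts`` bi-geomin rotation of an unrotated pattern.

    Returns ``(rotated loadings, factor correlation, criterion value,
    converged)``.  The first start is the identity; the rest are random
    orthonormal matrices from ``seed``.  Only the oblique flavour is
    implemented; ``oblique=False`` raises.
    """
    A = np.asarray(L, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("need an items x k loading matrix with k >= 2")
    if not oblique:
        raise NotImplementedError("only oblique bi-geomin is provided")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    k = A.shape[1]
    best = None
    any_converged = False
    for s in range(n_starts):
        T0 = np.eye(k) if s == 0 else _random_orthonormal(k, rng)
        Lr, Phi, f, conv = _gpf_oblique(A, T0, epsilon, max_iter=max_iter)
        any_converged = any_converged or conv
        if best is None or f < best[2]:
            best = (Lr, Phi, f, conv)
    if not any_converged:
        warnings.warn("no rotation start converged; best iterate returned")
    return best


# ---------------------------------------------------------------------------
# alignment and summaries

def align_general_factor(
    loadings: np.ndarray,
    factor_corr: np.ndarray,
    dense_threshold: float = 0.20,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Move the densest column first and fix signs.

    The general factor is identified as the column with the largest count
    of absolute loadings >= ``dense_threshold`` (ties broken by larger sum
    of squares, with a warning); it is placed in column 0 and sign-flipped
    so its mean loading is positive.  Every specific column is also
    sign-flipped to a positive loading sum, a reporting convention that
    leaves the model invariant.  Returns the aligned loadings, aligned
    factor correlation and the original index of the general column.
    """
    L = np.asarray(loadings, dtype=float).copy()
    Phi = np.asarray(factor_corr, dtype=float).copy()
    counts = (np.abs(L) >= dense_threshold).sum(axis=0)
    ssq = (L * L).sum(axis=0)
    top = counts.max()
    candidates = np.flatnonzero(counts == top)
    if candidates.size > 1:
        warnings.warn("tie between candidate general columns; "
                      "using largest sum of squared loadings")
        g = candidates[np.argmax(ssq[candidates])]
    else:
        g = int(candidates[0])
    order = [g] + [j for j in range(L.shape[1]) if j != g]
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    signs = np.where(L.sum(axis=0) >= 0, 1.0, -1.0)
    L = L * signs[None, :]
    Phi = Phi * np.outer(signs, signs)
    return L, Phi, g


def order_specifics_by_inventory(
    solution: BifactorSolution, specs: list[ItemSpec]
) -> BifactorSolution:
    """Reorder specific columns by their dominant inventory, for reporting."""
    inv_rank = {Inventory.CORE_OM: 0, Inventory.PHQ9: 1,
                Inventory.OASIS: 2, Inventory.AUDIT_C: 3}
    by_id = {s.item_id: s for s in specs}
    L = solution.loadings
    keys = []
    for j in range(1, solution.k):
        col = L.iloc[:, j].abs()
        weights: dict = {}
        for iid, val in col.items():
            inv = by_id[iid].inventory
            weights[inv] = weights.get(inv, 0.0) + val * val
        dom = max(weights, key=weights.get)
        keys.append((inv_rank[dom], -col.pow(2).sum(), j))
    order = [0] + [j for *_key, j in sorted(keys)]
    newL = L.iloc[:, order]
    newL.columns = ["general"] + [f"specific_{i}" for i in range(1, solution.k)]
    return BifactorSolution(
        loadings=newL,
        factor_corr=solution.factor_corr[np.ix_(order, order)],
        uniqueness=solution.uniqueness,
        rotation_criterion_value=solution.rotation_criterion_value,
        n_starts=solution.n_starts,
        converged=solution.converged,
        excluded_items=list(solution.excluded_items),
    )


def fit_bifactor(
    R: pd.DataFrame,
    k: int,
    epsilon: float = 0.01,
    n_starts: int = 30,
    seed: int = 0,
    dense_threshold: float = 0.20,
) -> BifactorSolution:
    """Extraction + bi-geomin rotation + general-factor alignment."""
    ids = list(R.index)
    L0, psi, conv_ex = extract_factors(R.to_numpy(), k)
    Lr, Phi, f, conv_rot = rotate_bigeomin(
        L0, epsilon=epsilon, n_starts=n_starts, seed=seed
    )
    La, Phia, _ = align_general_factor(Lr, Phi, dense_threshold)
    cols = ["general"] + [f"specific_{i}" for i in range(1, k)]
    return BifactorSolution(
        loadings=pd.DataFrame(La, index=ids, columns=cols),
        factor_corr=Phia,
        uniqueness=pd.Series(psi, index=ids),
        rotation_criterion_value=f,
        n_starts=n_starts,
        converged=bool(conv_ex and conv_rot),
    )


def stability_screen(
    solution: BifactorSolution,
    loading_bound: float = 1.5,
    communality_bound: float = 0.97,
) -> list[str]:
    """Items with pathological estimates, candidates for exclusion.

    Flags items whose largest absolute rotated loading exceeds
    ``loading_bound`` or whose communality sits at/above
    ``communality_bound`` (capped Heywood cases), mirroring the practice
    of dropping a screening item whose estimates are extreme and unstable.
    """
    flagged = []
    h2 = 1.0 - solution.uniqueness
    for iid in solution.loadings.index:
        big = solution.loadings.loc[iid].abs().max() > loading_bound
        heywood = h2.loc[iid] >= communality_bound
        if big or heywood:
            flagged.append(iid)
    return flagged


def general_factor_covariance_share(solution: BifactorSolution) -> float:
    """% of factor-explained covariance attributable to the general factor.

    Oblique columns are orthogonalized by the Cholesky factor of the
    factor correlation with the general factor ordered first, so the
    general column keeps its own variance plus what it shares with the
    specifics — consistent with the marginal (projective) treatment.
    """
    L = solution.loadings.to_numpy()
    Phi = solution.factor_corr
    C = np.linalg.cholesky(Phi)
    Lo = L @ C
    total = float((Lo * Lo).sum())
    if total == 0:
        raise ValueError("all-zero loading matrix")
    return 100.0 * float((Lo[:, 0] ** 2).sum()) / total
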