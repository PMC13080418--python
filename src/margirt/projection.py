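"""Isolating the general factor: marginal (projective) graded-response items.

A bifactor solution describes each item by a multidimensional normal-ogive
model on the underlying-variable metric,

    P(X >= c | theta) = Phi((lambda' theta - tau_c) / sqrt(psi)).

Conditioning on the general factor t, the specific factors are normal with
mean Phi_21 t and covariance Phi_22 - Phi_21 Phi_12; because the ogive link
is a normal CDF, integrating them out is exact and yields another ogive
item in t alone:

    P(X >= c | t) = Phi((alpha t - tau_c) / sigma),
    alpha   = lambda_g + lambda_s' Phi_21,
    sigma^2 = psi + lambda_s' (Phi_22 - Phi_21 Phi_12) lambda_s,

reported as discrimination a* = alpha/sigma and boundary locations
b*_c = tau_c / alpha.  When specific loadings are nonzero and factors
orthogonal, sigma > sqrt(psi), so marginal discriminations shrink relative
to the conditional ones — the price of isolating the general factor.
"""

from __future__ import annotations

import numpy as np

from .types import BifactorSolution, MarginalGRMItem, MGRMItem, PolychoricResult

#: logistic/ogive scaling constant
D_CONST = 1.702

_COMMUNALITY_CAP = 0.995


def fa_to_mgrm(
    solution: BifactorSolution, poly: PolychoricResult
) -> list[MGRMItem]:
    """Convert a factor solution plus thresholds to normal-ogive items.

    Items whose fitted uniqueness is non-positive even after the
    communality cap are dropped (none should survive extraction, but the
    contract is defensive).
    """
    items: list[MGRMItem] = []
    for item_id in solution.loadings.index:
        lam = solution.loadings.loc[item_id].to_numpy(dtype=float)
        psi = float(solution.uniqueness.loc[item_id])
        if psi <= 0:
            psi = 1.0 - _COMMUNALITY_CAP
        tau = np.asarray(poly.thresholds[item_id], dtype=float)
        items.append(MGRMItem(item_id=item_id, loading_vec=lam,
                              thresholds=tau, uniqueness=psi))
    return items


def marginal_slope_scale(
    loading_vec: np.ndarray,
    uniqueness: float,
    factor_corr: np.ndarray,
    general_index: int = 0,
) -> tuple[float, float]:
    """(alpha, sigma) of the exact ogive marginal over the specific factors."""
    lam = np.asarray(loading_vec, dtype=float)
    phi = np.asarray(factor_corr, dtype=float)
    k = lam.size
    if phi.shape != (k, k):
        raise ValueError("factor correlation shape mismatch")
    g = general_index
    s = [j for j in range(k) if j != g]
    lam_g = lam[g]
    if not s:
        return float(lam_g), float(np.sqrt(uniqueness))
    lam_s = lam[s]
    phi_21 = phi[np.ix_(s, [g])][:, 0]
    phi_22 = phi[np.ix_(s, s)]
    cond_cov = phi_22 - np.outer(phi_21, phi_21)
    alpha = lam_g + lam_s @ phi_21
    sigma2 = uniqueness + lam_s @ cond_cov @ lam_s
    if sigma2 <= 0:
        raise ValueError("non-positive marginal variance; factor_corr not PD?")
    return float(alpha), float(np.sqrt(sigma2))


def marginalize(
    item: MGRMItem, factor_corr: np.ndarray, general_index: int = 0
) -> MarginalGRMItem:
    """Exact marginal general-factor GRM parameters of one item."""
    alpha, sigma = marginal_slope_scale(
        item.loading_vec, item.uniqueness, factor_corr, general_index
    )
    if alpha < 0:
        # sign of the general factor is a convention; alignment should have
        # fixed it, but an individually reversed item keeps |alpha| with
        # reversed thresholds
        alpha, tau = -alpha, -item.thresholds[::-1]
    else:
        tau = item.thresholds
    if alpha == 0.0:
        return MarginalGRMItem(item_id=item.item_id, a=0.0,
                               b=np.array([]), flagged=len(tau) > 0)
    return MarginalGRMItem(item_id=item.item_id, a=alpha / sigma,
                           b=np.asarray(tau, float) / alpha)


def marginalize_solution(
    solution: BifactorSolution, poly: PolychoricResult, general_index: int = 0
) -> list[MarginalGRMItem]:
    return [
        marginalize(it, solution.factor_corr, general_index)
        for it in fa_to_mgrm(solution, poly)
    ]


def to_logistic(item: MarginalGRMItem, D: float = D_CONST) -> MarginalGRMItem:
    """Ogive -> logistic metric: a/D with the same boundary locations."""
    if item.metric != "ogive":
        raise ValueError("expected an ogive-metric item")
    return MarginalGRMItem(item_id=item.item_id, a=item.a / D, b=item.b.copy(),
                           metric="logistic", flagged=item.flagged)


def to_ogive(item: MarginalGRMItem, D: float = D_CONST) -> MarginalGRMItem:
    if item.metric != "logistic":
        raise ValueError("expected a logistic-metric item")
    return MarginalGRMItem(item_id=item.item_id, a=item.a * D, b=item.b.copy(),
                           metric="ogive", flagged=item.flagged)
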