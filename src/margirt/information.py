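"""Fisher information and StdEM for marginal graded-response items.

All statistics concern the general factor t after marginalization.  For a
graded item with boundary curves P_c(t) (ogive: Phi(a(t - b_c)); logistic:
expit(D a (t - b_c))), the category probabilities are pi_c = P_c - P_{c+1}
and the Fisher information of the observed category is

    I(t) = sum_c (d pi_c / dt)^2 / pi_c.

Test information adds item curves; total information is the area under a
curve over a finite trait range; averaged total information divides by the
number of items, the simplest way to compare inventories of different
lengths; StdEM(t) = 1 / sqrt(I(t)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .types import MarginalGRMItem

D_CONST = 1.702

#: default integration range for total information
DEFAULT_BOUNDS = (-6.0, 6.0)
DEFAULT_NODES = 101

#: default display grid (approximately the inner 95% of a standard normal,
#: with margin)
DEFAULT_GRID = np.linspace(-4.0, 4.0, 201)

_FLOOR = 1e-300


def _norm_pdf(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)


def _stable_cells(z: np.ndarray, metric: str) -> np.ndarray:
    """Category probabilities from boundary arguments, cancellation-free.

    ``z`` holds a(theta - b_c) per row, extended here with +-inf
    sentinels; cells with both boundaries in the upper tail are computed
    on the survival side so they never cancel to zero while their
    derivative is still finite.
    """
    n = z.shape[0]
    zext = np.concatenate(
        [np.full((n, 1), np.inf), z, np.full((n, 1), -np.inf)], axis=1
    )
    link = ndtr if metric == "ogive" else (lambda u: expit(D_CONST * u))
    F = link(zext)
    G = link(-zext)
    lo, hi = zext[:, 1:], zext[:, :-1]
    upper_tail = np.nan_to_num(lo, posinf=1.0, neginf=-1.0) + np.nan_to_num(
        hi, posinf=1.0, neginf=-1.0
    ) > 0
    cells = np.where(upper_tail, G[:, 1:] - G[:, :-1], F[:, :-1] - F[:, 1:])
    return np.clip(cells, 0.0, 1.0)


def category_probabilities(item: MarginalGRMItem, theta) -> np.ndarray:
    """pi_c(theta), shape (len(theta), n_categories)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if item.a == 0.0:
        # flat item: probabilities do not depend on theta; boundary info lost
        # in marginalization is represented by a single sure category
        return np.ones((theta.size, 1))
    z = item.a * (theta[:, None] - item.b[None, :])
    return _stable_cells(z, item.metric)


def point_item_information(item: MarginalGRMItem, theta) -> np.ndarray:
    """Fisher information about t from one item, vectorized over theta."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if item.a == 0.0:
        return np.zeros(theta.size)
    z = item.a * (theta[:, None] - item.b[None, :])
    if item.metric == "ogive":
        dP = item.a * _norm_pdf(z)
    else:
        p = expit(D_CONST * z)
        dP = D_CONST * item.a * p * (1.0 - p)
    zero = np.zeros((theta.size, 1))
    dcum = np.concatenate([zero, dP, zero], axis=1)
    dpi = -np.diff(dcum, axis=1)
    pi = _stable_cells(z, item.metric)
    # where a cell's mass underflows, its true contribution is ~|z| pdf -> 0
    contrib = np.where(pi > 1e-160, dpi * dpi / np.maximum(pi, _FLOOR), 0.0)
    return np.sum(contrib, axis=1)


def point_test_information(items: list[MarginalGRMItem], theta) -> np.ndarray:
    if not items:
        raise ValueError("empty item set")
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    total = np.zeros(theta.size)
    for it in items:
        total += point_item_information(it, theta)
    return total


def total_information(
    info_fn,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    n_nodes: int = DEFAULT_NODES,
) -> float:
    """Area under a point-information curve by Gauss-Legendre quadrature.

    ``info_fn`` maps a theta array to information values; ``bounds`` must
    be finite with lo < hi.
    """
    lo, hi = bounds
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError("bounds must be finite with lo < hi")
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    theta = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    vals = np.asarray(info_fn(theta), dtype=float)
    return float(0.5 * (hi - lo) * np.dot(w, vals))


def total_item_information(item: MarginalGRMItem, **kw) -> float:
    return total_information(lambda t: point_item_information(item, t), **kw)


def total_test_information(items: list[MarginalGRMItem], **kw) -> float:
    return total_information(lambda t: point_test_information(items, t), **kw)


def averaged_total_test_information(total: float, n_items: int) -> float:
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    return total / n_items


def stdem(point_info) -> np.ndarray:
    """Standard error of measurement, 1/sqrt(I); +inf where I == 0."""
    info = np.atleast_1d(np.asarray(point_info, dtype=float))
    if np.any(info < 0):
        raise ValueError("information must be non-negative")
    with np.errstate(divide="ignore"):
        return np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, _FLOOR)), np.inf)


def scaled_point_curve(curve: np.ndarray, n_items: int) -> np.ndarray:
    """Rescale a point test-information curve to a common 10-item length."""
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    return 10.0 * np.asarray(curve, dtype=float) / n_items


@dataclass
class InformationProfile:
    """Per-inventory information curves and totals on a common theta grid."""

    theta_grid: np.ndarray
    point_item_info: pd.DataFrame        # items x grid
    point_test_info: pd.DataFrame        # inventories x grid
    total_item_info: pd.Series
    total_test_info: pd.Series
    averaged_total_test_info: pd.Series
    n_items: pd.Series
    stdem: pd.DataFrame = field(default=None)

    def comparison_table(self, exclude=("ALL", "AUDIT_C")) -> pd.DataFrame:
        keep = [i for i in self.total_test_info.index if i not in set(exclude)]
        return comparison_table(
            self.total_test_info[keep],
            self.averaged_total_test_info[keep],
            self.n_items[keep],
        )


def build_profile(
    items: list[MarginalGRMItem],
    membership: dict[str, list[str]],
    theta_grid: np.ndarray = DEFAULT_GRID,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    n_nodes: int = DEFAULT_NODES,
) -> InformationProfile:
    """Assemble curves and totals for every inventory in ``membership``.

    ``membership`` maps inventory name -> member item ids (an item may
    appear in several inventories, e.g. the embedded short form).
    """
    by_id = {it.item_id: it for it in items}
    grid = np.asarray(theta_grid, dtype=float)
    item_curves = pd.DataFrame(
        {iid: point_item_information(by_id[iid], grid) for iid in by_id},
        index=grid,
    ).T
    item_totals = pd.Series(
        {iid: total_item_information(by_id[iid], bounds=bounds, n_nodes=n_nodes)
         for iid in by_id}
    )
    test_curves, test_totals, avg_totals, counts, sems = {}, {}, {}, {}, {}
    for inv, ids in membership.items():
        members = [by_id[i] for i in ids if i in by_id]
        if not members:
            continue
        curve = point_test_information(members, grid)
        test_curves[inv] = curve
        tot = total_test_information(members, bounds=bounds, n_nodes=n_nodes)
        test_totals[inv] = tot
        counts[inv] = len(members)
        avg_totals[inv] = averaged_total_test_information(tot, len(members))
        sems[inv] = stdem(curve)
    return InformationProfile(
        theta_grid=grid,
        point_item_info=item_curves,
        point_test_info=pd.DataFrame(test_curves, index=grid).T,
        total_item_info=item_totals,
        total_test_info=pd.Series(test_totals),
        averaged_total_test_info=pd.Series(avg_totals),
        n_items=pd.Series(counts),
        stdem=pd.DataFrame(sems, index=grid).T,
    )


def comparison_table(
    totals: pd.Series, averaged: pd.Series, n_items: pd.Series
) -> pd.DataFrame:
    """Inventories ranked by averaged total information, with adjacent
    differences — the inventory-comparison summary table."""
    if len(totals) < 2:
        raise ValueError("need at least 2 inventories to compare")
    order = averaged.sort_values(ascending=False).index
    rows = []
    for rank, inv in enumerate(order, start=1):
        diff = np.nan
        comparison = ""
        if rank > 1:
            prev = order[rank - 2]
            diff = averaged[prev] - averaged[inv]
            comparison = f"{rank - 1}. vs. {rank}."
        rows.append({
            "rank": rank,
            "measure": inv,
            "n_items": int(n_items[inv]),
            "total_test_information": totals[inv],
            "averaged_total_test_information": averaged[inv],
            "comparison": comparison,
            "difference_in_averaged_information": diff,
        })
    return pd.DataFrame(rows).set_index("rank")
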