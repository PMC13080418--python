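"""Registry-like synthetic cohort from a known bifactor graded-response model.

The generator emulates the structure of a psychotherapy quality-registry
item pool: 51 unique ordinal items across four self-report inventories
(CORE-OM with an embedded CORE-10 subset, PHQ-9, OASIS, AUDIT-C), a
dominant general internalizing factor plus eight specific factors, an
anxiety-specific factor that loads the OASIS items, and a small block of
externalizing items (alcohol use, aggression) with no general-factor
loading.  The true parameters are exposed so every downstream estimation
stage can be checked against ground truth.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy.special import ndtri

from . import information as info_mod
from . import projection
from .types import CohortConfig, Inventory, ItemSpec, ResponseMatrix, TrueModel

#: seed under which the default true model's loadings and thresholds were
#: drawn once from their stated ranges and frozen
_BUILD_SEED = 20260926

#: CORE-OM item numbers forming the embedded 10-item short form (synthetic
#: stand-in for the real embedding; includes the two high-information items
#: 23 and 27 and one risk item)
CORE10_ITEMS = (2, 4, 11, 13, 15, 16, 23, 27, 28, 31)

#: CORE-OM aggression items that load no general factor
AGGRESSION_ITEMS = (6, 22)

_SPECIFIC_GROUPS = {
    "anxiety": [("OASIS", k) for k in range(1, 6)] + [("CORE_OM", k) for k in (2, 11, 15)],
    "depression": [("PHQ9", k) for k in range(1, 10)],
    "alcohol": [("AUDIT_C", k) for k in range(1, 4)],
    "risk": [("CORE_OM", k) for k in (6, 9, 16, 22, 24, 34)],
    "functioning": [("CORE_OM", k) for k in (7, 10, 12, 21, 25, 29, 32)],
    "wellbeing": [("CORE_OM", k) for k in (3, 4, 5, 8, 13, 20)],
    "social": [("CORE_OM", k) for k in (1, 19, 26, 28, 31, 33)],
    "somatic": [("CORE_OM", k) for k in (14, 17, 18, 23, 27, 30)],
}

FACTOR_NAMES = ["general"] + list(_SPECIFIC_GROUPS)


def default_item_specs() -> list[ItemSpec]:
    """The 51-item registry pool: 34 + 9 + 5 + 3 items."""
    specs = [
        ItemSpec(f"CORE_OM_{k}", Inventory.CORE_OM, 5, in_core10=k in CORE10_ITEMS)
        for k in range(1, 35)
    ]
    specs += [ItemSpec(f"PHQ9_{k}", Inventory.PHQ9, 4) for k in range(1, 10)]
    specs += [ItemSpec(f"OASIS_{k}", Inventory.OASIS, 5) for k in range(1, 6)]
    specs += [ItemSpec(f"AUDIT_C_{k}", Inventory.AUDIT_C, 5) for k in range(1, 4)]
    return specs


def default_registry_spec() -> tuple[list[ItemSpec], TrueModel]:
    """Item specs plus the frozen data-generating bifactor model.

    General loadings of loading items are uniform on [0.4, 0.85]; each
    item's single specific loading takes a substantial fraction
    (0.65-0.9) of the admissible residual scale sqrt(0.9 - lambda_g^2),
    so uniqueness stays positive while every specific factor is strong
    enough to be recoverable at registry sample sizes — a deliberate
    design requirement, since the generator doubles as the ground-truth
    oracle for factor-count and loading recovery.  Alcohol and aggression
    items have zero general loading and a strong specific loading.
    Factors are orthogonal in the generating model; thresholds are mildly
    dispersed around roughly equal category occupancies, with rare top
    categories for the externalizing items (the aggression item 22
    analogue is extreme enough that large cohorts leave its top category
    nearly empty).
    """
    specs = default_item_specs()
    rng = np.random.default_rng(_BUILD_SEED)
    ids = [s.item_id for s in specs]
    idx = {iid: i for i, iid in enumerate(ids)}
    p, k = len(specs), 1 + len(_SPECIFIC_GROUPS)
    lam = np.zeros((p, k))
    zero_general = {f"AUDIT_C_{j}" for j in range(1, 4)} | {
        f"CORE_OM_{j}" for j in AGGRESSION_ITEMS
    }
    for f, (name, members) in enumerate(_SPECIFIC_GROUPS.items(), start=1):
        for pos, (inv, num) in enumerate(members):
            iid = f"{inv}_{num}"
            i = idx[iid]
            # alternate the polarity of specific loadings (wording/method
            # effects); this keeps each specific dimension distinguishable
            # from the general factor instead of collinear with it
            sign = 1.0 if pos % 2 == 0 else -1.0
            if iid in zero_general:
                lam[i, 0] = 0.0
                lam[i, f] = rng.uniform(0.6, 0.8)
            else:
                lam[i, 0] = rng.uniform(0.4, 0.85)
                lam[i, f] = sign * rng.uniform(0.65, 0.9) * np.sqrt(0.9 - lam[i, 0] ** 2)

    thresholds = []
    for s in specs:
        K = s.n_categories
        base = ndtri(np.arange(1, K) / K)
        center = rng.uniform(-0.4, 0.4)
        spread = rng.uniform(0.85, 1.15)
        tau = center + spread * base
        if s.inventory is Inventory.AUDIT_C:
            tau = tau + 0.5                      # drinking: skewed low
        if s.item_id == "CORE_OM_6":
            tau = tau + np.array([0.8, 1.0, 1.2, 1.4])
        if s.item_id == "CORE_OM_22":
            # threats/intimidation analogue: top category essentially empty
            tau = tau + np.array([1.0, 1.3, 1.7, 2.6])
        thresholds.append(tau)

    model = TrueModel(
        loadings=lam,
        factor_corr=np.eye(k),
        thresholds=thresholds,
        factor_names=list(FACTOR_NAMES),
    )
    model.validate()
    return specs, model


def plant_unstable_item(model: TrueModel, item_index: int,
                        communality: float = 0.998) -> TrueModel:
    """Return a copy with one item's communality pushed near 1.

    Such an item destabilizes least-squares extraction (a Heywood case),
    mimicking a screening item with extreme, unstable estimates.
    """
    lam = model.loadings.copy()
    row = lam[item_index]
    h2 = row @ model.factor_corr @ row
    if h2 <= 0:
        raise ValueError("cannot scale an all-zero loading row")
    lam[item_index] = row * np.sqrt(communality / h2)
    out = TrueModel(lam, model.factor_corr.copy(),
                    [t.copy() for t in model.thresholds],
                    list(model.factor_names))
    out.validate()
    return out


def sample_responses(
    model: TrueModel, specs: list[ItemSpec], cfg: CohortConfig
) -> tuple[ResponseMatrix, ResponseMatrix]:
    """Draw a pre/post ordinal cohort from the model.

    Latent factors are multivariate normal with the model's factor
    correlations; the underlying response is y* = lambda' theta + e with
    normal residual variance equal to the item uniqueness, and the
    observed category counts the thresholds below y*.  A random subset of
    floor(completion_rate * n_pre) persons completes posttreatment, where
    the general factor is shifted by -(treatment_effect + personal
    deviation) and residuals are redrawn.  Missing responses (if any) are
    completely at random.
    """
    model.validate()
    psi = model.uniqueness()
    p = len(specs)
    if model.loadings.shape[0] != p:
        raise ValueError("model/item spec length mismatch")
    rng = np.random.default_rng(cfg.seed)
    chol = np.linalg.cholesky(model.factor_corr)
    theta = rng.standard_normal((cfg.n_pre, model.n_factors)) @ chol.T

    def categorize(lin: np.ndarray) -> np.ndarray:
        ystar = lin + rng.standard_normal(lin.shape) * np.sqrt(psi)[None, :]
        X = np.empty_like(ystar)
        for j in range(p):
            X[:, j] = np.searchsorted(model.thresholds[j], ystar[:, j])
        return X

    def knock_out(X: np.ndarray) -> np.ndarray:
        if cfg.missing_rate > 0:
            X[rng.random(X.shape) < cfg.missing_rate] = np.nan
        return X

    lin_pre = theta @ model.loadings.T
    X_pre = knock_out(categorize(lin_pre))

    n_post = int(np.floor(cfg.completion_rate * cfg.n_pre))
    completers = np.sort(rng.choice(cfg.n_pre, size=n_post, replace=False))
    theta_post = theta[completers].copy()
    change = cfg.treatment_effect + cfg.treatment_effect_sd * rng.standard_normal(n_post)
    theta_post[:, 0] -= change
    X_post = knock_out(categorize(theta_post @ model.loadings.T))

    ids = [s.item_id for s in specs]
    persons = np.arange(1, cfg.n_pre + 1)
    pre = ResponseMatrix(pd.DataFrame(X_pre, index=persons, columns=ids), list(specs))
    post = ResponseMatrix(
        pd.DataFrame(X_post, index=persons[completers], columns=ids), list(specs)
    )
    pre.data.index.name = post.data.index.name = "person_id"
    return pre, post


def _inventory_ids(specs: list[ItemSpec], inventory) -> list[str]:
    if inventory == "CORE_10":
        return [s.item_id for s in specs if s.in_core10]
    inv = Inventory(inventory)
    return [s.item_id for s in specs if s.inventory is inv]


def true_marginal_items(model: TrueModel, specs: list[ItemSpec]) -> list:
    """Marginal general-factor GRM items implied by the true model."""
    out = []
    psi = model.uniqueness()
    for i, s in enumerate(specs):
        from .types import MGRMItem

        item = MGRMItem(s.item_id, model.loadings[i], model.thresholds[i], psi[i])
        out.append(projection.marginalize(item, model.factor_corr, general_index=0))
    return out


def true_marginal_information(
    model: TrueModel, specs: list[ItemSpec], inventory,
    bounds=info_mod.DEFAULT_BOUNDS, n_nodes=info_mod.DEFAULT_NODES,
) -> float:
    """True total test information about the general factor for an inventory."""
    ids = set(_inventory_ids(specs, inventory))
    if not ids:
        raise ValueError(f"unknown or empty inventory: {inventory}")
    items = [it for it in true_marginal_items(model, specs) if it.item_id in ids]
    return info_mod.total_test_information(items, bounds=bounds, n_nodes=n_nodes)


def write_true_model(model: TrueModel, specs: list[ItemSpec], path) -> None:
    payload = {
        "factor_names": model.factor_names,
        "items": [
            {
                "item_id": s.item_id,
                "inventory": s.inventory.value,
                "in_core10": s.in_core10,
                "n_categories": s.n_categories,
                "loadings": model.loadings[i].tolist(),
                "thresholds": model.thresholds[i].tolist(),
                "uniqueness": float(model.uniqueness()[i]),
            }
            for i, s in enumerate(specs)
        ],
        "factor_corr": model.factor_corr.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
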