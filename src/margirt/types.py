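"""Shared containers for the inventory-comparison pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd


class Inventory(str, Enum):
    CORE_OM = "CORE_OM"
    PHQ9 = "PHQ9"
    OASIS = "OASIS"
    AUDIT_C = "AUDIT_C"


@dataclass(frozen=True)
class ItemSpec:
    """One ordinal item: which inventory it belongs to and its scale."""

    item_id: str
    inventory: Inventory
    n_categories: int
    in_core10: bool = False

    def __post_init__(self):
        if self.n_categories < 2:
            raise ValueError("an item needs at least two categories")
        if self.in_core10 and self.inventory is not Inventory.CORE_OM:
            raise ValueError("CORE-10 items are a subset of CORE-OM")


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with NaN for missing.

    ``data`` is a DataFrame indexed by person id whose columns follow the
    item ids of ``items``; values are small non-negative integers stored
    as float so missing cells can be NaN.
    """

    data: pd.DataFrame
    items: list[ItemSpec]

    def __post_init__(self):
        ids = [it.item_id for it in self.items]
        if list(self.data.columns) != ids:
            raise ValueError("data columns must match item ids, in order")

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def item_ids(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, keep: Sequence[str]) -> "ResponseMatrix":
        keep = list(keep)
        items = [it for it in self.items if it.item_id in keep]
        return ResponseMatrix(self.data[[it.item_id for it in items]].copy(), items)

    def inventory_members(self, inventory: Inventory | str) -> list[str]:
        inv = Inventory(inventory)
        return [it.item_id for it in self.items if it.inventory is inv]

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "person_id", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, items: list[ItemSpec]) -> "ResponseMatrix":
        df = pd.read_csv(path)
        df = df.set_index("person_id")
        return cls(df[[it.item_id for it in items]].astype(float), items)


@dataclass
class TrueModel:
    """Data-generating bifactor graded-response model (column 0 = general)."""

    loadings: np.ndarray          # items x factors
    factor_corr: np.ndarray       # factors x factors
    thresholds: list[np.ndarray]  # per item, strictly increasing
    factor_names: list[str] = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def uniqueness(self) -> np.ndarray:
        lam = self.loadings
        return 1.0 - np.einsum("ik,kl,il->i", lam, self.factor_corr, lam)

    def validate(self) -> None:
        if np.any(self.uniqueness() <= 0):
            raise ValueError("inadmissible model: non-positive uniqueness")
        for tau in self.thresholds:
            if np.any(np.diff(tau) <= 0):
                raise ValueError("thresholds must be strictly increasing")


@dataclass
class CohortConfig:
    """Simulation settings for a registry-like pre/post cohort."""

    n_pre: int = 5000
    completion_rate: float = 0.59
    treatment_effect: float = 0.8
    treatment_effect_sd: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pre < 1:
            raise ValueError("n_pre must be >= 1")
        if not 0 < self.completion_rate <= 1:
            raise ValueError("completion_rate must be in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class PolychoricResult:
    thresholds: dict[str, np.ndarray]
    corr: pd.DataFrame
    pair_n: pd.DataFrame
    smoothed: bool = False
    warnings: list[str] = field(default_factory=list)

    def matrix(self) -> np.ndarray:
        return self.corr.to_numpy()


@dataclass
class BifactorSolution:
    """Rotated EFA solution aligned so column 0 is the general factor."""

    loadings: pd.DataFrame        # items x factors, column 0 = "general"
    factor_corr: np.ndarray       # k x k
    uniqueness: pd.Series
    rotation_criterion_value: float
    n_starts: int
    converged: bool
    excluded_items: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def general(self) -> pd.Series:
        return self.loadings.iloc[:, 0]


@dataclass
class MGRMItem:
    """Multidimensional normal-ogive graded item (underlying-variable metric)."""

    item_id: str
    loading_vec: np.ndarray
    thresholds: np.ndarray
    uniqueness: float


@dataclass
class MarginalGRMItem:
    """Unidimensional graded item for the general factor after marginalization."""

    item_id: str
    a: float                       # discrimination, >= 0
    b: np.ndarray                  # ordered boundary locations (empty if a == 0)
    metric: str = "ogive"          # "ogive" or "logistic"
    flagged: bool = False

    def __post_init__(self):
        if self.a < 0:
            raise ValueError("discrimination must be non-negative")
        if self.a > 0 and np.any(np.diff(self.b) <= 0):
            raise ValueError("boundary locations must be strictly increasing")
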