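import numpy as np
import pandas as pd
import pytest

from margirt.synthetic import default_registry_spec, sample_responses
from margirt.types import CohortConfig, Inventory, ItemSpec, ResponseMatrix


@pytest.fixture(scope="session")
def registry():
    specs, model = default_registry_spec()
    return specs, model


@pytest.fixture(scope="session")
def small_cohort(registry):
    """n = 600 pre/post cohort used by the fast pipeline tests."""
    specs, model = registry
    return sample_responses(model, specs, CohortConfig(n_pre=600, seed=7))


@pytest.fixture(scope="session")
def large_cohort(registry):
    """n = 5000 pretreatment cohort for the recovery checks."""
    specs, model = registry
    pre, _ = sample_responses(model, specs, CohortConfig(n_pre=5000, seed=11))
    return pre


def make_matrix(X: np.ndarray, n_categories: int = 5,
                inventory: Inventory = Inventory.CORE_OM) -> ResponseMatrix:
    """Wrap a raw integer array as a ResponseMatrix with generic items."""
    p = X.shape[1]
    items = [ItemSpec(f"{inventory.value}_{j + 1}", inventory, n_categories)
             for j in range(p)]
    df = pd.DataFrame(np.asarray(X, dtype=float),
                      columns=[it.item_id for it in items])
    df.index = np.arange(1, X.shape[0] + 1)
    df.index.name = "person_id"
    return ResponseMatrix(df, items)
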