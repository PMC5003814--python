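import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from proteoage import (
    SimulationParams,
    build_ratio_matrix,
    filter_quantifiable,
    simulate_proteome,
)
from proteoage.io import RatioMatrix
from proteoage.simulate import PAIRS

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated experiment shared across read-only tests."""
    params = SimulationParams(n_proteins=600, seed=7)
    tables, truth = simulate_proteome(params)
    return tables, truth


@pytest.fixture(scope="session")
def small_matrix(small_dataset) -> RatioMatrix:
    tables, _ = small_dataset
    filtered, _ = filter_quantifiable(tables)
    return build_ratio_matrix(filtered)


def matrix_from_values(values: dict[str, np.ndarray], ref=None) -> RatioMatrix:
    """Build a RatioMatrix directly from per-pair (n x n_rep) arrays."""
    n, n_rep = next(iter(values.values())).shape
    ids = pd.Index([f"P{i:05d}" for i in range(n)], name="protein")
    columns = pd.MultiIndex.from_product(
        [list(PAIRS), range(1, n_rep + 1)], names=["pair", "replicate"]
    )
    log2 = pd.DataFrame(np.nan, index=ids, columns=columns)
    for pair in PAIRS:
        arr = values.get(pair)
        if arr is not None:
            log2.loc[:, pair] = np.asarray(arr, dtype=float)
    if ref is None:
        ref = np.full(n, 1e7)
    return RatioMatrix(
        log2=log2,
        ref_intensity=pd.Series(np.asarray(ref, dtype=float), index=ids),
        n_replicates=n_rep,
    )
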