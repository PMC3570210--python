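import numpy as np
import pytest

from schurdle.core_data import EtMatrix
from schurdle.simulate import (
    canonical_bundle_config,
    canonical_plate_config,
    contaminated_bundle_config,
    simulate_bundle,
    simulate_plate,
)


def make_et(values, cells=None, unit=None, group=None, ct_max=40.0):
    """Small EtMatrix literal for tests: values is (wells x genes)."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return EtMatrix(
        et=values,
        well_ids=[f"w{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(m)],
        cells_per_well=np.ones(n, dtype=int) if cells is None else np.asarray(cells),
        unit=["u0"] * n if unit is None else list(unit),
        group=["a"] * n if group is None else list(group),
        ct_max=ct_max,
    )


@pytest.fixture(scope="session")
def canonical_plate():
    return simulate_plate(canonical_plate_config(seed=0))


@pytest.fixture(scope="session")
def clean_bundle():
    return simulate_bundle(canonical_bundle_config(seed=0))


@pytest.fixture(scope="session")
def contaminated_bundle():
    return simulate_bundle(contaminated_bundle_config(seed=0))
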