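import numpy as np
import pytest

from pleiolink import (
    MutationParams,
    SimConfig,
    build_architecture,
    build_selection,
    run_simulation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def hoc_pleio_result():
    """Small house-of-cards pleiotropy run reused by statistics tests.

    mu=1e-4 keeps the regime house-of-cards (mu < 0.1 * alpha2/omega2) while
    delivering enough mutations at this population size and duration for
    standing variation to accumulate.
    """
    arch = build_architecture("pleiotropy", 30)
    cfg = SimConfig(
        architecture=arch,
        mutation=MutationParams(mu=1e-4, alpha2=0.1),
        selection=build_selection(100.0, 0.9, (10.0, 10.0)),
        n_individuals=200,
        generations=800,
        sample_size=100,
        seed=7,
    )
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def qtn_linkage_result():
    """Small biallelic-QTN linkage run for sampling/scan/export tests."""
    arch = build_architecture("linkage", 25, biallelic=True)
    cfg = SimConfig(
        architecture=arch,
        mutation=MutationParams(mu=1e-4, alpha2=0.1, mode="qtn_biallelic"),
        selection=build_selection(100.0, 0.9, (10.0, 10.0)),
        n_individuals=200,
        generations=800,
        sample_size=150,
        seed=11,
    )
    return run_simulation(cfg)
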