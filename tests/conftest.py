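import numpy as np
import pytest

import sweepmodes as sm
from sweepmodes.kernels import SweepParams
from sweepmodes.simulate import (
    SimulationScenario,
    default_coancestry,
    simulate_neutral,
    simulate_selected_region,
)

SEED = 20260927


def small_config(**overrides) -> sm.RunConfig:
    """Desk-scale run configuration for fast structural tests."""
    base = dict(
        Ne=10_000.0,
        rec=0.005,
        selected_pops=[1, 3, 5],
        sels=[0.01, 0.03, 0.05, 0.1],
        migs=[0.001, 0.1],
        times=[0.0, 100.0, 1.0e4],
        gs=[0.001, 0.1],
        sources=[1, 3, 5],
        num_bins=50,
        sample_sizes=[10] * 6,
        n_sites=5,
        locus_name="test_locus",
    )
    base.update(overrides)
    return sm.RunConfig(**base)


def small_scenario(seed: int = SEED, mode: str = "independent", **overrides) -> SimulationScenario:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    base = dict(
        k=6,
        F_true=default_coancestry(6),
        mode=mode,
        params=SweepParams(Ne=10_000.0, s=0.05),
        true_site=0.0,
        positions=np.sort(rng.uniform(0.0, 1.0, size=60)),
        sample_sizes=np.full(6, 10),
        selected_pops0=[0, 2, 4],
        n_neutral_sites=1_500,
        rec=0.005,
        seed=seed,
    )
    base.update(overrides)
    return SimulationScenario(**base)


@pytest.fixture(scope="session")
def small_data():
    scenario = small_scenario()
    return simulate_neutral(scenario), simulate_selected_region(scenario)


@pytest.fixture(scope="session")
def small_ctx(small_data):
    neutral, selected = small_data
    return sm.build_context(small_config(), neutral, selected)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


def random_psd_coancestry(rng, k: int, scale: float = 0.2) -> np.ndarray:
    """Random PSD matrix with coancestry-scale entries (well below 1)."""
    A = rng.normal(size=(k, k + 2))
    F = A @ A.T
    F *= scale / np.abs(F).max()
    return (F + F.T) / 2.0
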