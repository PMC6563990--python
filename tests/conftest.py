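import numpy as np
import pytest

from oxbscreen import IntensityPanel, SimulationConfig, simulate_panels


@pytest.fixture
def toy_panel() -> IntensityPanel:
    """Two probes x two samples with hand-checkable intensities."""
    return IntensityPanel(
        probe_ids=["cg01", "cg02"],
        sample_ids=["s1", "s2"],
        M_bs=np.array([[110.0, 200.0], [200.0, 400.0]]),
        U_bs=np.array([[1000.0, 100.0], [100.0, 100.0]]),
        M_oxbs=np.array([[100.0, 100.0], [100.0, 400.0]]),
        U_oxbs=np.array([[100.0, 100.0], [100.0, 100.0]]),
    )


@pytest.fixture(scope="session")
def sim_pair():
    """Small matched healthy/cancer simulation shared across tests."""
    config = SimulationConfig(n_probes=800, n_samples=20, seed=11)
    healthy, cancer, truth = simulate_panels(config)
    return config, healthy, cancer, truth


def random_panel(rng: np.random.Generator, n_probes: int, n_samples: int = 1,
                 low: float = 0.0, high: float = 1000.0,
                 tissue: str = "unspecified") -> IntensityPanel:
    """Panel of independent uniform intensities for oracle-based checks."""
    shape = (n_probes, n_samples)
    return IntensityPanel(
        probe_ids=[f"p{i}" for i in range(n_probes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        tissue=tissue,
        M_bs=rng.uniform(low, high, shape),
        U_bs=rng.uniform(low, high, shape),
        M_oxbs=rng.uniform(low, high, shape),
        U_oxbs=rng.uniform(low, high, shape),
    )
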