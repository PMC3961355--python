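import numpy as np
import pytest

from wcna.dataset import ExpressionDataset
from wcna.synthetic import ModuleSpec, SimulationConfig, make_worked_example, simulate_dataset


@pytest.fixture(scope="session")
def worked_example():
    """8-probe deterministic fixture with loop-oracle expectations."""
    return make_worked_example()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_dataset(rng):
    """10 probes × 12 timepoints × 3 replicates, two conditions, random values."""
    values = {
        c: rng.normal(8.0, 1.0, size=(10, 12, 3)) for c in ("LD", "DD")
    }
    return ExpressionDataset(
        probe_ids=[f"p{i}" for i in range(10)],
        timepoints=np.arange(12) * 4.0,
        values=values,
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """300 probes with one 30-probe module tight in DD, loose in LD."""
    cfg = SimulationConfig(
        n_probes=300,
        modules=[
            ModuleSpec(
                size=30,
                correlation={"LD": 0.2, "DD": 0.9},
                amplitude={"LD": 1.0, "DD": 1.0},
            )
        ],
        background_sd=1.0,
        replicate_sd=0.3,
        seed=42,
    )
    return simulate_dataset(cfg)
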