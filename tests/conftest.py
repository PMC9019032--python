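import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isletid.gsea import GseaParams
from isletid.pipeline import PipelineParams, run_full
from isletid.simulate import SimulationConfig, generate_collection

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_sim_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A scaled-down collection for unit tests: 4 datasets, 4 types, 60 cells/type."""
    base = dict(
        n_datasets=4,
        cells_per_type=60,
        n_markers_per_type=40,
        marker_reproducibility=(1.0,) * 16 + (0.6,) * 16 + (0.3,) * 8,
        n_background_genes=300,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_collection(small_config):
    return generate_collection(small_config)


@pytest.fixture(scope="session")
def small_run():
    """Full pipeline on the scaled-down collection (geneset bounds scaled to its sizes)."""
    params = PipelineParams(
        sim=small_sim_config(seed=7),
        gsea=GseaParams(n_perm=300, seed=7),
        min_geneset_size=15,
    )
    return run_full(params)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline at the reference study conditions (7 datasets, 4 types)."""
    return run_full(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
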