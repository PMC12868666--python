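import numpy as np
import pytest

from spatipath.synthetic_data import (
    CellTypeSpec,
    GeneSpec,
    SimulationConfig,
    default_config,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_config():
    """A reduced tissue for fast end-to-end tests (~250 cells/sample)."""
    from dataclasses import replace

    cfg = default_config()
    return replace(cfg, width_um=320.0, height_um=240.0)


@pytest.fixture(scope="session")
def tg_sample(small_config):
    """One transgenic sample with image, plus its ground truth."""
    from spatipath.synthetic_data import generate_sample

    rng = np.random.default_rng(7)
    bundle, truth, affine = generate_sample(
        small_config, "tg_F1", "tg", "F", rng, perturb_affine=True
    )
    return bundle, truth, affine


def single_type_config(**kwargs) -> SimulationConfig:
    """One scattered cell type, two genes; for targeted distribution checks."""
    spec = dict(
        cell_types=(CellTypeSpec("T", "ExN", None, 300.0, mean_library_size=100.0),),
        genes=(
            GeneSpec("G1", "base", {"T": 1.0}, 0.0),
            GeneSpec("G2", "custom", {"T": 9.0}, 0.0),
        ),
        width_um=400.0,
        height_um=400.0,
    )
    spec.update(kwargs)
    return SimulationConfig(**spec)
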