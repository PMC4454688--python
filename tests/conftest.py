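import pytest

from embryomito import SimulationConfig, build_synthetic_grid, te_reference


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def small_grid():
    """22 autosomes x 40 fixed-width bins with random GC fractions."""
    return build_synthetic_grid(seed=11)


@pytest.fixture(scope="session")
def reference_df():
    """The bundled 23-sample trophectoderm dataset."""
    return te_reference()
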