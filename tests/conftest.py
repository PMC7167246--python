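import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def catalog():
    from baitpond.catalog import load_catalog

    return load_catalog()


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic study (seed 1): genome, inputs, ground truth."""
    from baitpond.simulate import make_genome, make_pond_and_gwas, small_config

    cfg = small_config(1)
    genome = make_genome(cfg)
    inputs = make_pond_and_gwas(cfg, genome)
    return cfg, genome, inputs
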