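import pytest

from omicsforest.synthetic import SyntheticConfig, build_bundle


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        seed=7, n_genes=300, n_nodes=120, n_peaks=60, n_variants=30, module_size=10
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return build_bundle(small_config)
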