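import pytest

from mirkit.synthdata import (
    SyntheticConfig,
    generate_reference,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        seed=1,
        n_mirnas=6,
        reads_per_library=4000,
        contaminant_fraction=0.05,
    )


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory):
    """One generated study (bundle, truth, fastq paths) shared by the suite."""
    bundle, truth = generate_reference(small_config)
    out = tmp_path_factory.mktemp("study")
    paths = simulate_reads(small_config, bundle, truth, str(out))
    return small_config, bundle, truth, paths
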