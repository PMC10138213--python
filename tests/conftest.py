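import pytest

from coderep.synthdata import SyntheticConfig, generate_bundle

# A scaled-down study used by most unit tests: same structure as the
# default conditions, smaller gene count and genome for speed.
SMALL = dict(
    seed=7,
    n_genes=120,
    n_planted_cooperative=8,
    n_planted_ezh2i_only=5,
    n_planted_hdaci_only=5,
    n_planted_additive=5,
    chrom_length=2_000_000,
    genome_n_chroms=3,
    cohort_n_normal=20,
    cohort_n_primary=30,
    cohort_n_metastatic=40,
    n_background_peaks=30,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(**SMALL)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def noiseless_bundle():
    return generate_bundle(SyntheticConfig(**{**SMALL, "noise_sd": 0.0}))


@pytest.fixture(scope="session")
def default_bundle():
    """The full default study conditions (1000 genes, 3 replicates)."""
    return generate_bundle(SyntheticConfig(seed=7))
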