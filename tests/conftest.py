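import pytest

from crosspeak.simulate import SynthConfig, generate

# A desk-scale study: same designed gradients as the full defaults, smaller
# genome and peak counts so module tests stay fast.
SMALL_KWARGS = dict(
    n_chroms=2,
    chrom_length_bp=200_000,
    n_arena_chroms=2,
    arena_chrom_length_bp=150_000,
    n_genes=80,
    base_peaks=60,
    new_peaks_per_level=(0, 60, 90, 120),
    method1_count=120,
    method2_exclusive_count=100,
)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(seed=7, **SMALL_KWARGS)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)
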