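import pytest

from neoxy.simulate import RearrangementConfig, SimConfig, simulate_neo_xy

NO_REARRANGEMENTS = RearrangementConfig(
    n_blocks=2, block_length=4000,
    n_inversions=0, n_translocations=0, n_duplications=0,
)


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A 3 Mb neo-X-only population: fast, with genes in a 1 Mb stratum."""
    defaults = dict(
        seed=seed,
        genome=(("neoX", 3_000_000),),
        stratum=(1_000_000, 2_000_000),
        xl_interval=None,
        n_genes_stratum=12,
        n_genes_background=4,
        repeat_families=(),
        rearrangements=NO_REARRANGEMENTS,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_neo_xy(small_config())


def scan_config(seed: int) -> SimConfig:
    """The default 100 Mb genome, without repeats/blocks (scan-only runs)."""
    return SimConfig(seed=seed, repeat_families=(), rearrangements=NO_REARRANGEMENTS)


@pytest.fixture(scope="session")
def scan_bundle():
    return simulate_neo_xy(scan_config(11))
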