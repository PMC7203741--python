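import pytest
from hypothesis import settings

from haplopurge.purge_core import ChainParams, PurgeParams
from haplopurge.synthetic import SimConfig, simulate

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")

# Down-scaled scenario (400 kb) for fast closed-loop tests; the acceptance
# tests use the full default 2 Mb configuration.
SMALL = SimConfig(
    genome_length=400_000,
    n_contigs=10,
    n_haplotigs=2,
    n_overlaps=2,
    overlap_len=12_000,
    n_junk=1,
    n_repeat=1,
    junk_len=8_000,
    read_len=5_000,
)

# purge parameters proportionate to the 400 kb scale
SMALL_CHAIN = ChainParams(min_chain_score=2_000)
SMALL_PURGE = PurgeParams(end_tolerance_bp=3_000)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(SMALL)


@pytest.fixture(scope="session")
def default_sim():
    return simulate(SimConfig())
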