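import pytest

from igannot.simulate import (LocusSimConfig, RepertoireSimConfig,
                              simulate_locus, simulate_repertoire)


@pytest.fixture(scope="session")
def heavy_locus():
    """Default heavy locus: 20 V (with pseudogenes and leaderless), 7 D, 5 J."""
    return simulate_locus(LocusSimConfig(seed=11))


@pytest.fixture(scope="session")
def clean_locus():
    """All-functional heavy locus for repertoire work."""
    return simulate_locus(LocusSimConfig(
        pseudogene_fraction=0.0, leaderless_fraction=0.0, seed=31))


@pytest.fixture(scope="session")
def clean_repertoire(clean_locus):
    """500 SHM-free sequences in 60 clones."""
    return simulate_repertoire(
        clean_locus.database,
        RepertoireSimConfig(n_sequences=500, clone_count=60, shm_rate=0.0,
                            seed=22))
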