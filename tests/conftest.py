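import numpy as np
import pytest

from glacierpace import synthetic_data as synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_copy_family():
    """A pair of copies that split 2.6e5 years ago (neutral, 2000 codons)."""
    cfg = synth.BurstSimConfig(seed=7, n_codons=2000, mu_year=4e-9, omega=0.0,
                               burst_times=(2.6e5,), copies_per_burst=1)
    records, history = synth.simulate_burst_family(cfg)
    return records, history


@pytest.fixture(scope="session")
def resolvable_burst_ds():
    """Node dS values from a burst family simulated at a scale where the
    three duplication waves are well separated relative to the
    substitution sampling noise."""
    from glacierpace import molevo

    cfg = synth.BurstSimConfig(seed=1, n_codons=6000, mu_year=4e-9, omega=0.0,
                               burst_times=(6e6, 4e6, 2e6), copies_per_burst=16)
    records, _ = synth.simulate_burst_family(cfg)
    dup, _, _ = molevo.family_dup_ds(records)
    return dup
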