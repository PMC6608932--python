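import pytest

from amphase import simulate


@pytest.fixture(scope="session")
def small_family():
    """A small error-free family: 1 amplicon, 12 sequenced offspring,
    high depth, no recombination or dropout."""
    cfg = simulate.SimConfig(
        seed=11,
        n_offspring=20,
        n_sequenced=12,
        amplicon_length=1500,
        depth_mean=120,
        depth_sd=20,
        error_rate=0.0,
        recomb_prob=0.0,
        dropout_prob=0.0,
    )
    truth = simulate.simulate_family(cfg)
    fragments, records = simulate.simulate_fragments(truth, cfg)
    return cfg, truth, fragments, records
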