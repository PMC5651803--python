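import pytest

from mitocomp import synthetic


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic mitogenome (~20 kb, 37 genes) plus truth."""
    cfg = synthetic.SimConfig(seed=11)
    genome, truth = synthetic.simulate_genome(cfg)
    return cfg, genome, truth
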