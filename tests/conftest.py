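import pytest

from tdmdkit.simulate import SimConfig, make_mirna_family, make_transcriptome


@pytest.fixture(scope="session")
def cfg():
    return SimConfig(rng_seed=7)


@pytest.fixture(scope="session")
def family(cfg):
    return make_mirna_family(cfg)


@pytest.fixture(scope="session")
def transcriptome(cfg, family):
    """(transcripts, truth) for the default planted study."""
    return make_transcriptome(cfg, family)
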