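import pytest

from mirconsensus.energy import load_parameters
from mirconsensus.sites import MatureMiRNA, Region, TranscriptRecord
from mirconsensus.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def mir100():
    return MatureMiRNA(name="miR-100", sequence="AACCCGUAGAUCCGAACUUGUG")


@pytest.fixture
def toy_transcript():
    """100-nt transcript, regions 5UTR 1-20 / CDS 21-70 / 3UTR 71-100."""
    return TranscriptRecord(
        id="TOY1",
        sequence="A" * 100,
        regions=(Region("5UTR", 1, 20), Region("CDS", 21, 70), Region("3UTR", 71, 100)),
    )


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(GeneratorConfig(), seed=7)


@pytest.fixture(scope="session")
def noise_free_dataset():
    return generate_dataset(GeneratorConfig(noise_sd=0.0, ct_noise_sd=0.0), seed=13)
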