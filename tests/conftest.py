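import numpy as np
import pytest

from splicetree.genome import GeneModel, Transcript
from splicetree.simulate import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def toy_transcript() -> Transcript:
    """Plus-strand 3-exon transcript; exons end/start at round coordinates.

    Exon1 ends at 1-based 1000, intron1 = 1001..1099, exon2 = 1100..1199,
    intron2 = 1200..1399, exon3 = 1400..1500.
    """
    return Transcript(
        "tx1", exons=[(899, 1000), (1099, 1199), (1399, 1500)], strand="+"
    )


@pytest.fixture(scope="session")
def toy_gene(toy_transcript) -> GeneModel:
    return GeneModel("g1", "chr1", "+", [toy_transcript])


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete small synthetic dataset shared across tests."""
    out = tmp_path_factory.mktemp("fixtures")
    cfg = SyntheticConfig(seed=11)
    paths = simulate_dataset(cfg, out)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
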