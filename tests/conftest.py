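import numpy as np
import pytest

from vipmut.gene_context import GeneModel, GenomeSequence
from vipmut.synthetic import SynthConfig
from vipmut.study import SyntheticStudy, generate_study


@pytest.fixture
def toy_genome() -> GenomeSequence:
    # 150 bp; transcript with exons [0,50) and [100,150), CDS [10,140)
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))
    return GenomeSequence({"c1": seq})


@pytest.fixture
def toy_model() -> GeneModel:
    return GeneModel(
        id="t1", chrom="c1", strand="+",
        exons=[(0, 50), (100, 150)], cds_start=10, cds_end=138,
    )


@pytest.fixture
def toy_model_minus() -> GeneModel:
    return GeneModel(
        id="t1m", chrom="c1", strand="-",
        exons=[(0, 50), (100, 150)], cds_start=10, cds_end=138,
    )


@pytest.fixture(scope="session")
def small_study() -> SyntheticStudy:
    """A modest synthetic study shared by read-only tests."""
    cfg = SynthConfig(
        seed=11, n_genes=12, n_sbs=6000,
        intron_len=(300, 1500), intergenic_len=(200, 800),
    )
    return generate_study(cfg)
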