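import numpy as np
import pytest

from regindel.core_io import GenomeSequence, Variant
from regindel.variant_sets import EqtlRecord


@pytest.fixture
def toy_genome() -> GenomeSequence:
    return GenomeSequence({"c1": "ACGTACGTACGTACGT", "c2": "GGGGCCCCAAAATTTT"})


@pytest.fixture
def random_genome() -> GenomeSequence:
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return GenomeSequence(
        {"chr1": "".join(bases[rng.integers(0, 4, size=20_000)])}
    )


def make_record(
    chrom="c1",
    pos=100,
    ref="AC",
    alt="A",
    gene="g1",
    dist=50_000,
    q=0.01,
    maf=0.2,
) -> EqtlRecord:
    return EqtlRecord(Variant(chrom, pos, ref, alt), gene, dist, q, maf)


@pytest.fixture
def record_factory():
    return make_record
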