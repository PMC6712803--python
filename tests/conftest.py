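import pytest

from retroexome.core import GeneModel, GenomicInterval, MateAlignment, AlignedPairRecord
from retroexome.simulate import Genome, SimulationConfig, make_genome


@pytest.fixture
def three_exon_gene() -> GeneModel:
    """200-bp exons at [1000,1200), [1500,1700), [2000,2200): two 300-bp
    introns, 600-bp cDNA."""
    return GeneModel(
        "G",
        "chr1",
        "+",
        (
            GenomicInterval("chr1", 1000, 1200, "+"),
            GenomicInterval("chr1", 1500, 1700, "+"),
            GenomicInterval("chr1", 2000, 2200, "+"),
        ),
    )


@pytest.fixture
def small_genome() -> Genome:
    cfg = SimulationConfig(seed=11, n_genes=6, exon_count_range=(2, 6))
    return make_genome(cfg)


def make_pair(
    m1=(1050, 1150),
    m2=(1550, 1650),
    mapq=(60, 60),
    chrom="chr1",
    sample="s",
    fragment="f",
) -> AlignedPairRecord:
    return AlignedPairRecord(
        sample_id=sample,
        fragment_id=fragment,
        chrom=chrom,
        mate1=MateAlignment(m1[0], m1[1], mapq[0]),
        mate2=MateAlignment(m2[0], m2[1], mapq[1]),
    )
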