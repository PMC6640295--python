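import numpy as np
import pytest

from pollenselect.io_formats import GeneModel
from pollenselect import synthetic_data as sd


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared by read-only tests."""
    cfg = sd.SimulationConfig(seed=42, n_chromosomes=2, genes_per_chromosome=30, n_strains=40)
    return sd.simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gene(seq_parts, strand="+", chrom="chr1", gene_id="g1", offset=0):
    """Build (GeneModel, chromosome string) from alternating exon/intron
    strings given in transcript sense for a + strand gene.

    ``seq_parts`` alternates exon, intron, exon, ...; for '-' strand the
    genomic sequence is the reverse complement of the concatenation.
    """
    from pollenselect.io_formats import reverse_complement

    locus = "".join(seq_parts)
    intervals = []
    pos = offset + 1
    for k, part in enumerate(seq_parts):
        if k % 2 == 0:
            intervals.append((pos, pos + len(part) - 1))
        pos += len(part)
    if strand == "-":
        genomic = "X" * offset + reverse_complement(locus)
        span_end = offset + len(locus)
        intervals = [
            (offset + 1 + (span_end - e), offset + 1 + (span_end - s))
            for s, e in intervals
        ]
        intervals_tx = sorted(intervals)[::-1]
    else:
        genomic = "X" * offset + locus
        intervals_tx = sorted(intervals)
    model = GeneModel(
        gene_id=gene_id, chromosome=chrom, strand=strand,
        cds_intervals=tuple(intervals_tx),
    )
    return model, genomic
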