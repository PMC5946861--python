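import numpy as np
import pytest

from supertx.models import GeneModel, GenomicInterval, Transcript
from supertx.simulate import FixtureSpec, generate_world

BASES = "ACGT"


@pytest.fixture(scope="session")
def world():
    """A compact synthetic world exercising every pipeline branch."""
    return generate_world(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def plain_world():
    """Degenerate world: no gaps, no novel genes, no chimeras, no junk."""
    return generate_world(
        FixtureSpec(
            seed=1,
            n_genes=10,
            n_gap_genes=0,
            n_novel_genes=0,
            n_chimeric_contigs=0,
            n_unmatched_contigs=0,
        )
    )


def random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def random_gene(rng, gene_id, chrom="chr1", origin=1):
    """A random gene model with 1-3 transcripts of non-overlapping exons."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 6))
    exons = []
    pos = origin + int(rng.integers(0, 50))
    for _ in range(n_exons):
        length = int(rng.integers(20, 200))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(20, 100))
    transcripts = []
    for t in range(int(rng.integers(1, 4))):
        take = sorted(
            rng.choice(n_exons, size=int(rng.integers(1, n_exons + 1)), replace=False)
        )
        transcripts.append(
            Transcript(
                f"{gene_id}.t{t + 1}",
                "reference",
                [GenomicInterval(chrom, s, e, strand) for s, e in (exons[i] for i in take)],
            )
        )
    return GeneModel(gene_id, chrom, strand, transcripts), pos


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_genes(rng):
    genes = []
    pos = 1
    for i in range(200):
        gene, pos = random_gene(rng, f"R{i:04d}", origin=pos + 100)
        genes.append(gene)
    return genes
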