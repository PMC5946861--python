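"""Genome-based superTranscript construction.

For each flattened gene, its exonic sequence is extracted from the genome
and concatenated in transcriptional order: exons in ascending genomic order,
with the whole concatenation reverse-complemented for minus-strand genes.
The block list records which genome interval every superTranscript segment
came from, keeping the genome <-> superTranscript coordinate map invertible.

Assembly gaps (N runs) in the genome are preserved verbatim, so they remain
visible to the reassembly stage, which may repair them with de novo sequence.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence, Union

import pyfaidx

from .io import read_fasta, write_fasta
from .models import FlatGene, GenomicInterval, STBlock, SuperTranscript

__all__ = [
    "reverse_complement",
    "build_genome_supertranscripts",
    "write_supertranscriptome",
    "read_supertranscriptome",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_genome(genome) -> Mapping[str, str]:
    """Accept a path (FASTA, faidx-indexed access), a pyfaidx.Fasta, or a
    plain id -> sequence mapping."""
    if isinstance(genome, (str, Path)):
        return pyfaidx.Fasta(str(genome), sequence_always_upper=True)
    return genome


def build_genome_supertranscripts(
    flat: Sequence[FlatGene],
    genome: Union[str, Path, Mapping[str, str]],
) -> list[SuperTranscript]:
    """Extract and concatenate each flat gene's exonic sequence.

    Plus-strand genes concatenate exon subsequences in ascending genomic
    order; minus-strand genes additionally reverse-complement the whole
    concatenation so the superTranscript reads in transcriptional order.
    Strand "." genes are emitted in "+" orientation with a logged warning.
    Output sequence is uppercase.

    Raises
    ------
    KeyError
        If a gene's chromosome is absent from the genome FASTA.
    ValueError
        If an exon extends beyond its chromosome end.
    """
    fasta = _open_genome(genome)
    out = []
    for gene in flat:
        try:
            chrom_seq = fasta[gene.chrom]
        except KeyError:
            raise KeyError(
                f"gene {gene.gene_id}: chromosome {gene.chrom!r} absent from genome"
            ) from None
        chrom_len = len(chrom_seq)
        parts = []
        for exon in gene.exons:
            if exon.end > chrom_len:
                raise ValueError(
                    f"gene {gene.gene_id}: exon {exon.start}-{exon.end} exceeds "
                    f"{gene.chrom} length {chrom_len}"
                )
            parts.append(str(chrom_seq[exon.start - 1 : exon.end]).upper())
        if gene.strand == "-":
            sequence = reverse_complement("".join(parts))
            ordered = list(reversed(gene.exons))  # transcriptional order
        else:
            if gene.strand == ".":
                logger.warning(
                    "gene %s has strand '.'; emitting in '+' orientation", gene.gene_id
                )
            sequence = "".join(parts)
            ordered = list(gene.exons)
        blocks = []
        pos = 1
        for exon in ordered:
            blocks.append(STBlock(pos, pos + len(exon) - 1, exon))
            pos += len(exon)
        out.append(SuperTranscript(gene.gene_id, sequence, blocks))
    return out


def _block_gtf_lines(st: SuperTranscript):
    for i, b in enumerate(st.blocks, start=1):
        if b.source is None:
            provenance = "inserted"
        else:
            s = b.source
            provenance = f"{s.chrom}:{s.start}-{s.end}({s.strand})"
        attr = (
            f'gene_id "{st.gene_id}"; transcript_id "{st.gene_id}"; '
            f'block_id "{st.gene_id}:block{i}"; source_interval "{provenance}";'
        )
        yield "\t".join(
            [st.gene_id, "supertx", "exon", str(b.start), str(b.end), ".", "+", ".", attr]
        )


def write_supertranscriptome(
    sts: Sequence[SuperTranscript],
    fasta_path: Union[str, Path],
    map_path: Union[str, Path, None] = None,
) -> None:
    """Write the superTranscriptome FASTA (keyed by gene id) plus a companion
    block GTF on superTranscript coordinates recording each block's genome
    provenance (or "inserted" for de novo-only sequence).

    Raises
    ------
    ValueError
        On duplicate gene ids.
    """
    seen = set()
    for st in sts:
        if st.gene_id in seen:
            raise ValueError(f"duplicate superTranscript id {st.gene_id!r}")
        seen.add(st.gene_id)
    write_fasta(((st.gene_id, st.sequence) for st in sts), fasta_path)
    if map_path is not None:
        with open(map_path, "w") as fh:
            fh.write("# superTranscript block map; coordinates are superTranscript-local\n")
            for st in sts:
                for line in _block_gtf_lines(st):
                    fh.write(line + "\n")


def read_supertranscriptome(fasta_path: Union[str, Path]) -> list[SuperTranscript]:
    """Re-read a superTranscriptome FASTA written by
    :func:`write_supertranscriptome` (blocks reduce to one unannotated block
    per record; the block map GTF carries full provenance)."""
    return [
        SuperTranscript(name, seq, [STBlock(1, len(seq), None)])
        for name, seq in read_fasta(fasta_path).items()
    ]
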