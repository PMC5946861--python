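"""Combine assembled and reference annotations, then flatten genes to
nonredundant exon sets.

The combine step groups transcripts into genes by genomic locus: an
assembled transcript that shares exonic sequence with exactly one reference
gene joins it; one that bridges two or more reference genes unions those
genes into a single locus (incomplete genomes often annotate segments of one
gene as separate genes); one that overlaps nothing is kept as a candidate
novel locus.  Flattening then merges each gene's transcripts into a
nonredundant but complete set of exons, so each exonic base is represented
exactly once.
"""

from __future__ import annotations

from collections import OrderedDict, defaultdict
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .models import FlatGene, GeneModel, GenomicInterval, Transcript

__all__ = [
    "merge_annotations",
    "flatten",
    "flatten_genes",
    "flatten_cds_annotation",
    "merge_intervals",
    "flat_to_gene_models",
]


def _strands_compatible(a: str, b: str) -> bool:
    """Antisense overlap does not merge loci; '.' is compatible with both."""
    return a == "." or b == "." or a == b


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # deterministic: smaller index is the root
            if ri > rj:
                ri, rj = rj, ri
            self.parent[rj] = ri


def merge_annotations(
    reference: Sequence[GeneModel], assembled: Sequence[GeneModel]
) -> list[GeneModel]:
    """Combine a genome-guided assembly annotation with the reference.

    Every assembled transcript is tested for exonic overlap (>= 1 bp, same
    chromosome, strand-compatible) against the reference genes:

    * overlap with exactly one reference gene -> the transcript is
      re-labelled with that gene's id;
    * overlap with two or more reference genes -> those reference genes are
      unioned into a single merged gene whose id is the "+"-joined sorted
      list of member ids, and the bridging transcript joins it;
    * no overlap -> the transcript keeps its own gene id as a candidate
      novel locus.

    Reference transcripts are always retained; assembled transcripts are
    only re-labelled, merged or kept novel, never dropped.

    Raises
    ------
    ValueError
        If an assembled gene id collides with a reference gene id at a
        different locus (ids must be disambiguated upstream).
    """
    ref_ids = {g.gene_id for g in reference}
    # exonic interval index per chromosome -> reference gene index
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gi, gene in enumerate(reference):
        for exon in gene.all_exons():
            trees[gene.chrom].addi(exon.start, exon.end + 1, gi)

    uf = _UnionFind(len(reference))
    # assembled transcript -> set of overlapped reference gene indices
    overlaps_of: list[tuple[GeneModel, Transcript, frozenset[int]]] = []
    for agene in assembled:
        for tr in agene.transcripts:
            hit_idx = set()
            for exon in tr.exons:
                for iv in trees.get(agene.chrom, IntervalTree()).overlap(
                    exon.start, exon.end + 1
                ):
                    gi = iv.data
                    if _strands_compatible(agene.strand, reference[gi].strand):
                        hit_idx.add(gi)
            if not hit_idx and agene.gene_id in ref_ids:
                raise ValueError(
                    f"assembled gene id {agene.gene_id!r} duplicates a reference "
                    f"gene id at a different locus; disambiguate the inputs"
                )
            first = None
            for gi in sorted(hit_idx):
                if first is None:
                    first = gi
                else:
                    uf.union(first, gi)
            overlaps_of.append((agene, tr, frozenset(hit_idx)))

    # build merged reference components
    components: "OrderedDict[int, list[int]]" = OrderedDict()
    for gi in range(len(reference)):
        components.setdefault(uf.find(gi), []).append(gi)

    out: list[GeneModel] = []
    comp_gene: dict[int, GeneModel] = {}
    for root, members in components.items():
        member_genes = [reference[gi] for gi in members]
        gene_id = "+".join(sorted(g.gene_id for g in member_genes))
        strands = {g.strand for g in member_genes} - {"."}
        strand = strands.pop() if len(strands) == 1 else (
            "." if len(strands) != 1 else member_genes[0].strand
        )
        merged = GeneModel(
            gene_id,
            member_genes[0].chrom,
            strand,
            [t for g in member_genes for t in g.transcripts],
        )
        comp_gene[root] = merged
        out.append(merged)

    # attach assembled transcripts
    novel: "OrderedDict[str, GeneModel]" = OrderedDict()
    for agene, tr, hit_idx in overlaps_of:
        tr = Transcript(tr.transcript_id, "assembled", list(tr.exons), list(tr.exon_attrs))
        if hit_idx:
            comp_gene[uf.find(next(iter(hit_idx)))].transcripts.append(tr)
        else:
            g = novel.setdefault(
                agene.gene_id, GeneModel(agene.gene_id, agene.chrom, agene.strand, [])
            )
            g.transcripts.append(tr)
    out.extend(novel.values())
    return out


def merge_intervals(
    intervals: Iterable[GenomicInterval], merge_bookended: bool = True
) -> list[GenomicInterval]:
    """Union a set of same-chromosome intervals into sorted disjoint intervals.

    Bookended intervals (end + 1 == next start) are merged by default: the
    extracted sequence is identical either way and fewer blocks are simpler
    downstream.
    """
    ivs = sorted(intervals, key=lambda e: (e.start, e.end))
    if not ivs:
        return []
    merged: list[list[int]] = [[ivs[0].start, ivs[0].end]]
    chrom, strand = ivs[0].chrom, ivs[0].strand
    slack = 1 if merge_bookended else 0
    for iv in ivs[1:]:
        if iv.chrom != chrom:
            raise ValueError(f"cannot union intervals across {chrom} and {iv.chrom}")
        if iv.start <= merged[-1][1] + slack:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    return [GenomicInterval(chrom, s, e, strand) for s, e in merged]


def flatten(genes: Sequence[GeneModel]) -> list[FlatGene]:
    """Flatten each gene's transcripts into a nonredundant, complete exon set.

    Per gene, the exon intervals of all member transcripts are unioned;
    overlapping and bookended intervals are merged.  The set of covered
    bases is conserved exactly.  Output is sorted by (chrom, first exon
    start, gene_id).

    Raises
    ------
    ValueError
        If a gene has no exons.
    """
    out = []
    for gene in genes:
        exons = gene.all_exons()
        if not exons:
            raise ValueError(f"gene {gene.gene_id} has zero exons; cannot flatten")
        normalized = [
            GenomicInterval(gene.chrom, e.start, e.end, gene.strand) for e in exons
        ]
        out.append(FlatGene(gene.gene_id, gene.chrom, gene.strand, merge_intervals(normalized)))
    out.sort(key=lambda f: (f.chrom, f.exons[0].start, f.gene_id))
    return out


def flatten_cds_annotation(related: Sequence[GeneModel]) -> list[FlatGene]:
    """Flatten a related species' coding annotation (gene models parsed with
    ``feature="CDS"``) to one merged coding-exon set per gene.  Same contract
    as :func:`flatten`; kept separate because it feeds the related-species
    superTranscriptome used to validate de novo-only genes."""
    return flatten(related)


def flat_to_gene_models(flat: Sequence[FlatGene]) -> list[GeneModel]:
    """Represent flat genes as single-transcript gene models for GTF output
    (gene_id == transcript_id, one exon line per flat exon)."""
    return [
        GeneModel(
            f.gene_id,
            f.chrom,
            f.strand,
            [Transcript(f.gene_id, "reference", list(f.exons))],
        )
        for f in flat
    ]


# alias: lets callers that import the package namespace (where `flatten`
# names this function) still refer to the operation unambiguously
flatten_genes = flatten
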