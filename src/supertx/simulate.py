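"""Self-contained synthetic test worlds with planted ground truth.

A world contains a small genome, reference and assembled annotations, a
related-species genome with coding annotation, de novo contigs, and
alignments (PSL and SAM) — everything the pipeline consumes — generated
deterministically from a seed.  Alignments are synthesized from the known
source coordinates of every sequence instead of running an aligner, which
keeps the fixtures hermetic and byte-reproducible.

Planted structures mirror the failure modes of incomplete genomes:

* **gap genes** — the genome copy of one exon has a segment replaced by a
  short run of Ns (an assembly gap), while contigs and reads carry the real
  sequence, so reassembly can be scored on repairing it;
* **novel genes** — present only in the related species' coding annotation
  and among the contigs, absent from the main genome;
* **chimeric contigs** — fusions of two genes' sequence that the clustering
  stage must remove;
* **unmatched contigs** — random sequence matching nothing.

Every planted fact is recorded in the truth tables, which are sufficient to
score each pipeline stage.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import write_fasta, write_gtf, write_psl
from .models import GeneModel, GenomicInterval, PslHit, Transcript

__all__ = [
    "FixtureSpec",
    "World",
    "SimGene",
    "SimFragment",
    "generate_world",
    "generate_alignments",
    "simulate_fragments",
    "project_fragments",
    "write_sam",
    "VARIANTS",
]

_BASES = np.array(list("ACGT"))

# the three reference "variants" a gene's superTranscript can be built from:
# complete  - the true transcribed sequence (what a perfect merge recovers)
# genome    - as encoded in the genome (assembly gaps as N runs)
# reference - exons present in the reference annotation only
VARIANTS = ("complete", "genome", "reference_only")


@dataclass
class FixtureSpec:
    """Parameters of a synthetic world.  Defaults give a compact world that
    still exercises every pipeline branch: multi-exon genes on both strands,
    an assembly-gap gene, a novel gene backed by the related species, one
    chimeric and one unmatched contig."""

    seed: int = 0
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (120, 400)
    intron_length: tuple[int, int] = (60, 300)
    intergenic_length: tuple[int, int] = (200, 500)
    frac_minus_strand: float = 0.4
    n_gap_genes: int = 1
    gap_insert_length: int = 220
    gap_n_run: int = 20
    n_novel_genes: int = 1
    n_chimeric_contigs: int = 1
    n_unmatched_contigs: int = 1
    contig_error_rate: float = 0.0
    n_fragments: int = 60
    n_samples: int = 2
    fragment_length: int = 200
    read_length: int = 70
    frac_spliced: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_gap_genes",
            "n_novel_genes",
            "n_chimeric_contigs",
            "n_unmatched_contigs",
            "n_fragments",
            "n_samples",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_minus_strand", "contig_error_rate", "frac_spliced"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")
        if self.fragment_length > self.exons_per_gene[0] * self.exon_length[0]:
            raise ValueError(
                "fragment_length exceeds the minimum possible gene length; "
                "no fragment could be placed"
            )
        if self.n_gap_genes + 2 * min(1, self.n_chimeric_contigs) > self.n_genes:
            raise ValueError("not enough genes for the requested gap/chimera structure")
        if self.gap_n_run >= self.gap_insert_length:
            raise ValueError("gap_n_run must be smaller than gap_insert_length")


@dataclass
class SimGene:
    """One simulated gene with its true (complete) superTranscript sequence
    and its genomic encoding."""

    gene_id: str
    chrom: str
    strand: str
    exon_lens: list[int]  # transcript order, true lengths
    true_st: str  # complete superTranscript (transcriptional order)
    genome_exons: list[GenomicInterval] = field(default_factory=list)
    hidden: Optional[tuple[int, int]] = None  # true-ST coords absent from genome
    n_run: int = 0  # length of the N run standing in for `hidden`
    ref_exon_count: int = 0  # transcript-order exons present in the reference GTF
    junction: Optional[tuple[int, int]] = None  # planted skip span, true-ST coords

    @property
    def length(self) -> int:
        return len(self.true_st)

    def variant_pieces(self, variant: str) -> Optional[list[tuple]]:
        """How this gene's ``variant`` superTranscript is built from the true
        one: a list of ("T", start, end) copies (1-based true coords) and
        ("N", length) gap fillers, in superTranscript order."""
        L = self.length
        if variant == "complete":
            return [("T", 1, L)]
        if variant == "genome":
            if self.hidden is None:
                return [("T", 1, L)]
            hs, he = self.hidden
            return [("T", 1, hs - 1), ("N", self.n_run), ("T", he + 1, L)]
        if variant == "reference_only":
            if self.ref_exon_count == 0:
                return None  # gene absent from the reference annotation
            keep = sum(self.exon_lens[: self.ref_exon_count])
            pieces: list[tuple] = []
            if self.hidden is not None and self.hidden[0] <= keep:
                hs, he = self.hidden
                pieces = [("T", 1, hs - 1), ("N", self.n_run), ("T", he + 1, keep)]
            else:
                pieces = [("T", 1, keep)]
            return pieces
        raise ValueError(f"unknown variant {variant!r}")

    def variant_length(self, variant: str) -> Optional[int]:
        pieces = self.variant_pieces(variant)
        if pieces is None:
            return None
        return sum(p[1] if p[0] == "N" else p[2] - p[1] + 1 for p in pieces)

    def map_interval(self, variant: str, start: int, end: int) -> Optional[tuple[int, int]]:
        """Map a true-ST interval (1-based inclusive) into ``variant``
        coordinates, or None when it is not contiguously representable
        there (it touches hidden or annotation-absent sequence)."""
        pieces = self.variant_pieces(variant)
        if pieces is None:
            return None
        offset = 0
        for p in pieces:
            if p[0] == "N":
                offset += p[1]
                continue
            _, ts, te = p
            if ts <= start and end <= te:
                return (offset + start - ts + 1, offset + end - ts + 1)
            offset += te - ts + 1
        return None


@dataclass
class Truth:
    """Planted ground truth, sufficient to score every stage."""

    contig_fates: "OrderedDict[str, tuple[str, str]]"
    gap_genes: dict  # gene_id -> {hidden_start, hidden_end, insert_length, n_run, gain}
    novel_genes: dict  # related gene id -> its sequence length
    junctions: dict  # st_id -> (start, end) in complete-ST coordinates

    def to_json(self) -> str:
        return json.dumps(
            {
                "contig_fates": {k: list(v) for k, v in self.contig_fates.items()},
                "gap_genes": self.gap_genes,
                "novel_genes": self.novel_genes,
                "junctions": {k: list(v) for k, v in self.junctions.items()},
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class World:
    spec: FixtureSpec
    genes: list[SimGene]
    genome: "OrderedDict[str, str]"
    reference: list[GeneModel]
    assembled: list[GeneModel]
    related_genes: list[SimGene]
    related_genome: "OrderedDict[str, str]"
    related_cds: list[GeneModel]
    contigs: "OrderedDict[str, str]"
    contig_errors: dict  # contig_id -> sorted list of mutated positions (0-based)
    contig_sources: dict  # contig_id -> (kind, payload) used for PSL synthesis
    truth: Truth

    def st_lengths(self, variant: str = "complete") -> "OrderedDict[str, int]":
        """Per-cluster superTranscript lengths under a reference variant.
        Known genes are keyed by gene id; novel genes by their final cluster
        id (``novel:<related gene id>``) and exist only in ``complete``."""
        out: "OrderedDict[str, int]" = OrderedDict()
        for g in self.genes:
            L = g.variant_length(variant)
            if L is not None:
                out[g.gene_id] = L
        if variant == "complete":
            for rg in self.related_genes:
                out[f"novel:{rg.gene_id}"] = rg.length
        return out

    def write(self, outdir) -> dict[str, Path]:
        """Write the world's files; returns a name -> path mapping."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "reference_gtf": outdir / "reference.gtf",
            "assembled_gtf": outdir / "assembled.gtf",
            "related_genome": outdir / "related_genome.fa",
            "related_cds_gtf": outdir / "related_cds.gtf",
            "contigs": outdir / "contigs.fa",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.genome, paths["genome"])
        write_gtf(self.reference, paths["reference_gtf"])
        write_gtf(self.assembled, paths["assembled_gtf"])
        write_fasta(self.related_genome, paths["related_genome"])
        write_gtf(self.related_cds, paths["related_cds_gtf"], feature="CDS")
        write_fasta(self.contigs, paths["contigs"])
        paths["truth"].write_text(self.truth.to_json())
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, list[int]]:
    if rate <= 0:
        return seq, []
    arr = np.array(list(seq))
    hits = np.where(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), [int(i) for i in hits]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _build_gene(
    rng: np.random.Generator, spec: FixtureSpec, idx: int, gap: bool
) -> SimGene:
    gene_id = f"G{idx + 1:03d}"
    strand = "-" if rng.random() < spec.frac_minus_strand else "+"
    if gap:
        # fixed layout guaranteeing long anchors on both sides of the gap and
        # a left flank > half the gene (so the repair contig still clusters)
        m = spec.gap_insert_length
        exon_lens = [400, 350, m + 120, 300]
    else:
        k = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exon_lens = [
            int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
            for _ in range(k)
        ]
    true_st = _random_seq(rng, sum(exon_lens))
    gene = SimGene(gene_id, "chr1", strand, exon_lens, true_st)
    if gap:
        m = spec.gap_insert_length
        off = (exon_lens[2] - m) // 2  # centred in exon 3
        hs = exon_lens[0] + exon_lens[1] + off + 1
        gene.hidden = (hs, hs + m - 1)
        gene.n_run = spec.gap_n_run
    k = len(exon_lens)
    truncated = (not gap) and k >= 3 and idx % 3 == 2
    gene.ref_exon_count = k - 1 if truncated else k
    if k >= 3:
        # planted skip of the second transcript-order exon
        j_start = exon_lens[0] + 1
        gene.junction = (j_start, j_start + exon_lens[1] - 1)
    return gene


def _place_gene(
    rng: np.random.Generator, spec: FixtureSpec, gene: SimGene, chrom_parts: list[str], cursor: int
) -> int:
    """Append the gene's genomic encoding to the chromosome and fill in its
    genome exon coordinates.  Returns the new cursor (1-based length so far)."""
    spacer = int(rng.integers(spec.intergenic_length[0], spec.intergenic_length[1] + 1))
    chrom_parts.append(_random_seq(rng, spacer))
    cursor += spacer
    # genome copy of each exon, transcript order
    exon_seqs = []
    cum = 0
    for j, ln in enumerate(gene.exon_lens):
        seq = gene.true_st[cum : cum + ln]
        if gene.hidden is not None:
            hs, he = gene.hidden
            # hidden segment lies inside exon j when its true-ST span does
            if cum < hs <= cum + ln:
                seq = seq[: hs - 1 - cum] + "N" * gene.n_run + seq[he - cum :]
        exon_seqs.append(seq)
        cum += ln
    if gene.strand == "-":
        genomic_order = [(_revcomp(s), j) for s, j in zip(reversed(exon_seqs), reversed(range(len(exon_seqs))))]
    else:
        genomic_order = [(s, j) for j, s in enumerate(exon_seqs)]
    introns = [
        int(rng.integers(spec.intron_length[0], spec.intron_length[1] + 1))
        for _ in range(len(exon_seqs) - 1)
    ]
    coords: dict[int, GenomicInterval] = {}
    for i, (seq, j) in enumerate(genomic_order):
        start = cursor + 1
        end = cursor + len(seq)
        chrom_parts.append(seq)
        cursor = end
        coords[j] = GenomicInterval(gene.chrom, start, end, gene.strand)
        if i < len(genomic_order) - 1:
            chrom_parts.append(_random_seq(rng, introns[i]))
            cursor += introns[i]
    gene.genome_exons = [coords[j] for j in sorted(coords, key=lambda j: coords[j].start)]
    return cursor


def _annotation_models(genes: list[SimGene]) -> tuple[list[GeneModel], list[GeneModel]]:
    reference, assembled = [], []
    for gene in genes:
        tx_exons = gene_tx_exons(gene)
        ref_exons = [tx_exons[j] for j in range(gene.ref_exon_count)]
        transcripts = [Transcript(f"{gene.gene_id}.ref1", "reference", ref_exons)]
        if gene.ref_exon_count >= 2:
            transcripts.append(
                Transcript(f"{gene.gene_id}.ref2", "reference", ref_exons[:2])
            )
        reference.append(GeneModel(gene.gene_id, gene.chrom, gene.strand, transcripts))
        assembled.append(
            GeneModel(
                f"ASM.{gene.gene_id}",
                gene.chrom,
                gene.strand,
                [Transcript(f"{gene.gene_id}.asm1", "assembled", list(tx_exons))],
            )
        )
    return reference, assembled


def gene_tx_exons(gene: SimGene) -> list[GenomicInterval]:
    """Genome exons in transcriptional order (reverse genomic for '-')."""
    exons = list(gene.genome_exons)
    return exons[::-1] if gene.strand == "-" else exons


def generate_world(spec: FixtureSpec, outdir=None) -> World:
    """Generate a world from a spec.  Deterministic per seed: the same spec
    yields byte-identical files.  When ``outdir`` is given the files are
    written there as well."""
    rng = np.random.default_rng([int(spec.seed), 11])
    genes = [
        _build_gene(rng, spec, i, gap=i < spec.n_gap_genes) for i in range(spec.n_genes)
    ]
    chrom_parts: list[str] = []
    cursor = 0
    for gene in genes:
        cursor = _place_gene(rng, spec, gene, chrom_parts, cursor)
    chrom_parts.append(_random_seq(rng, 200))
    genome = OrderedDict([("chr1", "".join(chrom_parts))])

    reference, assembled = _annotation_models(genes)

    # related species: novel genes only (absent from the main genome)
    related_genes: list[SimGene] = []
    rel_parts: list[str] = []
    rel_cursor = 0
    related_cds: list[GeneModel] = []
    for i in range(spec.n_novel_genes):
        gid = f"HOM{i + 1:03d}"
        strand = "-" if rng.random() < spec.frac_minus_strand else "+"
        k = int(rng.integers(2, 4))
        exon_lens = [
            int(rng.integers(max(spec.exon_length[0], 150), spec.exon_length[1] + 1))
            for _ in range(k)
        ]
        rg = SimGene(gid, "h1", strand, exon_lens, _random_seq(rng, sum(exon_lens)))
        rg.ref_exon_count = k
        rel_cursor = _place_gene(rng, spec, rg, rel_parts, rel_cursor)
        related_genes.append(rg)
        related_cds.append(
            GeneModel(gid, "h1", strand, [Transcript(f"{gid}.1", "reference", gene_tx_exons(rg))])
        )
    rel_parts.append(_random_seq(rng, 100))
    related_genome = OrderedDict([("h1", "".join(rel_parts))])

    # contigs
    contigs: "OrderedDict[str, str]" = OrderedDict()
    contig_errors: dict[str, list[int]] = {}
    contig_sources: dict[str, tuple] = {}
    fates: "OrderedDict[str, tuple[str, str]]" = OrderedDict()
    for i, gene in enumerate(genes):
        cid = f"contig_{gene.gene_id}_1"
        seq, errs = _mutate(rng, gene.true_st, spec.contig_error_rate)
        contigs[cid] = seq
        contig_errors[cid] = errs
        contig_sources[cid] = ("known", gene.gene_id, 1, gene.length)
        fates[cid] = ("known", gene.gene_id)
        if gene.hidden is None and i % 2 == 1:
            L = gene.length
            start = L // 5
            length = max(int(0.6 * L), 150)
            end = min(start + length, L)
            cid2 = f"contig_{gene.gene_id}_2"
            seq2, errs2 = _mutate(rng, gene.true_st[start:end], spec.contig_error_rate)
            contigs[cid2] = seq2
            contig_errors[cid2] = errs2
            contig_sources[cid2] = ("known", gene.gene_id, start + 1, end)
            fates[cid2] = ("known", gene.gene_id)
    for i, rg in enumerate(related_genes):
        cid = f"contig_novel_{rg.gene_id}"
        seq, errs = _mutate(rng, rg.true_st, spec.contig_error_rate)
        contigs[cid] = seq
        contig_errors[cid] = errs
        contig_sources[cid] = ("novel", rg.gene_id, 1, rg.length)
        fates[cid] = ("novel", f"novel:{rg.gene_id}")
    non_gap = [g for g in genes if g.hidden is None]
    for c in range(spec.n_chimeric_contigs):
        a = non_gap[(2 * c) % len(non_gap)]
        b = non_gap[(2 * c + 1) % len(non_gap)]
        x = min(a.length, b.length) // 2
        cid = f"contig_chimera_{c + 1}"
        contigs[cid] = a.true_st[:x] + b.true_st[:x]
        contig_errors[cid] = []
        contig_sources[cid] = ("chimera", a.gene_id, b.gene_id, x)
        fates[cid] = ("filtered_chimeric", "")
    for c in range(spec.n_unmatched_contigs):
        cid = f"contig_unmatched_{c + 1}"
        contigs[cid] = _random_seq(rng, 300)
        contig_errors[cid] = []
        contig_sources[cid] = ("unmatched",)
        fates[cid] = ("filtered_unmatched", "")

    gap_truth = {}
    for gene in genes:
        if gene.hidden is not None:
            hs, he = gene.hidden
            gap_truth[gene.gene_id] = {
                "hidden_start": hs,
                "hidden_end": he,
                "insert_length": he - hs + 1,
                "n_run": gene.n_run,
                "gain": (he - hs + 1) - gene.n_run,
            }
    junction_truth = {g.gene_id: g.junction for g in genes if g.junction is not None}
    truth = Truth(
        contig_fates=fates,
        gap_genes=gap_truth,
        novel_genes={rg.gene_id: rg.length for rg in related_genes},
        junctions=junction_truth,
    )
    world = World(
        spec=spec,
        genes=genes,
        genome=genome,
        reference=reference,
        assembled=assembled,
        related_genes=related_genes,
        related_genome=related_genome,
        related_cds=related_cds,
        contigs=contigs,
        contig_errors=contig_errors,
        contig_sources=contig_sources,
        truth=truth,
    )
    if outdir is not None:
        world.write(outdir)
    return world


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def _count_errors(errors: list[int], q_start: int, q_end: int) -> int:
    """Errors (0-based contig positions) within [q_start, q_end)."""
    return sum(1 for p in errors if q_start <= p < q_end)


def contig_hits_genome(world: World) -> list[PslHit]:
    """PSL hits of every contig against the genome-based superTranscriptome,
    computed from known source coordinates (one hit per contiguously
    alignable run; assembly-gap segments interrupt the alignment)."""
    hits = []
    gene_of = {g.gene_id: g for g in world.genes}
    for cid, seq in world.contigs.items():
        src = world.contig_sources[cid]
        errs = world.contig_errors[cid]
        if src[0] == "known":
            gene = gene_of[src[1]]
            c_start, c_end = src[2], src[3]  # true-ST coords of the contig
            tsize = gene.variant_length("genome")
            for piece in gene.variant_pieces("genome"):
                if piece[0] == "N":
                    continue
                _, ts, te = piece
                o_s, o_e = max(ts, c_start), min(te, c_end)
                if o_e - o_s + 1 < 50:
                    continue
                q_start = o_s - c_start
                q_end = o_e - c_start + 1
                t_span = gene.map_interval("genome", o_s, o_e)
                matches = (q_end - q_start) - _count_errors(errs, q_start, q_end)
                hits.append(
                    PslHit(
                        query_name=cid,
                        target_name=gene.gene_id,
                        matches=matches,
                        query_size=len(seq),
                        query_start=q_start,
                        query_end=q_end,
                        target_size=tsize,
                        target_start=t_span[0] - 1,
                        target_end=t_span[1],
                    )
                )
        elif src[0] == "chimera":
            _, gid_a, gid_b, x = src
            for half, gid in enumerate((gid_a, gid_b)):
                gene = gene_of[gid]
                hits.append(
                    PslHit(
                        query_name=cid,
                        target_name=gid,
                        matches=x,
                        query_size=len(seq),
                        query_start=half * x,
                        query_end=(half + 1) * x,
                        target_size=gene.variant_length("genome"),
                        target_start=0,
                        target_end=gene.map_interval("genome", 1, x)[1],
                    )
                )
        # novel and unmatched contigs produce no genome hits
    return hits


def contig_hits_related(world: World) -> list[PslHit]:
    """PSL hits against the related species' coding superTranscriptome
    (novel contigs only; everything else has no related match)."""
    hits = []
    rel_of = {g.gene_id: g for g in world.related_genes}
    for cid, seq in world.contigs.items():
        src = world.contig_sources[cid]
        if src[0] != "novel":
            continue
        rg = rel_of[src[1]]
        errs = world.contig_errors[cid]
        hits.append(
            PslHit(
                query_name=cid,
                target_name=rg.gene_id,
                matches=len(seq) - len(errs),
                query_size=len(seq),
                query_start=0,
                query_end=len(seq),
                target_size=rg.length,
                target_start=0,
                target_end=rg.length,
            )
        )
    return hits


@dataclass
class SimFragment:
    """One simulated read pair in complete-ST (true) coordinates."""

    name: str
    st_id: str
    # per mate: (sorted exonic intervals, junction spans), 1-based inclusive
    mates: list[tuple[list[tuple[int, int]], list[tuple[int, int]]]]


def _mate_in_true_coords(
    a0: int, a1: int, junction: Optional[tuple[int, int]], spliced: bool
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Isoform-coordinate half-open span [a0, a1) -> true-ST intervals,
    splitting over the skipped junction when the mate crosses it."""
    if not spliced or junction is None:
        return [(a0 + 1, a1)], []
    j_s, j_e = junction
    jlen = j_e - j_s + 1
    cut = j_s - 1  # isoform 0-based position where the skip sits
    if a1 <= cut:
        return [(a0 + 1, a1)], []
    if a0 >= cut:
        return [(a0 + jlen + 1, a1 + jlen)], []
    return [(a0 + 1, cut), (j_e + 1, a1 + jlen)], [(j_s, j_e)]


def simulate_fragments(world: World) -> "OrderedDict[str, list[SimFragment]]":
    """Simulate paired-end fragments per sample on the complete
    superTranscriptome (known genes plus novel clusters).  A fraction of
    fragments from genes with a planted junction use the spliced isoform,
    so their reads carry CIGAR N spans over the skipped interval."""
    spec = world.spec
    rng = np.random.default_rng([int(spec.seed), 101])
    targets: list[tuple[str, int, Optional[tuple[int, int]]]] = [
        (g.gene_id, g.length, g.junction) for g in world.genes
    ] + [(f"novel:{rg.gene_id}", rg.length, None) for rg in world.related_genes]
    out: "OrderedDict[str, list[SimFragment]]" = OrderedDict()
    for s in range(spec.n_samples):
        sample = f"sample_{s + 1}"
        frags: list[SimFragment] = []
        for st_id, L, junction in targets:
            for n in range(spec.n_fragments):
                spliced = junction is not None and rng.random() < spec.frac_spliced
                iso_len = L - (junction[1] - junction[0] + 1) if spliced else L
                flen = min(spec.fragment_length, iso_len)
                start = int(rng.integers(0, iso_len - flen + 1))
                rl = spec.read_length
                m1 = _mate_in_true_coords(start, start + rl, junction, spliced)
                m2 = _mate_in_true_coords(start + flen - rl, start + flen, junction, spliced)
                name = f"{sample}:{st_id}:frag{n + 1}"
                frags.append(SimFragment(name, st_id, [m1, m2]))
        out[sample] = frags
    return out


def project_fragments(
    world: World,
    fragments: "OrderedDict[str, list[SimFragment]]",
    variant: str = "complete",
) -> "OrderedDict[str, list[SimFragment]]":
    """Project true-coordinate fragments onto a reference variant, dropping
    fragments that touch sequence absent from that variant (exactly the
    reads an aligner would fail to place)."""
    gene_of = {g.gene_id: g for g in world.genes}
    out: "OrderedDict[str, list[SimFragment]]" = OrderedDict()
    for sample, frags in fragments.items():
        kept: list[SimFragment] = []
        for frag in frags:
            if frag.st_id.startswith("novel:"):
                if variant == "complete":
                    kept.append(frag)
                continue  # novel genes exist only in the final superTranscriptome
            gene = gene_of[frag.st_id]
            mates = []
            ok = True
            for intervals, junctions in frag.mates:
                new_iv, new_j = [], []
                for s, e in intervals:
                    m = gene.map_interval(variant, s, e)
                    if m is None:
                        ok = False
                        break
                    new_iv.append(m)
                if not ok:
                    break
                for s, e in junctions:
                    m = gene.map_interval(variant, s, e)
                    if m is None:
                        ok = False
                        break
                    new_j.append(m)
                if not ok:
                    break
                mates.append((new_iv, new_j))
            if ok:
                kept.append(SimFragment(frag.name, frag.st_id, mates))
        out[sample] = kept
    return out


def as_aligned_fragments(fragments):
    """Convert simulated fragments (one sample's list, or a mapping of
    sample -> list) to the counting stage's :class:`AlignedFragment` form
    without a SAM round trip."""
    from .models import AlignedFragment, MateAlignment

    if hasattr(fragments, "items"):
        return OrderedDict(
            (sample, as_aligned_fragments(frags)) for sample, frags in fragments.items()
        )
    return [
        AlignedFragment(
            f.name, [MateAlignment(f.st_id, list(iv), list(jn)) for iv, jn in f.mates]
        )
        for f in fragments
    ]


def write_sam(
    fragments: list[SimFragment], st_lengths: "OrderedDict[str, int]", path
) -> None:
    """Emit fragments as a coordinate-unsorted SAM file (no base sequences;
    the pipeline never needs them)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for st, L in st_lengths.items():
            fh.write(f"@SQ\tSN:{st}\tLN:{L}\n")
        for frag in fragments:
            (iv1, j1), (iv2, j2) = frag.mates
            pos1, pos2 = iv1[0][0], iv2[0][0]
            end2 = iv2[-1][1]
            tlen = end2 - pos1 + 1
            for flag, iv, jn, pos, pnext, tl in (
                (99, iv1, j1, pos1, pos2, tlen),
                (147, iv2, j2, pos2, pos1, -tlen),
            ):
                cigar = _cigar(iv, jn)
                fh.write(
                    f"{frag.name}\t{flag}\t{frag.st_id}\t{pos}\t60\t{cigar}\t=\t"
                    f"{pnext}\t{tl}\t*\t*\n"
                )


def _cigar(intervals: list[tuple[int, int]], junctions: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(intervals):
        parts.append(f"{e - s + 1}M")
        if i < len(intervals) - 1:
            js, je = junctions[i]
            parts.append(f"{je - js + 1}N")
    return "".join(parts)


def generate_alignments(
    world: World, outdir, variant: str = "complete"
) -> dict[str, Path]:
    """Write the alignment files an aligner would produce for this world:
    contig-vs-superTranscriptome PSLs and one SAM per sample against the
    requested reference variant.  Returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {
        "psl_genome": outdir / "contigs_vs_genome_st.psl",
        "psl_related": outdir / "contigs_vs_related_st.psl",
    }
    write_psl(contig_hits_genome(world), paths["psl_genome"], header=True)
    write_psl(contig_hits_related(world), paths["psl_related"])
    st_lengths = world.st_lengths(variant)
    fragments = project_fragments(world, simulate_fragments(world), variant)
    for sample, frags in fragments.items():
        p = outdir / f"{sample}.sam"
        write_sam(frags, st_lengths, p)
        paths[f"sam:{sample}"] = p
    return paths
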