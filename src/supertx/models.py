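"""Core domain types shared by all pipeline stages.

Coordinate conventions
----------------------
Every interval exposed by this package is **1-based, fully inclusive**
(the GTF convention), with one deliberate exception: :class:`PslHit`
stores the PSL-native 0-based half-open query/target coordinates
verbatim, so that PSL files round-trip bit-faithfully.  Conversion
happens only at use sites (contig clustering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "FlatGene",
    "STBlock",
    "SuperTranscript",
    "PslHit",
    "MateAlignment",
    "AlignedFragment",
    "HitFilter",
    "ContigAssignment",
    "Cluster",
    "SpliceJunction",
    "Block",
    "CountTable",
    "FATE_KNOWN",
    "FATE_NOVEL",
    "FATE_CHIMERIC",
    "FATE_UNMATCHED",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval: ``start`` and ``end`` are 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class Transcript:
    """A transcript: an ordered list of exons on one chromosome.

    ``source`` tags where the transcript came from: ``"reference"`` for the
    curated annotation, ``"assembled"`` for genome-guided assembly output.
    ``exon_attrs`` optionally carries opaque leftover GTF attribute text per
    exon so foreign attributes survive a read/write round trip.
    """

    transcript_id: str
    source: str = "reference"
    exons: list[GenomicInterval] = field(default_factory=list)
    exon_attrs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.exon_attrs and len(self.exon_attrs) != len(self.exons):
            raise ValueError("exon_attrs must parallel exons")
        order = sorted(range(len(self.exons)), key=lambda i: self.exons[i].start)
        self.exons = [self.exons[i] for i in order]
        if self.exon_attrs:
            self.exon_attrs = [self.exon_attrs[i] for i in order]
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


@dataclass
class GeneModel:
    """A gene: a set of transcripts sharing a locus.

    All exons of all transcripts must lie on ``chrom``.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            for e in t.exons:
                if e.chrom != self.chrom:
                    raise ValueError(
                        f"gene {self.gene_id}: exon on {e.chrom}, gene on {self.chrom}"
                    )

    def all_exons(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]

    @property
    def span(self) -> GenomicInterval:
        exons = self.all_exons()
        if not exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        return GenomicInterval(
            self.chrom, min(e.start for e in exons), max(e.end for e in exons), self.strand
        )


@dataclass
class FlatGene:
    """A gene flattened to a nonredundant set of merged, disjoint exons.

    Invariant: exons are sorted, pairwise disjoint and never bookended
    (``end + 1 < next.start``), so the union of bases is represented by the
    minimal number of intervals.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"flat gene {self.gene_id} has no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end + 1:
                raise ValueError(
                    f"flat gene {self.gene_id}: exons {a.start}-{a.end} and "
                    f"{b.start}-{b.end} overlap or abut"
                )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class STBlock:
    """One block of a superTranscript: ``start``/``end`` are superTranscript
    coordinates (1-based inclusive); ``source`` is the genome interval the
    block was copied from, or ``None`` for sequence inserted from de novo
    assembly (absent from the genome)."""

    start: int
    end: int
    source: Optional[GenomicInterval] = None

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def inserted(self) -> bool:
        return self.source is None


@dataclass
class SuperTranscript:
    """One sequence per gene containing all of that gene's exonic sequence in
    transcriptional order, with a block map back to the genome."""

    gene_id: str
    sequence: str
    blocks: list[STBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        pos = 1
        for b in self.blocks:
            if b.start != pos:
                raise ValueError(
                    f"superTranscript {self.gene_id}: block starts at {b.start}, "
                    f"expected {pos} (blocks must tile the sequence)"
                )
            pos = b.end + 1
        if self.blocks and pos != len(self.sequence) + 1:
            raise ValueError(
                f"superTranscript {self.gene_id}: blocks cover {pos - 1} bp, "
                f"sequence is {len(self.sequence)} bp"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PslHit:
    """One PSL alignment record (the BLAT exchange format).

    Query/target coordinates are kept PSL-native: 0-based half-open.
    """

    query_name: str
    target_name: str
    matches: int
    query_size: int
    query_start: int
    query_end: int
    target_size: int
    target_start: int
    target_end: int
    block_count: int = 1
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_size):
            raise ValueError(
                f"hit {self.query_name}->{self.target_name}: invalid query span "
                f"{self.query_start}..{self.query_end} (size {self.query_size})"
            )
        if self.matches > self.query_size:
            raise ValueError(
                f"hit {self.query_name}: matches ({self.matches}) exceed "
                f"query size ({self.query_size})"
            )

    @property
    def aligned_query_bases(self) -> int:
        return self.query_end - self.query_start

    @property
    def identity(self) -> float:
        """Matches over the aligned query span."""
        return self.matches / self.aligned_query_bases

    @property
    def aligned_query_fraction(self) -> float:
        return self.aligned_query_bases / self.query_size


@dataclass
class MateAlignment:
    """Reference placement of one mate: exonic intervals (from CIGAR M/=/X/D)
    and skipped junction spans (from CIGAR N), both 1-based inclusive."""

    reference_name: str
    intervals: list[tuple[int, int]]
    junctions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.intervals, self.intervals[1:]):
            if s2 <= e1:
                raise ValueError("mate intervals must be sorted and non-overlapping")
        for s, e in self.junctions:
            if not any(e1 + 1 == s for _, e1 in self.intervals) or not any(
                s2 == e + 1 for s2, _ in self.intervals
            ):
                raise ValueError(
                    f"junction {s}-{e} does not lie between two exonic intervals"
                )


@dataclass
class AlignedFragment:
    """One sequenced fragment: a read pair (or single read) aligned to the
    superTranscriptome.  Secondary/supplementary records become their own
    non-primary fragments."""

    read_name: str
    mates: list[MateAlignment]
    is_primary: bool = True
    is_paired: bool = True

    @property
    def reference_name(self) -> str:
        return self.mates[0].reference_name

    @property
    def mate_intervals(self) -> list[list[tuple[int, int]]]:
        return [m.intervals for m in self.mates]

    @property
    def junctions(self) -> list[tuple[str, int, int]]:
        """All skipped spans of this fragment as (reference, start, end)."""
        return [(m.reference_name, s, e) for m in self.mates for s, e in m.junctions]


@dataclass
class HitFilter:
    """Alignment quality thresholds used when deciding whether a contig
    "aligns to" a superTranscript.

    min_identity : fraction of matching bases over the aligned query span.
    min_aligned_fraction : aligned query span over total contig length.
    min_aligned_bases : absolute floor on the aligned query span.
    """

    min_identity: float = 0.98
    min_aligned_fraction: float = 0.5
    min_aligned_bases: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if not (0 < self.min_aligned_fraction <= 1):
            raise ValueError("min_aligned_fraction must be in (0, 1]")
        if self.min_aligned_bases < 1:
            raise ValueError("min_aligned_bases must be >= 1")

    def passes(self, hit: PslHit) -> bool:
        return (
            hit.identity >= self.min_identity
            and hit.aligned_query_fraction >= self.min_aligned_fraction
            and hit.aligned_query_bases >= self.min_aligned_bases
        )


FATE_KNOWN = "known"
FATE_NOVEL = "novel"
FATE_CHIMERIC = "filtered_chimeric"
FATE_UNMATCHED = "filtered_unmatched"
FATES = (FATE_KNOWN, FATE_NOVEL, FATE_CHIMERIC, FATE_UNMATCHED)


@dataclass
class ContigAssignment:
    """The clustering fate of one de novo assembled contig."""

    contig_id: str
    fate: str
    cluster_id: str = ""
    hits: list[PslHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")
        if self.fate in (FATE_KNOWN, FATE_NOVEL) and not self.cluster_id:
            raise ValueError(f"contig {self.contig_id}: fate {self.fate} needs a cluster")
        if self.fate in (FATE_CHIMERIC, FATE_UNMATCHED) and self.cluster_id:
            raise ValueError(f"contig {self.contig_id}: filtered fates have no cluster")
        if self.fate == FATE_NOVEL and not self.cluster_id.startswith("novel:"):
            raise ValueError("novel cluster ids must be prefixed with 'novel:'")


@dataclass
class Cluster:
    """A gene's reassembly unit: its genome-based superTranscript (the
    backbone, absent for novel genes) plus its de novo contigs."""

    cluster_id: str
    backbone: Optional[SuperTranscript] = None
    members: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.backbone is None and not self.members:
            raise ValueError(f"cluster {self.cluster_id} is empty")


@dataclass(frozen=True)
class SpliceJunction:
    """A skipped span on a superTranscript (1-based inclusive) supported by
    ``read_support`` primary fragments."""

    st_id: str
    start: int
    end: int
    read_support: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid junction span {self.start}-{self.end}")
        if self.read_support < 1:
            raise ValueError("read_support must be >= 1")


@dataclass(frozen=True)
class Block:
    """A contiguous superTranscript segment delimited by junction boundaries."""

    st_id: str
    start: int
    end: int
    block_id: str

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class CountTable:
    """Fragment counts per feature group and sample, with the assignment
    ledger featureCounts-style: assigned + every unassigned category sums to
    the total number of fragments seen per sample."""

    counts: pd.DataFrame
    summary: pd.DataFrame
    feature_info: Optional[pd.DataFrame] = None

    STATUSES = (
        "assigned",
        "unassigned_ambiguous",
        "unassigned_no_feature",
        "unassigned_secondary",
    )

    def __post_init__(self) -> None:
        missing = [s for s in self.STATUSES if s not in self.summary.index]
        if missing:
            raise ValueError(f"summary ledger missing statuses: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def total_fragments(self, sample: str) -> int:
        return int(self.summary[sample].sum())
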