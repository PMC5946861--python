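"""Readers and writers for the standard formats the pipeline touches.

GTF is parsed directly line by line (rather than through a database layer)
so that attribute text round-trips bit-faithfully and parse errors can name
the offending line.  Both the Ensembl ``key "value";`` and the bare
``key value;`` attribute dialects are accepted.  PSL has no parser in the
scientific Python stack, so one lives here.  SAM/BAM goes through pysam.
"""

from __future__ import annotations

import re
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pysam

from .models import (
    AlignedFragment,
    GeneModel,
    GenomicInterval,
    MateAlignment,
    PslHit,
    Transcript,
)

__all__ = [
    "GtfParseError",
    "PslParseError",
    "read_gtf",
    "write_gtf",
    "read_psl",
    "write_psl",
    "read_fragments",
    "read_fasta",
    "write_fasta",
]

PathLike = Union[str, Path]


class GtfParseError(ValueError):
    pass


class PslParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

# quoted (key "value";) or bare (key value;) attribute pairs
_ATTR_RE = re.compile(r'(\S+)\s+(?:"([^"]*)"|([^;\s]+))\s*;?')


def _parse_attributes(text: str) -> "OrderedDict[str, str]":
    attrs: "OrderedDict[str, str]" = OrderedDict()
    for m in _ATTR_RE.finditer(text):
        key = m.group(1)
        value = m.group(2) if m.group(2) is not None else m.group(3)
        if key not in attrs:
            attrs[key] = value
    return attrs


def _strip_known_attrs(text: str) -> str:
    """Drop gene_id/transcript_id pairs, keep everything else verbatim."""
    out = []
    for m in _ATTR_RE.finditer(text):
        if m.group(1) not in ("gene_id", "transcript_id"):
            out.append(m.group(0).strip().rstrip(";") + ";")
    return " ".join(out)


def read_gtf(
    path: PathLike,
    feature: str = "exon",
    source: Optional[str] = None,
) -> list[GeneModel]:
    """Read a GTF file into :class:`GeneModel` objects.

    Only lines whose feature column equals ``feature`` are used (pass
    ``"CDS"`` to build coding-only gene models, as done for the
    related-species annotation); all other feature lines are ignored.
    Coordinates are kept 1-based inclusive, exactly as in the file.

    Parameters
    ----------
    path:
        GTF file (Ensembl or StringTie dialect).
    feature:
        Feature-column filter; default ``"exon"``.
    source:
        Source tag to stamp on every transcript (``"reference"`` or
        ``"assembled"``).  When ``None``, the GTF source column is used if it
        is one of those two tags, else ``"reference"``.
    """
    genes: "OrderedDict[str, dict]" = OrderedDict()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, src_col, feat, start_s, end_s, _score, strand, _frame, attr_text = fields
            if feat != feature:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if end < start:
                raise GtfParseError(f"{path}:{lineno}: end ({end}) < start ({start})")
            if strand not in ("+", "-", "."):
                raise GtfParseError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = _parse_attributes(attr_text)
            if "gene_id" not in attrs:
                raise GtfParseError(f"{path}:{lineno}: {feature} line lacks gene_id")
            gene_id = attrs["gene_id"]
            transcript_id = attrs.get("transcript_id", gene_id)
            tr_source = source
            if tr_source is None:
                tr_source = src_col if src_col in ("reference", "assembled") else "reference"
            g = genes.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "transcripts": OrderedDict()},
            )
            if g["chrom"] != chrom:
                raise GtfParseError(
                    f"{path}:{lineno}: gene {gene_id} spans chromosomes "
                    f"{g['chrom']} and {chrom}"
                )
            if g["strand"] != strand:
                g["strand"] = "."
            t = g["transcripts"].setdefault(
                transcript_id, {"source": tr_source, "exons": [], "attrs": []}
            )
            t["exons"].append(GenomicInterval(chrom, start, end, strand))
            t["attrs"].append(_strip_known_attrs(attr_text))
    out = []
    for gene_id, g in genes.items():
        transcripts = [
            Transcript(tid, t["source"], t["exons"], t["attrs"])
            for tid, t in g["transcripts"].items()
        ]
        out.append(GeneModel(gene_id, g["chrom"], g["strand"], transcripts))
    return out


def write_gtf(genes: Iterable[GeneModel], path: PathLike, feature: str = "exon") -> None:
    """Write gene models as GTF, one line per exon.

    The source column carries each transcript's source tag so that
    ``read_gtf(write_gtf(x))`` reproduces genes, transcripts, exon
    coordinates, strands and source tags exactly.
    """
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                attrs_extra = t.exon_attrs if t.exon_attrs else [""] * len(t.exons)
                for exon, extra in zip(t.exons, attrs_extra):
                    attr = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                    if extra:
                        attr += " " + extra
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom,
                                t.source,
                                feature,
                                str(exon.start),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attr,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------

_PSL_NCOLS = 21


def read_psl(path: PathLike) -> list[PslHit]:
    """Read a PSL alignment file (with or without the 5-line psLayout header).

    Coordinates are kept PSL-native (0-based half-open) inside
    :class:`PslHit`; see the clustering stage for the conversion policy.
    """
    hits = []
    with open(path) as fh:
        lines = fh.readlines()
    start_idx = 0
    if lines and lines[0].startswith("psLayout"):
        # standard header: psLayout line, blank, two column-name lines, dashes
        start_idx = 5
    for lineno, raw in enumerate(lines[start_idx:], start=start_idx + 1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < _PSL_NCOLS:
            raise PslParseError(
                f"{path}:{lineno}: expected {_PSL_NCOLS} columns, got {len(fields)}"
            )
        try:
            hits.append(
                PslHit(
                    matches=int(fields[0]),
                    strand=fields[8],
                    query_name=fields[9],
                    query_size=int(fields[10]),
                    query_start=int(fields[11]),
                    query_end=int(fields[12]),
                    target_name=fields[13],
                    target_size=int(fields[14]),
                    target_start=int(fields[15]),
                    target_end=int(fields[16]),
                    block_count=int(fields[17]),
                )
            )
        except ValueError as exc:
            raise PslParseError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_psl(hits: Iterable[PslHit], path: PathLike, header: bool = False) -> None:
    """Write PSL records.  Fields the domain type does not carry (mismatches,
    repeat matches, per-block lists) are emitted as a single-block summary."""
    with open(path, "w") as fh:
        if header:
            fh.write("psLayout version 3\n\n")
            fh.write(
                "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\t"
                "Q        \tQ   \tQ    \tQ  \tT        \tT   \tT    \tT  \t"
                "block\tblockSizes \tqStarts\t tStarts\n"
            )
            fh.write(
                " \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \t"
                "name     \tsize\tstart\tend\tname     \tsize\tstart\tend\t"
                "count\n"
            )
            fh.write("-" * 159 + "\n")
        for h in hits:
            span = h.query_end - h.query_start
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        h.matches,
                        span - h.matches,  # mismatches
                        0,
                        0,
                        0,
                        0,
                        0,
                        0,
                        h.strand,
                        h.query_name,
                        h.query_size,
                        h.query_start,
                        h.query_end,
                        h.target_name,
                        h.target_size,
                        h.target_start,
                        h.target_end,
                        h.block_count,
                        f"{span},",
                        f"{h.query_start},",
                        f"{h.target_start},",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

# CIGAR ops by pysam numeric code
_CIGAR_REF_EXONIC = {0, 2, 7, 8}  # M, D, =, X consume reference into exonic span
_CIGAR_REF_SKIP = 3  # N
_CIGAR_QUERY_ONLY = {1, 4, 5, 6}  # I, S, H, P consume no reference
_CIGAR_KNOWN = _CIGAR_REF_EXONIC | {_CIGAR_REF_SKIP} | _CIGAR_QUERY_ONLY


def _walk_cigar(pos1: int, cigartuples) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Convert a CIGAR at 1-based reference position ``pos1`` into exonic
    intervals and skipped junction spans (both 1-based inclusive)."""
    intervals: list[tuple[int, int]] = []
    junctions: list[tuple[int, int]] = []
    cur_start = pos1
    cur_end = pos1 - 1
    for op, length in cigartuples:
        if op not in _CIGAR_KNOWN:
            raise ValueError(f"unknown CIGAR op code {op}")
        if op in _CIGAR_REF_EXONIC:
            cur_end += length
        elif op == _CIGAR_REF_SKIP:
            if cur_end >= cur_start:
                intervals.append((cur_start, cur_end))
            junctions.append((cur_end + 1, cur_end + length))
            cur_start = cur_end + length + 1
            cur_end = cur_start - 1
    if cur_end >= cur_start:
        intervals.append((cur_start, cur_end))
    return intervals, junctions


def read_fragments(path: PathLike) -> list[AlignedFragment]:
    """Read a SAM (or BAM) file of reads aligned to the superTranscriptome
    and pair mates into :class:`AlignedFragment` objects.

    Primary records sharing a read name form one fragment.  Every
    secondary/supplementary record becomes its own fragment flagged
    ``is_primary=False`` so the counting stage can ledger it.  Unmapped
    records are skipped.  Base sequences and qualities are not retained.
    """
    primary: "OrderedDict[str, list]" = OrderedDict()
    fragments: list[AlignedFragment] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        valid_refs = set(sam.references)
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                # htslib demotes records naming an absent @SQ to unmapped but
                # keeps their CIGAR; surface those as errors instead of
                # silently dropping aligned evidence
                if rec.cigartuples:
                    raise ValueError(
                        f"record {rec.query_name} references a sequence absent "
                        f"from the SAM header"
                    )
                continue
            if rec.reference_name not in valid_refs:  # pragma: no cover - guarded above
                raise ValueError(
                    f"record {rec.query_name} references absent sequence "
                    f"{rec.reference_name!r}"
                )
            try:
                intervals, junctions = _walk_cigar(
                    rec.reference_start + 1, rec.cigartuples or []
                )
            except ValueError as exc:
                raise ValueError(f"record {rec.query_name}: {exc}") from None
            mate = MateAlignment(rec.reference_name, intervals, junctions)
            if rec.is_secondary or rec.is_supplementary:
                fragments.append(
                    AlignedFragment(
                        rec.query_name, [mate], is_primary=False, is_paired=rec.is_paired
                    )
                )
            else:
                key = rec.query_name
                order = 1 if rec.is_read2 else 0
                primary.setdefault(key, []).append((order, rec.is_paired, mate))
    for name, mates in primary.items():
        mates.sort(key=lambda x: x[0])
        fragments.append(
            AlignedFragment(
                name,
                [m for _, _, m in mates],
                is_primary=True,
                is_paired=any(p for _, p, _ in mates),
            )
        )
    return fragments


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathLike) -> "OrderedDict[str, str]":
    """Read a FASTA file into an ordered id -> sequence mapping (uppercased)."""
    seqs: "OrderedDict[str, str]" = OrderedDict()
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts).upper()
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts).upper()
    return seqs


def write_fasta(seqs, path: PathLike, width: int = 60) -> None:
    """Write an id -> sequence mapping (or iterable of pairs) as FASTA."""
    items = seqs.items() if hasattr(seqs, "items") else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
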