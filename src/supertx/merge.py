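"""Reassembly: merge each cluster's sequences into one superTranscript.

The merge is anchor-based and deterministic.  Sequences are taken in a
fixed order (genome-based backbone first, then contigs by descending
length, then id), and each is decomposed against the growing consensus
into co-linear matched segments ("anchors").  Sequence present in a member
but absent between two consensus anchors is spliced in at its anchored
position; consensus regions that are runs of N (genome assembly gaps)
flanked by anchors are replaced by the member's real sequence.  Because
members are only ever inserted relative to existing anchors, the block
graph built this way is acyclic by construction and the backbone's blocks
keep their original (genomic) order — the defining superTranscript
property.

Shared sequence therefore appears exactly once, and on error-free input
every member occurs in the output as a co-linear chain of exact blocks.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .models import Cluster, GenomicInterval, STBlock, SuperTranscript

__all__ = [
    "MatchedSegment",
    "pairwise_block_decompose",
    "merge_cluster",
    "merge_all",
    "BlockGraph",
]

DEFAULT_MIN_ANCHOR = 30


@dataclass(frozen=True)
class MatchedSegment:
    """A co-linear matched segment between two sequences (0-based starts).
    ``length`` is the segment span in both sequences; ``matches`` counts
    identical bases within it (>= 99% of the span)."""

    a_start: int
    b_start: int
    length: int
    matches: int

    @property
    def a_end(self) -> int:  # exclusive
        return self.a_start + self.length

    @property
    def b_end(self) -> int:  # exclusive
        return self.b_start + self.length


def pairwise_block_decompose(
    a: str,
    b: str,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    max_sub_gap: int = 10,
    min_segment_identity: float = 0.99,
) -> list[MatchedSegment]:
    """Decompose two sequences into mutually consistent matched segments.

    Maximal exact matches are found with a longest-common-subsequence block
    matcher (guaranteeing a non-crossing, co-linear chain), then exact
    blocks separated only by short equal-length substitution gaps are fused
    into near-exact segments while identity stays >= ``min_segment_identity``.
    Segments shorter than ``min_anchor`` are discarded: anchors below
    read-length scale create spurious joins.  Deterministic for fixed input.
    """
    if not a or not b:
        return []
    sm = difflib.SequenceMatcher(None, a, b, autojunk=False)
    segments: list[list[int]] = []  # [a_start, b_start, span, matches]
    for blk in sm.get_matching_blocks():
        if blk.size == 0:
            continue
        if segments:
            a0, b0, span, matches = segments[-1]
            gap_a = blk.a - (a0 + span)
            gap_b = blk.b - (b0 + span)
            if gap_a == gap_b and 0 <= gap_a <= max_sub_gap:
                new_span = blk.a + blk.size - a0
                new_matches = matches + blk.size
                if new_matches / new_span >= min_segment_identity:
                    segments[-1] = [a0, b0, new_span, new_matches]
                    continue
        segments.append([blk.a, blk.b, blk.size, blk.size])
    return [
        MatchedSegment(a0, b0, span, matches)
        for a0, b0, span, matches in segments
        if span >= min_anchor
    ]


# ---------------------------------------------------------------------------
# consensus assembly
# ---------------------------------------------------------------------------


@dataclass
class _Seg:
    seq: str
    source: Optional[GenomicInterval]  # genome provenance; None = inserted

    def split(self, k: int) -> tuple["_Seg", "_Seg"]:
        """Split after the first k bases, dividing a genome source interval
        consistently with the segment's transcriptional orientation."""
        left_src = right_src = None
        if self.source is not None:
            s = self.source
            if s.strand == "-":
                # sequence is the reverse complement of the genome interval:
                # the first k bases come from the interval's 3' (high) end
                left_src = GenomicInterval(s.chrom, s.end - k + 1, s.end, s.strand)
                right_src = GenomicInterval(s.chrom, s.start, s.end - k, s.strand)
            else:
                left_src = GenomicInterval(s.chrom, s.start, s.start + k - 1, s.strand)
                right_src = GenomicInterval(s.chrom, s.start + k, s.end, s.strand)
        return _Seg(self.seq[:k], left_src), _Seg(self.seq[k:], right_src)


class _Consensus:
    """The growing merged sequence as an ordered list of provenance-tagged
    segments, supporting split/insert/replace at string offsets."""

    def __init__(self, segments: list[_Seg]):
        self.segs = [s for s in segments if s.seq]

    @property
    def sequence(self) -> str:
        return "".join(s.seq for s in self.segs)

    def _boundary_index(self, pos: int) -> int:
        """Ensure a segment boundary at offset ``pos``; return the index of
        the segment starting there (== len(segs) when pos is the end)."""
        off = 0
        for i, seg in enumerate(self.segs):
            if off == pos:
                return i
            if off + len(seg.seq) > pos:
                left, right = seg.split(pos - off)
                self.segs[i : i + 1] = [left, right]
                return i + 1
            off += len(seg.seq)
        if off == pos:
            return len(self.segs)
        raise IndexError(f"position {pos} beyond consensus length {off}")

    def insert(self, pos: int, seq: str) -> None:
        i = self._boundary_index(pos)
        self.segs.insert(i, _Seg(seq, None))

    def replace(self, start: int, end: int, seq: str) -> None:
        j = self._boundary_index(end)
        i = self._boundary_index(start)
        # re-find j: splitting at start may have shifted indices
        off = 0
        j = i
        while off < end - start:
            off += len(self.segs[j].seq)
            j += 1
        self.segs[i:j] = [_Seg(seq, None)]


def _frac_n(seq: str) -> float:
    return seq.upper().count("N") / len(seq) if seq else 0.0


def _hamming_frac(a: str, b: str) -> float:
    return sum(1 for x, y in zip(a, b) if x != y) / len(a)


def _edits_for_member(cons: str, member: str, min_anchor: int) -> list[tuple]:
    """Plan the insertions/replacements needed to absorb ``member`` into the
    consensus.  Returns edits with positions on the *current* consensus,
    strictly increasing, applied right-to-left by the caller."""
    anchors = pairwise_block_decompose(cons, member, min_anchor)
    if not anchors:
        return [("insert", len(cons), member)]
    edits: list[tuple] = []
    first = anchors[0]
    if first.b_start > 0:
        edits.append(("insert", first.a_start, member[: first.b_start]))
    for k in range(len(anchors) - 1):
        cur, nxt = anchors[k], anchors[k + 1]
        m_gap = member[cur.b_end : nxt.b_start]
        if not m_gap:
            continue  # member lacks this consensus stretch (e.g. partial contig)
        if nxt.a_start == cur.a_end:
            edits.append(("insert", cur.a_end, m_gap))
            continue
        c_gap = cons[cur.a_end : nxt.a_start]
        if _frac_n(c_gap) >= 0.5:
            # genome assembly gap bridged by real de novo sequence
            edits.append(("replace", cur.a_end, nxt.a_start, m_gap))
        elif len(c_gap) == len(m_gap) and _hamming_frac(c_gap, m_gap) <= 0.01:
            pass  # near-identical: the existing (genome-derived) bases win
        else:
            # genuinely alternative segments: keep both, member's goes second
            edits.append(("insert", nxt.a_start, m_gap))
    last = anchors[-1]
    if last.b_end < len(member):
        edits.append(("insert", last.a_end, member[last.b_end :]))
    return edits


@dataclass
class BlockGraph:
    """The merged cluster as a DAG of sequence blocks.  Construction by
    anchored insertion keeps the graph a simple chain, so the topological
    order is unique and backbone blocks retain their original order."""

    graph: nx.DiGraph

    @classmethod
    def from_segments(cls, segs: Sequence[_Seg]) -> "BlockGraph":
        g = nx.DiGraph()
        for i, seg in enumerate(segs):
            g.add_node(i, seq=seg.seq, source=seg.source, backbone=seg.source is not None)
        for i in range(len(segs) - 1):
            g.add_edge(i, i + 1)
        if not nx.is_directed_acyclic_graph(g):  # pragma: no cover - by construction
            raise ValueError("block graph contains a cycle")
        return cls(g)

    def ordered_blocks(self) -> list[tuple[str, Optional[GenomicInterval]]]:
        order = list(nx.lexicographical_topological_sort(self.graph))
        return [
            (self.graph.nodes[i]["seq"], self.graph.nodes[i]["source"]) for i in order
        ]


def merge_cluster(c: Cluster, min_anchor: int = DEFAULT_MIN_ANCHOR) -> SuperTranscript:
    """Merge one cluster into a single superTranscript.

    With a backbone, all backbone blocks appear in backbone order and
    member-only sequence (absent from the genome) is inserted at its
    anchored position, tagged "inserted" in the block map.  Without a
    backbone (novel gene), members are merged by the anchor chain alone.
    Output is independent of the order members are supplied in.
    """
    if c.backbone is not None:
        segs = []
        for b in c.backbone.blocks:
            segs.append(_Seg(c.backbone.sequence[b.start - 1 : b.end], b.source))
        members = sorted(c.members, key=lambda m: (-len(m[1]), m[0]))
    else:
        ordered = sorted(c.members, key=lambda m: (-len(m[1]), m[0]))
        segs = [_Seg(ordered[0][1].upper(), None)]
        members = ordered[1:]
    consensus = _Consensus(segs)
    for _mid, seq in members:
        seq = seq.upper()
        cons = consensus.sequence
        for edit in reversed(_edits_for_member(cons, seq, min_anchor)):
            if edit[0] == "insert":
                consensus.insert(edit[1], edit[2])
            else:
                consensus.replace(edit[1], edit[2], edit[3])
    blocks = []
    pos = 1
    for seq, source in BlockGraph.from_segments(consensus.segs).ordered_blocks():
        blocks.append(STBlock(pos, pos + len(seq) - 1, source))
        pos += len(seq)
    return SuperTranscript(c.cluster_id, consensus.sequence, blocks)


def merge_all(
    clusters: Sequence[Cluster], min_anchor: int = DEFAULT_MIN_ANCHOR
) -> list[SuperTranscript]:
    """Merge every cluster; one superTranscript per cluster, input order
    preserved, deterministic across runs."""
    seen = set()
    for c in clusters:
        if c.cluster_id in seen:
            raise ValueError(f"duplicate cluster id {c.cluster_id!r}")
        seen.add(c.cluster_id)
    return [merge_cluster(c, min_anchor) for c in clusters]
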