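"""Summarization: splice junctions, block segmentation, fragment counting.

Reads aligned back to the superTranscriptome carry splice junctions as
CIGAR N spans.  Junction boundaries cut each superTranscript into
contiguous blocks — the counting unit for differential isoform usage —
while gene-level counts use the whole superTranscript.  Counting follows
featureCounts fragment semantics with ``--primary -p``: primary alignments
only, a read pair is one fragment, a fragment overlapping features of two
or more groups is left unassigned as ambiguous.
"""

from __future__ import annotations

from collections import Counter, OrderedDict, defaultdict
from typing import Mapping, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from .models import AlignedFragment, Block, CountTable, FlatGene, SpliceJunction, SuperTranscript

__all__ = [
    "collect_junctions",
    "segment_blocks",
    "count_fragments",
    "write_counts",
    "read_counts",
    "write_blocks_gtf",
    "gene_features",
    "block_features",
    "flat_gene_features",
]

# feature spaces are mappings: group id -> list of (reference, start, end),
# 1-based inclusive, on the same coordinate system as the alignments
FeatureMap = Mapping[str, Sequence[tuple[str, int, int]]]


def collect_junctions(
    fragments: Sequence[AlignedFragment], min_support: int = 1
) -> list[SpliceJunction]:
    """Aggregate distinct skipped spans over primary fragments.

    ``read_support`` counts fragments containing the span (a span present in
    both mates of one pair counts once).  Spans with support below
    ``min_support`` are dropped.  Output sorted by (reference, start, end).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    support: Counter = Counter()
    for frag in fragments:
        if not frag.is_primary:
            continue
        for key in set(frag.junctions):
            support[key] += 1
    return [
        SpliceJunction(ref, s, e, n)
        for (ref, s, e), n in sorted(support.items())
        if n >= min_support
    ]


def segment_blocks(
    st_lengths: Mapping[str, int], junctions: Sequence[SpliceJunction]
) -> list[Block]:
    """Cut superTranscripts into contiguous blocks at junction boundaries.

    The cut-point set per superTranscript is ``{1, L+1}`` plus
    ``{j.start, j.end + 1}`` for every junction; blocks are the intervals
    between consecutive cut points and tile ``[1, L]`` exactly.  Junction
    coordinates use the skipped-span convention: ``start`` is the first
    skipped base.

    Raises
    ------
    ValueError
        If a junction names an unknown superTranscript or exceeds its length.
    """
    cuts: dict[str, set[int]] = {st: {1, L + 1} for st, L in st_lengths.items()}
    for j in junctions:
        if j.st_id not in st_lengths:
            raise ValueError(f"junction on unknown superTranscript {j.st_id!r}")
        L = st_lengths[j.st_id]
        if j.end > L:
            raise ValueError(
                f"junction {j.start}-{j.end} exceeds superTranscript "
                f"{j.st_id} length {L}"
            )
        cuts[j.st_id].update((j.start, j.end + 1))
    blocks = []
    for st_id in st_lengths:
        points = sorted(cuts[st_id])
        for i, (a, b) in enumerate(zip(points, points[1:]), start=1):
            blocks.append(Block(st_id, a, b - 1, f"{st_id}:block{i}"))
    return blocks


# ---------------------------------------------------------------------------
# feature spaces
# ---------------------------------------------------------------------------


def gene_features(st_lengths: Mapping[str, int]) -> "OrderedDict[str, list]":
    """Gene-level feature space on the superTranscriptome: one group per
    superTranscript covering its whole length."""
    return OrderedDict((st, [(st, 1, L)]) for st, L in st_lengths.items())


def block_features(blocks: Sequence[Block]) -> "OrderedDict[str, list]":
    """Block-level feature space: one group per block."""
    out: "OrderedDict[str, list]" = OrderedDict()
    for b in blocks:
        out.setdefault(b.block_id, []).append((b.st_id, b.start, b.end))
    return out


def flat_gene_features(flat: Sequence[FlatGene]) -> "OrderedDict[str, list]":
    """Gene feature space in genome coordinates (for reference-style
    counting against a flattened annotation)."""
    out: "OrderedDict[str, list]" = OrderedDict()
    for g in flat:
        out[g.gene_id] = [(e.chrom, e.start, e.end) for e in g.exons]
    return out


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


def _feature_index(features: FeatureMap) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for group, ivs in features.items():
        for ref, start, end in ivs:
            trees[ref].addi(start, end + 1, group)
    return trees


def count_fragments(
    fragments: Union[Sequence[AlignedFragment], Mapping[str, Sequence[AlignedFragment]]],
    features: FeatureMap,
    paired: bool = True,
) -> CountTable:
    """Count fragments per feature group, featureCounts-style.

    ``fragments`` is either one sample's fragment list or a mapping of
    sample name -> fragments.  Only primary fragments are counted
    (non-primary ones are ledgered as ``unassigned_secondary``).  A fragment
    is assigned to a group if any aligned base of either mate overlaps any
    interval of that group; fragments touching two or more groups are
    ``unassigned_ambiguous``, fragments touching none are
    ``unassigned_no_feature``.  Mates are never counted twice.  Per sample,
    assigned plus all unassigned categories equals the total number of
    fragments.
    """
    if not isinstance(fragments, Mapping):
        fragments = {"sample_1": fragments}
    trees = _feature_index(features)
    order = list(features)
    counts = pd.DataFrame(0, index=order, columns=list(fragments), dtype=int)
    summary = pd.DataFrame(
        0, index=list(CountTable.STATUSES), columns=list(fragments), dtype=int
    )
    for sample, frags in fragments.items():
        for frag in frags:
            if not frag.is_primary:
                summary.loc["unassigned_secondary", sample] += 1
                continue
            groups = set()
            for mate in frag.mates:
                tree = trees.get(mate.reference_name)
                if tree is None:
                    raise ValueError(
                        f"fragment {frag.read_name} aligned to {mate.reference_name!r}, "
                        f"which is unknown to this feature space"
                    )
                for s, e in mate.intervals:
                    for iv in tree.overlap(s, e + 1):
                        groups.add(iv.data)
            if len(groups) == 1:
                counts.loc[groups.pop(), sample] += 1
                summary.loc["assigned", sample] += 1
            elif len(groups) >= 2:
                summary.loc["unassigned_ambiguous", sample] += 1
            else:
                summary.loc["unassigned_no_feature", sample] += 1
    return CountTable(counts, summary)


def feature_annotation(features: FeatureMap) -> pd.DataFrame:
    """featureCounts-style per-group annotation columns (semicolon-joined
    per interval), so expression columns start at column 7 of the table."""
    rows = []
    for group, ivs in features.items():
        rows.append(
            {
                "Geneid": group,
                "Chr": ";".join(r for r, _, _ in ivs),
                "Start": ";".join(str(s) for _, s, _ in ivs),
                "End": ";".join(str(e) for _, _, e in ivs),
                "Strand": ";".join("+" for _ in ivs),
                "Length": sum(e - s + 1 for _, s, e in ivs),
            }
        )
    return pd.DataFrame(rows).set_index("Geneid")


def write_counts(ct: CountTable, path, features: FeatureMap | None = None) -> None:
    """Write the count table as TSV (annotation columns, then one column per
    sample, expression starting at column 7) plus a ``.summary`` ledger file."""
    if features is not None:
        info = feature_annotation(features)
    elif ct.feature_info is not None:
        info = ct.feature_info
    else:
        info = pd.DataFrame(
            {
                "Chr": ct.counts.index,
                "Start": 1,
                "End": 1,
                "Strand": "+",
                "Length": 1,
            },
            index=pd.Index(ct.counts.index, name="Geneid"),
        )
    table = info.join(ct.counts, how="right")
    table.index.name = "Geneid"
    table.to_csv(path, sep="\t")
    summary = ct.summary.copy()
    summary.index.name = "Status"
    summary.to_csv(str(path) + ".summary", sep="\t")


def read_counts(path) -> CountTable:
    """Re-read a count table written by :func:`write_counts`."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = ["Chr", "Start", "End", "Strand", "Length"]
    counts = table.drop(columns=[c for c in meta_cols if c in table.columns]).astype(int)
    summary = pd.read_csv(str(path) + ".summary", sep="\t", index_col=0)
    return CountTable(counts, summary, table[[c for c in meta_cols if c in table.columns]])


def write_blocks_gtf(blocks: Sequence[Block], path) -> None:
    """Write blocks as a GTF on superTranscript coordinates.  Junction
    coordinates follow the skipped-span convention (start = first skipped
    base), noted in the header."""
    with open(path, "w") as fh:
        fh.write(
            "# superTranscript blocks; coordinates are superTranscript-local;\n"
            "# block boundaries derive from skipped-span junctions "
            "(start = first skipped base)\n"
        )
        for b in blocks:
            attr = f'gene_id "{b.st_id}"; transcript_id "{b.st_id}"; block_id "{b.block_id}";'
            fh.write(
                "\t".join(
                    [b.st_id, "supertx", "exon", str(b.start), str(b.end), ".", "+", ".", attr]
                )
                + "\n"
            )
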