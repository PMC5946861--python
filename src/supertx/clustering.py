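"""Assign de novo assembled contigs to gene clusters.

Contigs aligning (well enough, see :class:`~supertx.models.HitFilter`) to the
genome-based superTranscriptome are allocated to known genes; contigs not
found in the genome but aligning to the related species' coding
superTranscriptome are assigned to novel genes; contigs matching more than
one gene are removed as likely false chimeras; contigs found in neither are
filtered out, since de novo assemblies are error prone and strict filtering
keeps artifacts out of the annotation.
"""

from __future__ import annotations

from collections import OrderedDict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .io import read_fasta
from .models import (
    FATE_CHIMERIC,
    FATE_KNOWN,
    FATE_NOVEL,
    FATE_UNMATCHED,
    Cluster,
    ContigAssignment,
    HitFilter,
    PslHit,
    SuperTranscript,
)

__all__ = [
    "filter_hits",
    "cluster_contigs",
    "build_clusters",
    "write_assignments",
    "read_assignments",
]

NOVEL_PREFIX = "novel:"


def filter_hits(hits: Sequence[PslHit], f: HitFilter) -> list[PslHit]:
    """Keep hits passing all three thresholds (identity over the aligned
    query span, aligned fraction of the contig, absolute aligned bases).
    Input order is preserved."""
    return [h for h in hits if f.passes(h)]


def _hits_by_contig(hits: Sequence[PslHit]) -> "OrderedDict[str, list[PslHit]]":
    by: "OrderedDict[str, list[PslHit]]" = OrderedDict()
    for h in hits:
        if not h.query_name:
            raise ValueError("PSL hit with empty query name")
        by.setdefault(h.query_name, []).append(h)
    return by


def cluster_contigs(
    genome_hits: Sequence[PslHit],
    related_hits: Sequence[PslHit],
    f: HitFilter = HitFilter(),
    contig_ids: Optional[Sequence[str]] = None,
) -> list[ContigAssignment]:
    """Decide each contig's fate from its alignments.

    Decision order per contig (genome evidence takes precedence over the
    related species):

    1. passing genome hits to exactly one gene  -> ``known`` in that gene;
    2. passing genome hits to two or more genes -> ``filtered_chimeric``;
    3. otherwise, passing related-species hits to exactly one gene ->
       ``novel`` in cluster ``novel:<related gene id>``;
    4. related hits to two or more genes -> ``filtered_chimeric``;
    5. no passing hit anywhere -> ``filtered_unmatched``.

    Every contig receives exactly one assignment.  The contig universe is
    ``contig_ids`` when given (contigs an aligner found no hit for produce
    no PSL lines at all, yet must still be ledgered as unmatched);
    otherwise it is the union of query names in the two hit lists.
    Multiple passing hits to the *same* gene (isoforms) are fine; only
    multi-gene contigs are removed.
    """
    genome_by = _hits_by_contig(genome_hits)
    related_by = _hits_by_contig(related_hits)
    contigs = list(contig_ids) if contig_ids is not None else []
    known = set(contigs)
    for c in list(genome_by) + list(related_by):
        if c not in known:
            known.add(c)
            contigs.append(c)

    out = []
    for contig in contigs:
        g_pass = filter_hits(genome_by.get(contig, []), f)
        g_genes = sorted({h.target_name for h in g_pass})
        if len(g_genes) == 1:
            out.append(ContigAssignment(contig, FATE_KNOWN, g_genes[0], g_pass))
            continue
        if len(g_genes) >= 2:
            out.append(ContigAssignment(contig, FATE_CHIMERIC, "", g_pass))
            continue
        r_pass = filter_hits(related_by.get(contig, []), f)
        r_genes = sorted({h.target_name for h in r_pass})
        if len(r_genes) == 1:
            out.append(
                ContigAssignment(contig, FATE_NOVEL, NOVEL_PREFIX + r_genes[0], r_pass)
            )
        elif len(r_genes) >= 2:
            out.append(ContigAssignment(contig, FATE_CHIMERIC, "", r_pass))
        else:
            out.append(ContigAssignment(contig, FATE_UNMATCHED, "", []))
    return out


def build_clusters(
    assignments: Sequence[ContigAssignment],
    sts: Sequence[SuperTranscript],
    contigs: Union[str, Path, Mapping[str, str]],
) -> list[Cluster]:
    """Group sequences for reassembly: one cluster per genome-based gene
    (its superTranscript as backbone plus any contigs assigned to it, or the
    backbone alone if no contig matched) and one backbone-less cluster per
    novel related-species gene.

    ``contigs`` is the de novo contig FASTA (path or mapping).

    Raises
    ------
    KeyError
        If an assigned contig's sequence is missing from the FASTA.
    """
    seqs = read_fasta(contigs) if isinstance(contigs, (str, Path)) else contigs
    members: "OrderedDict[str, list[tuple[str, str]]]" = OrderedDict()
    for st in sts:
        members.setdefault(st.gene_id, [])
    for a in assignments:
        if a.fate not in (FATE_KNOWN, FATE_NOVEL):
            continue
        if a.contig_id not in seqs:
            raise KeyError(f"contig {a.contig_id!r} missing from contig FASTA")
        members.setdefault(a.cluster_id, []).append((a.contig_id, seqs[a.contig_id]))
    backbone_of = {st.gene_id: st for st in sts}
    return [
        Cluster(cid, backbone_of.get(cid), mem)
        for cid, mem in members.items()
        if backbone_of.get(cid) is not None or mem
    ]


def write_assignments(assignments: Sequence[ContigAssignment], path) -> None:
    """Write the cluster table: contig_id, fate, cluster_id (TSV)."""
    with open(path, "w") as fh:
        fh.write("contig_id\tfate\tcluster_id\n")
        for a in assignments:
            fh.write(f"{a.contig_id}\t{a.fate}\t{a.cluster_id}\n")


def read_assignments(path) -> list[ContigAssignment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            contig_id, fate, cluster_id = line.rstrip("\n").split("\t")
            out.append(ContigAssignment(contig_id, fate, cluster_id))
    return out
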