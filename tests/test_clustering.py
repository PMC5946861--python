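"""Contig-to-gene clustering: filters, fates, cluster assembly."""

from collections import Counter

import pytest

from supertx.clustering import build_clusters, cluster_contigs, filter_hits
from supertx.models import (
    FATE_CHIMERIC,
    FATE_KNOWN,
    FATE_NOVEL,
    FATE_UNMATCHED,
    HitFilter,
    PslHit,
    STBlock,
    SuperTranscript,
)
from supertx.simulate import (
    FixtureSpec,
    contig_hits_genome,
    contig_hits_related,
    generate_world,
)


def hit(q, t, matches=None, qsize=1000, qstart=0, qend=1000):
    return PslHit(
        query_name=q,
        target_name=t,
        matches=matches if matches is not None else (qend - qstart),
        query_size=qsize,
        query_start=qstart,
        query_end=qend,
        target_size=5000,
        target_start=0,
        target_end=qend - qstart,
    )


class TestFilterHits:
    def test_perfect_full_length_hit_kept(self):
        assert filter_hits([hit("c", "G")], HitFilter()) == [hit("c", "G")]

    def test_short_alignment_dropped(self):
        h = hit("c", "G", qsize=60, qend=30, matches=30)
        assert filter_hits([h], HitFilter(min_aligned_bases=100, min_aligned_fraction=0.1)) == []

    def test_low_identity_dropped(self):
        h = hit("c", "G", matches=900)  # 90% identity over the span
        assert filter_hits([h], HitFilter(min_identity=0.98)) == []

    def test_low_query_fraction_dropped(self):
        h = hit("c", "G", qsize=3000, qend=1000)
        assert filter_hits([h], HitFilter(min_aligned_fraction=0.5)) == []

    def test_random_hits_match_predicate_oracle(self, rng):
        f = HitFilter(0.95, 0.4, 120)
        hits = []
        for i in range(300):
            qsize = int(rng.integers(100, 2000))
            qstart = int(rng.integers(0, qsize - 50))
            qend = int(rng.integers(qstart + 50, qsize + 1))
            span = qend - qstart
            matches = int(rng.integers(int(span * 0.9), span + 1))
            hits.append(
                PslHit(f"c{i}", "G", matches, qsize, qstart, qend, 9000, 0, span)
            )
        kept = filter_hits(hits, f)
        oracle = [
            h
            for h in hits
            if h.matches / (h.query_end - h.query_start) >= 0.95
            and (h.query_end - h.query_start) / h.query_size >= 0.4
            and (h.query_end - h.query_start) >= 120
        ]
        assert kept == oracle


class TestClusterContigs:
    def test_single_gene_hit_is_known(self):
        (a,) = cluster_contigs([hit("c", "G")], [])
        assert (a.fate, a.cluster_id) == (FATE_KNOWN, "G")

    def test_two_gene_hits_are_chimeric(self):
        hits = [
            hit("c", "G1", qsize=2000, qstart=0, qend=1000),
            hit("c", "G2", qsize=2000, qstart=1000, qend=2000),
        ]
        (a,) = cluster_contigs(hits, [])
        assert a.fate == FATE_CHIMERIC
        assert a.cluster_id == ""

    def test_related_only_hit_is_novel(self):
        (a,) = cluster_contigs([], [hit("c", "HOM1")])
        assert (a.fate, a.cluster_id) == (FATE_NOVEL, "novel:HOM1")

    def test_no_passing_hits_filtered_unmatched(self):
        weak = hit("c", "G", matches=500)  # identity 0.5
        (a,) = cluster_contigs([weak], [])
        assert a.fate == FATE_UNMATCHED

    def test_genome_precedence_over_related(self):
        (a,) = cluster_contigs([hit("c", "G")], [hit("c", "HOM1")])
        assert (a.fate, a.cluster_id) == (FATE_KNOWN, "G")

    def test_multiple_hits_same_gene_still_known(self):
        hits = [
            hit("c", "G", qsize=2000, qstart=0, qend=1200),
            hit("c", "G", qsize=2000, qstart=1200, qend=2000, matches=800),
        ]
        (a,) = cluster_contigs(hits, [])
        assert (a.fate, a.cluster_id) == (FATE_KNOWN, "G")

    def test_partition_every_contig_exactly_one_fate(self):
        for seed in (1, 2, 3):
            world = generate_world(FixtureSpec(seed=seed))
            assignments = cluster_contigs(
                contig_hits_genome(world),
                contig_hits_related(world),
                contig_ids=list(world.contigs),
            )
            assert Counter(a.contig_id for a in assignments) == Counter(list(world.contigs))

    def test_tightening_filter_never_rescues_a_contig(self, world):
        loose = HitFilter(0.9, 0.3, 50)
        tight = HitFilter(0.99, 0.8, 200)
        g, r = contig_hits_genome(world), contig_hits_related(world)
        ids = list(world.contigs)
        loose_fates = {a.contig_id: a.fate for a in cluster_contigs(g, r, loose, ids)}
        tight_fates = {a.contig_id: a.fate for a in cluster_contigs(g, r, tight, ids)}
        for cid in ids:
            if loose_fates[cid] == FATE_UNMATCHED:
                assert tight_fates[cid] == FATE_UNMATCHED


def st(gene_id, seq):
    return SuperTranscript(gene_id, seq, [STBlock(1, len(seq), None)])


class TestBuildClusters:
    def test_gene_without_contigs_is_backbone_only(self):
        clusters = build_clusters([], [st("G", "ACGT")], {})
        assert len(clusters) == 1
        assert clusters[0].backbone is not None
        assert clusters[0].members == []

    def test_known_contigs_join_their_gene(self):
        from supertx.models import ContigAssignment

        assignments = [
            ContigAssignment(f"c{i}", FATE_KNOWN, "G", []) for i in range(3)
        ]
        contigs = {f"c{i}": "ACGT" for i in range(3)}
        (cluster,) = build_clusters(assignments, [st("G", "ACGTACGT")], contigs)
        assert len(cluster.members) == 3

    def test_missing_contig_sequence_names_contig(self):
        from supertx.models import ContigAssignment

        with pytest.raises(KeyError, match="c0"):
            build_clusters(
                [ContigAssignment("c0", FATE_KNOWN, "G", [])], [st("G", "ACGT")], {}
            )

    def test_planted_world_cluster_membership(self, world):
        assignments = cluster_contigs(
            contig_hits_genome(world),
            contig_hits_related(world),
            contig_ids=list(world.contigs),
        )
        truth_fates = Counter(f for f, _ in world.truth.contig_fates.values())
        assert Counter(a.fate for a in assignments) == truth_fates
        for a in assignments:
            assert (a.fate, a.cluster_id) == world.truth.contig_fates[a.contig_id]
        sts = [st(g.gene_id, g.true_st) for g in world.genes]
        clusters = {c.cluster_id: c for c in build_clusters(assignments, sts, world.contigs)}
        # every genome gene has a cluster; novel clusters are backbone-less
        assert set(clusters) >= {g.gene_id for g in world.genes}
        for cid, c in clusters.items():
            if cid.startswith("novel:"):
                assert c.backbone is None
            else:
                assert c.backbone is not None
        # no cluster mixes genes: member contigs were assigned to exactly it
        for a in assignments:
            if a.fate == FATE_KNOWN:
                assert a.contig_id in {m[0] for m in clusters[a.cluster_id].members}
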