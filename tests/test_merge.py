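"""Cluster reassembly: anchored block merge into one superTranscript."""

import itertools

import pytest

from supertx.merge import merge_all, merge_cluster, pairwise_block_decompose
from supertx.models import Cluster, GenomicInterval, STBlock, SuperTranscript
from supertx.simulate import FixtureSpec, generate_world

from conftest import random_seq


def backbone(seq, gene_id="G", chrom="chr1"):
    """A genome-based superTranscript with one genome-sourced block."""
    return SuperTranscript(
        gene_id, seq, [STBlock(1, len(seq), GenomicInterval(chrom, 1, len(seq), "+"))]
    )


def brute_force_overlap_merge(a, b, min_overlap):
    """Toy oracle: merge b onto a by the longest suffix(a)==prefix(b) overlap."""
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a[-k:] == b[:k]:
            return a + b[k:]
    return a + b


class TestPairwiseBlockDecompose:
    def test_identical_sequences_single_full_match(self, rng):
        s = random_seq(rng, 500)
        (m,) = pairwise_block_decompose(s, s)
        assert (m.a_start, m.b_start, m.length) == (0, 0, 500)

    def test_disjoint_sequences_empty(self, rng):
        a = "A" * 200
        b = "C" * 200
        assert pairwise_block_decompose(a, b) == []

    def test_insertion_yields_two_flanking_matches(self, rng):
        left, insert, right = random_seq(rng, 300), random_seq(rng, 200), random_seq(rng, 300)
        a = left + right
        b = left + insert + right
        matches = pairwise_block_decompose(a, b)
        assert len(matches) == 2
        first, second = matches
        assert (first.a_start, first.b_start, first.length) == (0, 0, 300)
        assert (second.a_start, second.b_start, second.length) == (300, 500, 300)

    def test_substitutions_fused_into_near_exact_segment(self, rng):
        s = random_seq(rng, 600)
        # one substitution in the middle; should still come back as one segment
        mutated = s[:300] + ("A" if s[300] != "A" else "C") + s[301:]
        matches = pairwise_block_decompose(s, mutated)
        assert len(matches) == 1
        assert matches[0].length == 600
        assert matches[0].matches == 599

    def test_matches_are_colinear(self, rng):
        a = random_seq(rng, 800)
        b = a[400:] + a[:400]  # rearranged: only one side can be kept
        matches = pairwise_block_decompose(a, b)
        for m1, m2 in zip(matches, matches[1:]):
            assert m1.a_end <= m2.a_start and m1.b_end <= m2.b_start


class TestMergeCluster:
    def test_backbone_only_identity(self, rng):
        bb = backbone(random_seq(rng, 400))
        st = merge_cluster(Cluster("G", bb, []))
        assert st.sequence == bb.sequence
        assert [b.source for b in st.blocks] == [b.source for b in bb.blocks]

    def test_toy_overlap_matches_brute_force_oracle(self):
        bb, contig = "AAAACCCC", "CCCCGGGG"
        st = merge_cluster(Cluster("G", backbone(bb), [("c", contig)]), min_anchor=4)
        assert st.sequence == brute_force_overlap_merge(bb, contig, 4) == "AAAACCCCGGGG"
        # the extension is marked as inserted (absent from the genome backbone)
        assert st.blocks[-1].source is None

    def test_random_overlap_extensions_match_oracle(self, rng):
        for _ in range(10):
            core = random_seq(rng, 400)
            ext = random_seq(rng, 150)
            bb = backbone(core)
            st = merge_cluster(Cluster("G", bb, [("c", core[200:] + ext)]))
            assert st.sequence == brute_force_overlap_merge(core, core[200:] + ext, 30)

    def test_gap_bridging_contig_repairs_n_run(self, rng):
        # genome copy has an assembly gap (N run) where the true gene carries
        # real sequence; the contig restores it as an inserted block
        left, hidden, right = random_seq(rng, 300), random_seq(rng, 250), random_seq(rng, 300)
        genome_st = backbone(left + "N" * 20 + right)
        contig = left + hidden + right
        st = merge_cluster(Cluster("G", genome_st, [("c", contig)]))
        assert st.sequence == contig
        assert len(st) - len(genome_st) == 250 - 20
        inserted = [b for b in st.blocks if b.source is None]
        assert sum(len(b) for b in inserted) == 250

    def test_member_only_internal_sequence_inserted_once(self, rng):
        seq = random_seq(rng, 600)
        extra = random_seq(rng, 120)
        contig = seq[:300] + extra + seq[300:]
        st = merge_cluster(Cluster("G", backbone(seq), [("c1", contig), ("c2", contig)]))
        # shared by both contigs, but appears exactly once
        assert st.sequence == contig
        assert st.sequence.count(extra) == 1

    def test_backbone_block_order_preserved(self, rng):
        seq = random_seq(rng, 900)
        blocks = [
            STBlock(1, 300, GenomicInterval("chr1", 101, 400, "+")),
            STBlock(301, 600, GenomicInterval("chr1", 1001, 1300, "+")),
            STBlock(601, 900, GenomicInterval("chr1", 2001, 2300, "+")),
        ]
        bb = SuperTranscript("G", seq, blocks)
        contig = seq[150:750] + random_seq(rng, 100)
        st = merge_cluster(Cluster("G", bb, [("c", contig)]))
        genome_starts = [b.source.start for b in st.blocks if b.source is not None]
        assert genome_starts == sorted(genome_starts)

    def test_member_permutation_invariance(self, rng):
        seq = random_seq(rng, 500)
        members = [
            ("a", seq[:300] + random_seq(rng, 80)),
            ("b", seq[100:450]),
            ("c", seq[250:]),
        ]
        results = {
            merge_cluster(Cluster("G", backbone(seq), list(perm))).sequence
            for perm in itertools.permutations(members)
        }
        assert len(results) == 1

    def test_novel_cluster_without_backbone(self, rng):
        seq = random_seq(rng, 700)
        c = Cluster("novel:H", None, [("c1", seq), ("c2", seq[100:500])])
        st = merge_cluster(c)
        assert st.sequence == seq
        assert all(b.source is None for b in st.blocks)

    def test_error_free_members_contained_as_block_chains(self, world):
        # every cluster member of the synthetic world aligns back co-linearly
        gene_of = {g.gene_id: g for g in world.genes}
        for g in world.genes:
            bb = backbone(
                "".join(
                    "N" * p[1] if p[0] == "N" else g.true_st[p[1] - 1 : p[2]]
                    for p in g.variant_pieces("genome")
                ),
                g.gene_id,
            )
            members = [
                (cid, seq)
                for cid, seq in world.contigs.items()
                if world.truth.contig_fates[cid] == ("known", g.gene_id)
            ]
            st = merge_cluster(Cluster(g.gene_id, bb, members))
            for cid, seq in members:
                chain = pairwise_block_decompose(st.sequence, seq)
                covered = sum(m.length for m in chain)
                assert covered == len(seq)  # fully contained, co-linear


class TestMergeAll:
    def test_three_trivial_clusters(self, rng):
        clusters = [
            Cluster(f"G{i}", backbone(random_seq(rng, 200), f"G{i}"), [])
            for i in range(3)
        ]
        assert [st.gene_id for st in merge_all(clusters)] == ["G0", "G1", "G2"]

    def test_duplicate_cluster_ids_rejected(self, rng):
        c = Cluster("G", backbone(random_seq(rng, 100)), [])
        with pytest.raises(ValueError, match="duplicate"):
            merge_all([c, c])

    def test_planted_insertions_each_in_exactly_one_output(self, rng):
        clusters, inserts = [], []
        for i in range(20):
            seq = random_seq(rng, 500)
            ins = random_seq(rng, 90)
            inserts.append(ins)
            clusters.append(
                Cluster(
                    f"G{i}",
                    backbone(seq, f"G{i}"),
                    [("c", seq[:250] + ins + seq[250:])],
                )
            )
        merged = merge_all(clusters)
        assert len(merged) == 20
        for ins in inserts:
            assert sum(st.sequence.count(ins) for st in merged) == 1

    def test_remerging_output_is_a_fixed_point(self, rng):
        seq = random_seq(rng, 400)
        contig = seq[:200] + random_seq(rng, 100) + seq[200:]
        st1 = merge_cluster(Cluster("G", backbone(seq), [("c", contig)]))
        st2 = merge_cluster(Cluster("G", st1, [("c", contig)]))
        assert st2.sequence == st1.sequence
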