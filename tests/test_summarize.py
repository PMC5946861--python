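"""Junction aggregation, block segmentation, fragment counting."""

import numpy as np
import pytest

from supertx.models import AlignedFragment, MateAlignment, SpliceJunction
from supertx.summarize import (
    block_features,
    collect_junctions,
    count_fragments,
    gene_features,
    read_counts,
    segment_blocks,
    write_counts,
)


def frag(name, ref, intervals, junctions=(), primary=True):
    return AlignedFragment(
        name, [MateAlignment(ref, list(intervals), list(junctions))], is_primary=primary
    )


def pair(name, ref, iv1, iv2):
    return AlignedFragment(
        name, [MateAlignment(ref, [iv1]), MateAlignment(ref, [iv2])]
    )


class TestCollectJunctions:
    def test_two_reads_same_skip_aggregate(self):
        frags = [
            frag(f"r{i}", "ST1", [(1, 10), (111, 120)], [(11, 110)]) for i in range(2)
        ]
        assert collect_junctions(frags) == [SpliceJunction("ST1", 11, 110, 2)]

    def test_no_spliced_reads_empty(self):
        assert collect_junctions([frag("r", "ST1", [(1, 20)])]) == []

    def test_min_support_threshold(self):
        frags = [frag("r1", "ST1", [(1, 10), (111, 120)], [(11, 110)])]
        assert collect_junctions(frags, min_support=2) == []

    def test_non_primary_fragments_ignored(self):
        frags = [
            frag("r", "ST1", [(1, 10), (111, 120)], [(11, 110)], primary=False)
        ]
        assert collect_junctions(frags) == []

    def test_random_fixture_matches_counting_oracle(self, rng):
        spans = [(11, 110), (200, 350), (400, 420)]
        frags, oracle = [], {}
        for i in range(200):
            s, e = spans[rng.integers(0, 3)]
            frags.append(frag(f"r{i}", "ST1", [(s - 10, s - 1), (e + 1, e + 10)], [(s, e)]))
            oracle[(s, e)] = oracle.get((s, e), 0) + 1
        result = {(j.start, j.end): j.read_support for j in collect_junctions(frags)}
        assert result == oracle


class TestSegmentBlocks:
    def test_single_junction_worked_example(self):
        blocks = segment_blocks({"ST1": 300}, [SpliceJunction("ST1", 101, 150, 1)])
        assert [(b.start, b.end) for b in blocks] == [(1, 100), (101, 150), (151, 300)]

    def test_no_junctions_single_block(self):
        (b,) = segment_blocks({"ST1": 500}, [])
        assert (b.start, b.end) == (1, 500)

    def test_overlapping_junctions_boundary_set(self):
        blocks = segment_blocks(
            {"ST1": 300},
            [SpliceJunction("ST1", 101, 150, 1), SpliceJunction("ST1", 121, 180, 1)],
        )
        assert [(b.start, b.end) for b in blocks] == [
            (1, 100),
            (101, 120),
            (121, 150),
            (151, 180),
            (181, 300),
        ]

    def test_blocks_always_tile(self, rng):
        lengths = {f"ST{i}": int(rng.integers(200, 2000)) for i in range(20)}
        junctions = []
        for st, L in lengths.items():
            for _ in range(int(rng.integers(0, 4))):
                s = int(rng.integers(1, L - 10))
                e = int(rng.integers(s, min(L, s + 300)))
                junctions.append(SpliceJunction(st, s, e, 1))
        blocks = segment_blocks(lengths, junctions)
        for st, L in lengths.items():
            mine = [b for b in blocks if b.st_id == st]
            assert mine[0].start == 1 and mine[-1].end == L
            assert sum(len(b) for b in mine) == L
            for b1, b2 in zip(mine, mine[1:]):
                assert b2.start == b1.end + 1

    def test_junction_beyond_length_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            segment_blocks({"ST1": 100}, [SpliceJunction("ST1", 50, 150, 1)])

    def test_refinement_leaves_gene_counts_unchanged(self):
        # adding a junction splits blocks but cannot change gene-level counts
        frags = [pair(f"r{i}", "ST1", (1, 70), (150, 220)) for i in range(30)]
        genes = gene_features({"ST1": 300})
        before = count_fragments(frags, genes).counts.iloc[:, 0].sum()
        # block-level refinement
        blocks = segment_blocks({"ST1": 300}, [SpliceJunction("ST1", 101, 140, 1)])
        assert len(blocks) == 3
        after = count_fragments(frags, genes).counts.iloc[:, 0].sum()
        assert before == after == 30


class TestCountFragments:
    def test_pair_counts_once(self):
        genes = {"G": [("ST1", 1, 500)]}
        ct = count_fragments([pair("r", "ST1", (1, 70), (200, 270))], genes)
        assert ct.counts.loc["G"].iloc[0] == 1

    def test_two_gene_overlap_is_ambiguous(self):
        feats = {"G1": [("ST1", 1, 100)], "G2": [("ST1", 101, 200)]}
        ct = count_fragments([frag("r", "ST1", [(90, 120)])], feats)
        assert ct.summary.iloc[:, 0]["unassigned_ambiguous"] == 1
        assert ct.counts.sum().sum() == 0

    def test_no_overlap_is_no_feature(self):
        feats = {"G1": [("ST1", 1, 100)]}
        ct = count_fragments([frag("r", "ST1", [(300, 350)])], feats)
        assert ct.summary.iloc[:, 0]["unassigned_no_feature"] == 1

    def test_secondary_fragments_ledgered(self):
        feats = {"G1": [("ST1", 1, 100)]}
        ct = count_fragments([frag("r", "ST1", [(1, 50)], primary=False)], feats)
        assert ct.summary.iloc[:, 0]["unassigned_secondary"] == 1

    def test_unknown_reference_rejected(self):
        feats = {"G1": [("ST1", 1, 100)]}
        with pytest.raises(ValueError, match="unknown"):
            count_fragments([frag("r", "STX", [(1, 50)])], feats)

    def test_random_fragments_match_overlap_oracle(self, rng):
        # 1,000 fragments vs a brute-force interval-overlap oracle
        feats = {}
        pos = 1
        for i in range(25):
            n_ex = int(rng.integers(1, 4))
            ivs = []
            for _ in range(n_ex):
                length = int(rng.integers(50, 300))
                ivs.append(("ST1", pos, pos + length - 1))
                pos += length + int(rng.integers(10, 80))
            feats[f"G{i}"] = ivs
        total_span = pos + 200
        frags = []
        for i in range(1000):
            a = int(rng.integers(1, total_span - 300))
            b = a + int(rng.integers(300, 600)) - 70
            frags.append(pair(f"r{i}", "ST1", (a, a + 69), (b, b + 69)))
        ct = count_fragments(frags, feats)
        # oracle
        expected = {g: 0 for g in feats}
        n_amb = n_none = 0
        for f in frags:
            touched = set()
            for mate in f.mates:
                for s, e in mate.intervals:
                    for g, ivs in feats.items():
                        if any(s <= ie and is_ <= e for _, is_, ie in ivs):
                            touched.add(g)
            if len(touched) == 1:
                expected[touched.pop()] += 1
            elif touched:
                n_amb += 1
            else:
                n_none += 1
        assert ct.counts.iloc[:, 0].to_dict() == expected
        col = ct.summary.iloc[:, 0]
        assert col["unassigned_ambiguous"] == n_amb
        assert col["unassigned_no_feature"] == n_none
        # conservation
        assert col.sum() == 1000

    def test_gene_counts_equal_block_sums_on_nested_features(self, rng):
        # single-block-resolvable fragments: gene count == sum of its blocks
        from supertx.models import Block

        blocks = [
            Block("ST1", 1, 100, "b1"),
            Block("ST1", 101, 220, "b2"),
            Block("ST1", 221, 400, "b3"),
        ]
        frags = []
        for i in range(90):
            b = blocks[i % 3]
            s = int(rng.integers(b.start, b.end - 40))
            frags.append(frag(f"r{i}", "ST1", [(s, s + 39)]))
        gene_ct = count_fragments(frags, gene_features({"ST1": 400}))
        block_ct = count_fragments(frags, block_features(blocks))
        assert gene_ct.counts.iloc[:, 0].sum() == block_ct.counts.iloc[:, 0].sum() == 90


class TestWriteCounts:
    def test_round_trip(self, tmp_path, rng):
        feats = {f"G{i}": [("ST1", 1 + 100 * i, 100 + 100 * i)] for i in range(4)}
        frags = {
            "s1": [frag("r1", "ST1", [(10, 50)])],
            "s2": [frag("r2", "ST1", [(110, 150)]), frag("r3", "ST1", [(115, 155)])],
        }
        ct = count_fragments(frags, feats)
        path = tmp_path / "counts.tsv"
        write_counts(ct, path, feats)
        back = read_counts(path)
        assert back.counts.equals(ct.counts)
        assert back.summary.equals(ct.summary)
        # featureCounts layout: expression data starts at column 7
        header = path.read_text().splitlines()[0].split("\t")
        assert header[:6] == ["Geneid", "Chr", "Start", "End", "Strand", "Length"]
        assert header[6:] == ["s1", "s2"]

    def test_empty_table_header_only(self, tmp_path):
        ct = count_fragments({"s1": []}, {})
        write_counts(ct, tmp_path / "c.tsv")
        lines = (tmp_path / "c.tsv").read_text().splitlines()
        assert len(lines) == 1

    def test_random_table_round_trip(self, tmp_path, rng):
        import pandas as pd

        counts = pd.DataFrame(
            rng.integers(0, 500, (30, 4)),
            index=[f"G{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(4)],
        )
        summary = pd.DataFrame(
            rng.integers(0, 100, (4, 4)),
            index=list(count_fragments({"s": []}, {}).summary.index),
            columns=counts.columns,
        )
        from supertx.models import CountTable

        ct = CountTable(counts, summary)
        write_counts(ct, tmp_path / "c.tsv")
        back = read_counts(tmp_path / "c.tsv")
        assert back.counts.equals(counts)
        assert back.summary.equals(summary)
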