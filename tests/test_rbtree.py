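"""The persistent red-black interval engine against the per-base oracle."""

import math

import pytest

from genomictk.errors import AssemblyMismatchError
from genomictk.genome import GenomeAssembly, GenomicInterval
from genomictk.rbtree import BLACK, IntervalSet, audit_tree
from genomictk.synthetic import (
    GeneratorConfig,
    gen_assembly,
    gen_intervals,
    oracle_interval_ops,
)


def spans(s: IntervalSet) -> list[tuple[str, int, int]]:
    return [(iv.seq_name, iv.start, iv.end) for iv in s]


class TestInsert:
    def test_single_insert_black_root(self, toy_assembly):
        s = IntervalSet(toy_assembly).insert(GenomicInterval("chr1", 0, 10))
        root = s.root("chr1")
        assert root is not None and root.color == BLACK
        assert root.left is None and root.right is None

    def test_duplicates_retained(self, toy_assembly):
        s = IntervalSet(toy_assembly)
        iv = GenomicInterval("chr1", 0, 10)
        for _ in range(3):
            s = s.insert(iv)
        assert s.to_list() == [iv, iv, iv]  # multiset semantics

    def test_insert_returns_new_set_and_preserves_old(self, toy_assembly):
        s0 = IntervalSet(toy_assembly)
        s1 = s0.insert(GenomicInterval("chr1", 5, 15))
        s2 = s1.insert(GenomicInterval("chr1", 0, 3))
        assert len(s0) == 0 and len(s1) == 1 and len(s2) == 2
        assert s1.to_list() == [GenomicInterval("chr1", 5, 15)]

    def test_structural_audit_after_many_randomized_inserts(self):
        cfg = GeneratorConfig(
            seed=11, n_sequences=1, seq_length_range=(50_000, 50_000)
        )
        asm = gen_assembly(cfg)
        rng = cfg.rng(99)
        s = IntervalSet(asm)
        n = 2000
        for _ in range(n):
            start = rng.randint(0, 49_000)
            s = s.insert(GenomicInterval("seq1", start, start + rng.randint(1, 500)))
        bh, count, height = audit_tree(s.root("seq1"))
        assert count == n
        assert height <= 2 * math.log2(n + 1)


class TestSearch:
    def test_matches_linear_scan(self, cfg, assembly):
        intervals = gen_intervals(cfg, assembly, 300)
        s = IntervalSet.from_intervals(assembly, intervals)
        rng = cfg.rng(5)
        for _ in range(50):
            name, length = rng.choice(assembly.sequences)
            start = rng.randint(0, length - 10)
            end = min(length, start + rng.randint(1, 400))
            query = GenomicInterval(name, start, end)
            brute = sorted(
                (
                    iv
                    for iv in intervals
                    if iv.seq_name == query.seq_name
                    and iv.start < query.end
                    and query.start < iv.end
                ),
                key=lambda iv: (iv.start, iv.end),
            )
            assert s.search_overlapping(query) == brute

    def test_abutting_query_misses(self, toy_assembly):
        s = IntervalSet(toy_assembly).insert(GenomicInterval("chr1", 0, 10))
        assert s.search_overlapping(GenomicInterval("chr1", 10, 20)) == []

    def test_query_on_empty_sequence(self, toy_assembly):
        s = IntervalSet(toy_assembly).insert(GenomicInterval("chr1", 0, 10))
        assert s.search_overlapping(GenomicInterval("chr2", 0, 50)) == []


class TestSetOperations:
    def test_merge_overlapping_and_abutting(self, toy_assembly):
        s = IntervalSet.from_intervals(
            toy_assembly,
            [
                GenomicInterval("chr1", 1, 5),
                GenomicInterval("chr1", 4, 8),
                GenomicInterval("chr1", 10, 12),
                GenomicInterval("chr2", 0, 5),
                GenomicInterval("chr2", 5, 9),  # abutting: coalesces
            ],
        )
        assert spans(s.merge()) == [
            ("chr1", 1, 8),
            ("chr1", 10, 12),
            ("chr2", 0, 9),
        ]

    def test_merge_idempotent(self, cfg, assembly):
        s = IntervalSet.from_intervals(assembly, gen_intervals(cfg, assembly, 100))
        assert s.merge().merge() == s.merge()

    def test_intersect_basic_and_identities(self, toy_assembly):
        a = IntervalSet.from_intervals(
            toy_assembly, [GenomicInterval("chr1", 0, 10)]
        )
        b = IntervalSet.from_intervals(
            toy_assembly, [GenomicInterval("chr1", 5, 15)]
        )
        empty = IntervalSet(toy_assembly)
        assert spans(a.intersect(b)) == [("chr1", 5, 10)]
        assert a.intersect(empty).to_list() == []
        assert a.intersect(a) == a.merge()

    def test_subtract_basic_and_identities(self, toy_assembly):
        a = IntervalSet.from_intervals(
            toy_assembly, [GenomicInterval("chr1", 0, 10)]
        )
        b = IntervalSet.from_intervals(
            toy_assembly, [GenomicInterval("chr1", 3, 5)]
        )
        empty = IntervalSet(toy_assembly)
        assert spans(a.subtract(b)) == [("chr1", 0, 3), ("chr1", 5, 10)]
        assert a.subtract(a).to_list() == []
        assert a.subtract(empty) == a.merge()

    def test_complement_edge_cases(self, toy_assembly):
        empty = IntervalSet(toy_assembly)
        assert spans(empty.complement()) == [("chr1", 0, 100), ("chr2", 0, 50)]
        full = IntervalSet.from_intervals(
            toy_assembly,
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 0, 50)],
        )
        assert full.complement().to_list() == []

    def test_assembly_mismatch_rejected(self, toy_assembly):
        other_asm = GenomeAssembly.from_pairs([("chr1", 100)])
        with pytest.raises(AssemblyMismatchError):
            IntervalSet(toy_assembly).intersect(IntervalSet(other_asm))


class TestOracleEquivalence:
    """merge/intersect/subtract/complement agree base-for-base with the
    boolean coverage-array oracle on random instances."""

    @pytest.mark.parametrize("seed", range(25))
    def test_all_four_operations(self, seed):
        cfg = GeneratorConfig(
            seed=seed, n_sequences=2, seq_length_range=(500, 5000),
            interval_length_range=(1, 400),
        )
        asm = gen_assembly(cfg)
        rng = cfg.rng(3)
        a_ivs = gen_intervals(cfg, asm, rng.randint(0, 100))
        b_ivs = gen_intervals(
            GeneratorConfig(seed=seed + 10_000, n_sequences=2), asm,
            rng.randint(0, 100),
        )
        a = IntervalSet.from_intervals(asm, a_ivs)
        b = IntervalSet.from_intervals(asm, b_ivs)
        for op, result in (
            ("merge", a.merge()),
            ("complement", a.complement()),
            ("intersect", a.intersect(b)),
            ("subtract", a.subtract(b)),
        ):
            expected = oracle_interval_ops(asm, a_ivs, op, b_ivs)
            assert spans(result) == [
                (iv.seq_name, iv.start, iv.end) for iv in expected
            ], f"{op} diverged from the per-base oracle (seed {seed})"

    def test_algebraic_properties(self, cfg, assembly):
        a = IntervalSet.from_intervals(assembly, gen_intervals(cfg, assembly, 80))
        b_cfg = GeneratorConfig(seed=cfg.seed + 1)
        b = IntervalSet.from_intervals(assembly, gen_intervals(b_cfg, assembly, 80))
        assert a.intersect(b) == b.intersect(a)  # commutative
        assert a.complement().complement() == a.merge()  # involution mod merge
        diff = a.subtract(b)
        assert diff.intersect(b).to_list() == []  # disjoint from subtrahend


class TestPersistence:
    def test_operations_leave_operands_unchanged(self, cfg, assembly):
        a = IntervalSet.from_intervals(assembly, gen_intervals(cfg, assembly, 60))
        b = IntervalSet.from_intervals(
            assembly, gen_intervals(GeneratorConfig(seed=cfg.seed + 2), assembly, 60)
        )
        snapshot_a = a.to_list()
        snapshot_b = b.to_list()
        a.merge()
        a.intersect(b)
        a.subtract(b)
        a.complement()
        a.insert(GenomicInterval(assembly.names[0], 0, 1))
        a.search_overlapping(GenomicInterval(assembly.names[0], 0, 100))
        assert a.to_list() == snapshot_a
        assert b.to_list() == snapshot_b
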