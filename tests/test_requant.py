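import numpy as np
import pytest

from splicetarget.annotate import ContextSequence, add_context_seq, reverse_complement
from splicetarget.core import ContractViolation, SpliceTargetError, parse_junction_id
from splicetarget.fixtures import simulate_reads
from splicetarget.requant import (
    Alignment,
    Read,
    build_intervals,
    count_reads,
    ir_support,
    merge_replicates,
    naive_align,
    read_fastq,
    requantify,
)

from oracles import classify_reads


def _context(seq_len=400, junc_pos=200, event="ES"):
    seq = ("ACGT" * (seq_len // 4 + 1))[:seq_len]
    return ContextSequence(
        junction_id="chrT:1-2:+",
        transcript_id="TX",
        event_class=event,
        cts_seq=seq,
        cts_junc_pos=junc_pos,
        intron_interval=None,
        cts_id=f"ctx{seq_len}_{junc_pos}",
    )


def _ir_context(seq_len=300, intron=(101, 200)):
    seq = ("ACGT" * (seq_len // 4 + 1))[:seq_len]
    return ContextSequence(
        junction_id="chrT:100-101:+",
        transcript_id="TX",
        event_class="IR",
        cts_seq=seq,
        cts_junc_pos=None,
        intron_interval=intron,
        cts_id=f"ir{seq_len}",
    )


class TestBuildIntervals:
    def test_two_intervals_at_junction(self):
        p = build_intervals(_context(400, 200))
        assert p.intervals == ((1, 200), (201, 400))
        assert p.junction_positions == (200,)

    def test_three_intervals_for_ir(self):
        p = build_intervals(_ir_context(300, (101, 200)))
        assert p.intervals == ((1, 100), (101, 200), (201, 300))
        assert p.junction_positions == (100, 200)

    def test_junction_at_sequence_end_is_contract_violation(self):
        with pytest.raises(ContractViolation):
            build_intervals(_context(400, 400))


class TestCountReads:
    def test_ten_base_overlap_is_junction_read(self):
        p = build_intervals(_context(400, 200))
        res = count_reads([Alignment("r", None, 191, 240)], p)
        assert res.primary_junction_reads == 1

    def test_nine_base_overlap_is_not(self):
        p = build_intervals(_context(400, 200))
        res = count_reads([Alignment("r", None, 192, 241)], p)
        assert res.primary_junction_reads == 0

    def test_read_within_first_interval(self):
        p = build_intervals(_context(400, 200))
        res = count_reads([Alignment("r", None, 1, 50)], p)
        assert res.within_interval == [1, 0]
        assert res.primary_junction_reads == 0

    def test_uniform_ir_intron_coverage(self):
        p = build_intervals(_ir_context(300, (101, 200)))
        alignments = [
            Alignment(f"r{d}_{s}", None, s, s + 49)
            for d in range(3)
            for s in range(91, 161, 10)
        ]
        res = count_reads(alignments, p)
        # intron positions 101..200 are tiled at constant depth
        assert res.coverage_median[1] > 0
        assert res.coverage_perc[1] == 100.0

    def test_spanning_pair_counted_for_both_intervals(self):
        p = build_intervals(_context(400, 200))
        res = count_reads(
            [Alignment("r/1", "frag", 10, 59), Alignment("r/2", "frag", 301, 350)], p
        )
        assert res.span_interval_end_pairs == [1, 1]

    def test_alignment_outside_context_rejected(self):
        p = build_intervals(_context(400, 200))
        with pytest.raises(SpliceTargetError):
            count_reads([Alignment("r", None, 390, 440)], p)

    def test_junction_reads_monotone_in_min_overlap(self):
        rng = np.random.default_rng(5)
        p = build_intervals(_context(400, 200))
        alignments = [
            Alignment(f"r{i}", None, s, s + 49)
            for i, s in enumerate(rng.integers(1, 351, size=100))
        ]
        counts = [
            count_reads(alignments, p, min_overlap=d).primary_junction_reads
            for d in range(1, 26)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_oracle_equivalence_500_random_read_sets(self):
        """count_reads matches an independently written per-read classifier."""
        rng = np.random.default_rng(42)
        for trial in range(500):
            if trial % 2:
                length = int(rng.integers(150, 500))
                pos = int(rng.integers(30, length - 30))
                ctx, n_intervals = _context(length, pos), 2
            else:
                length = int(rng.integers(200, 500))
                lo = int(rng.integers(40, length // 2))
                hi = int(rng.integers(lo + 20, length - 30))
                ctx, n_intervals = _ir_context(length, (lo, hi)), 3
            partition = build_intervals(ctx)
            alignments = []
            for i in range(int(rng.integers(0, 25))):
                rl = int(rng.integers(20, 80))
                s = int(rng.integers(1, length - rl + 1))
                mate = f"m{i // 2}" if rng.random() < 0.6 else None
                alignments.append(Alignment(f"r{i}", mate, s, s + rl - 1))
            got = count_reads(alignments, partition)
            exp = classify_reads(
                [(a.read_id, a.mate_id, a.start, a.end) for a in alignments],
                list(partition.intervals),
                list(partition.junction_positions),
            )
            assert got.junction_reads == exp["junction_reads"]
            assert got.overlap_interval_end_reads == exp["overlap_interval_end_reads"]
            assert got.within_interval == exp["within_interval"]
            assert got.span_interval_end_pairs == exp["span_interval_end_pairs"]
            for i in range(n_intervals):
                assert got.coverage_perc[i] == pytest.approx(exp["coverage"][i]["perc"])
                assert got.coverage_mean[i] == pytest.approx(exp["coverage"][i]["mean"])
                assert got.coverage_median[i] == exp["coverage"][i]["median"]


class TestMergeReplicates:
    def _result(self, *alignments):
        p = build_intervals(_context(400, 200))
        return count_reads(list(alignments), p)

    def test_counts_sum(self):
        a = self._result(Alignment("a", None, 191, 240), Alignment("b", None, 180, 260))
        b = self._result(Alignment("c", None, 185, 235))
        merged = merge_replicates([a, b])
        assert merged.primary_junction_reads == 3

    def test_commutative_and_associative(self):
        rng = np.random.default_rng(3)
        results = []
        for _ in range(3):
            alns = [
                Alignment(f"r{i}", None, int(s), int(s) + 40)
                for i, s in enumerate(rng.integers(1, 360, size=10))
            ]
            results.append(self._result(*alns))
        ab_c = merge_replicates([merge_replicates(results[:2]), results[2]])
        a_bc = merge_replicates([results[0], merge_replicates(results[1:])])
        ba = merge_replicates([results[1], results[0]])
        ab = merge_replicates(results[:2])
        assert ab.junction_reads == ba.junction_reads
        assert ab_c.junction_reads == a_bc.junction_reads
        assert all((x == y).all() for x, y in zip(ab_c.depth, a_bc.depth))

    def test_single_input_identity(self):
        a = self._result(Alignment("a", None, 191, 240))
        merged = merge_replicates([a])
        assert merged.primary_junction_reads == a.primary_junction_reads

    def test_empty_list_rejected(self):
        with pytest.raises(SpliceTargetError):
            merge_replicates([])

    def test_mismatched_contexts_rejected(self):
        a = self._result()
        b = count_reads([], build_intervals(_context(300, 100)))
        with pytest.raises(SpliceTargetError):
            merge_replicates([a, b])


class TestIrSupport:
    def test_zero_median_is_unsupported(self):
        res = count_reads([], build_intervals(_ir_context()))
        assert not ir_support(res)

    def test_positive_median_is_supported(self):
        p = build_intervals(_ir_context(300, (101, 200)))
        alignments = [Alignment(f"r{s}", None, s, s + 49) for s in range(90, 160, 5)]
        res = count_reads(alignments, p)
        assert ir_support(res)

    def test_half_covered_intron_uses_lower_median(self):
        # depth 2 on half the intron, 0 on the other half -> lower median 0
        p = build_intervals(_ir_context(300, (101, 200)))
        alignments = [
            Alignment(f"r{i}", None, 101, 150) for i in range(2)
        ]
        res = count_reads(alignments, p)
        assert res.coverage_median[1] == 0.0
        assert not ir_support(res)

    def test_two_interval_result_is_contract_violation(self):
        res = count_reads([], build_intervals(_context()))
        with pytest.raises(ContractViolation):
            ir_support(res)


class TestNaiveAlign:
    def test_exact_match_placement(self):
        rng = np.random.default_rng(7)
        ctx = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        read = Read("r", ctx[190:240])
        (aln,) = naive_align([read], ctx)
        assert (aln.start, aln.end) == (191, 240)

    def test_one_mismatch_in_50nt_rejected(self):
        rng = np.random.default_rng(8)
        ctx = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        seq = list(ctx[190:240])
        seq[25] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[25]]
        assert naive_align([Read("r", "".join(seq))], ctx) == []

    def test_one_mismatch_in_100nt_accepted(self):
        rng = np.random.default_rng(9)
        ctx = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        seq = list(ctx[150:250])
        seq[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[50]]
        (aln,) = naive_align([Read("r", "".join(seq))], ctx)
        assert (aln.start, aln.end) == (151, 250)

    def test_reverse_complement_reads_align(self):
        rng = np.random.default_rng(10)
        ctx = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        read = Read("r", reverse_complement(ctx[190:240]))
        (aln,) = naive_align([read], ctx)
        assert (aln.start, aln.end) == (191, 240)


class TestSimulatedReadsClosedLoop:
    def test_planted_depth_recovered(self, tx1, genome, rng):
        junction = parse_junction_id("chrT:200-501:+", "ES")
        ctx = add_context_seq(junction, tx1, genome)
        reads = simulate_reads(ctx, depth=5, read_length=50, rng=rng)
        results = requantify([ctx], reads)
        assert results[ctx.cts_id].primary_junction_reads == 5

    def test_negative_control_reads_never_counted(self, tx1, genome, rng):
        junction = parse_junction_id("chrT:200-501:+", "ES")
        ctx = add_context_seq(junction, tx1, genome)
        reads = simulate_reads(
            ctx, depth=8, read_length=50, rng=rng, negative_control=True
        )
        results = requantify([ctx], reads)
        assert results[ctx.cts_id].primary_junction_reads == 0
        # the reads did align (they cover the breakpoint, just 9 bp short)
        assert max(results[ctx.cts_id].coverage_mean) > 0

    def test_depth_zero_gives_no_reads(self, tx1, genome, rng):
        junction = parse_junction_id("chrT:200-501:+", "ES")
        ctx = add_context_seq(junction, tx1, genome)
        assert simulate_reads(ctx, depth=0, read_length=50, rng=rng) == []

    def test_read_length_must_span_overlap(self, tx1, genome, rng):
        junction = parse_junction_id("chrT:200-501:+", "ES")
        ctx = add_context_seq(junction, tx1, genome)
        with pytest.raises(SpliceTargetError):
            simulate_reads(ctx, depth=1, read_length=15, rng=rng)


def test_fastq_round_trip(tmp_path, tx1, genome, rng):
    from splicetarget.fixtures import write_fastq

    junction = parse_junction_id("chrT:200-501:+", "ES")
    ctx = add_context_seq(junction, tx1, genome)
    reads = simulate_reads(ctx, depth=3, read_length=50, rng=rng)
    path = tmp_path / "reads.fastq"
    write_fastq(reads, str(path))
    loaded = read_fastq(str(path))
    assert [r.seq for r in loaded] == [r.seq for r in reads]
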