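"""Targeted requantification of splice junctions against context sequences.

Each candidate junction's context sequence is used as a miniature mapping
reference.  The context is partitioned into intervals — two for exon
skipping and alternative splice sites (the end of the first interval is the
junction breakpoint), three for intron retention (the middle interval is
the retained intron).  Per interval and junction the counters are:

* ``junction_reads`` / ``overlap_interval_end_reads``: reads covering an
  interval-end position with at least ``min_overlap`` aligned bases on each
  side of it (default 10);
* ``span_interval_end_pairs``: read pairs whose two mates map fully inside
  different intervals;
* ``within_interval``: reads mapping completely inside one interval;
* ``coverage_perc`` / ``coverage_mean`` / ``coverage_median``: per-position
  depth summaries (the median is the lower median, conservative for the
  "median coverage > 0" intron-retention support call).

A small end-to-end aligner (`naive_align`) places error-free or
low-mismatch reads on the context (mismatch fraction <= ``mismatch_ratio``,
no indels), so the whole engine runs without an external aligner;
pre-aligned SAM input against the context FASTA is accepted as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import ContractViolation, SpliceTargetError
from .annotate import ContextSequence, reverse_complement


@dataclass(frozen=True)
class Alignment:
    """End-to-end placement of one read on a context sequence (1-based)."""

    read_id: str
    mate_id: str | None
    start: int
    end: int


@dataclass(frozen=True)
class Read:
    """A plain read sequence; ``mate_id`` groups the two mates of a pair."""

    read_id: str
    seq: str
    mate_id: str | None = None


@dataclass(frozen=True)
class IntervalPartition:
    """Tiling of a context sequence into junction-delimited intervals."""

    cts_id: str
    intervals: tuple[tuple[int, int], ...]
    junction_positions: tuple[int, ...]

    @property
    def length(self) -> int:
        return self.intervals[-1][1]


@dataclass
class RequantResult:
    """Table-2-style counters for one context sequence."""

    cts_id: str
    partition: IntervalPartition
    junction_reads: dict[int, int]  # junction position -> qualified read count
    overlap_interval_end_reads: list[int]
    span_interval_end_pairs: list[int]
    within_interval: list[int]
    depth: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def coverage_perc(self) -> list[float]:
        return [100.0 * float((d > 0).mean()) if d.size else 0.0 for d in self.depth]

    @property
    def coverage_mean(self) -> list[float]:
        return [float(d.mean()) if d.size else 0.0 for d in self.depth]

    @property
    def coverage_median(self) -> list[float]:
        return [_lower_median(d) for d in self.depth]

    @property
    def primary_junction_reads(self) -> int:
        """Reads supporting the junction of interest (first breakpoint)."""
        return self.junction_reads[self.partition.junction_positions[0]]


def _lower_median(depth: np.ndarray) -> float:
    if depth.size == 0:
        return 0.0
    return float(np.sort(depth)[(depth.size - 1) // 2])


def build_intervals(context: ContextSequence) -> IntervalPartition:
    """Partition a context sequence at its breakpoint(s).

    ES/A3SS/A5SS contexts split at ``cts_junc_pos`` into two intervals; IR
    contexts split around ``intron_interval`` into three, the middle one
    being the retained intron.
    """
    length = len(context.cts_seq)
    if context.event_class == "IR":
        assert context.intron_interval is not None
        lo, hi = context.intron_interval
        if lo <= 1 or hi >= length:
            raise ContractViolation(
                f"IR context {context.cts_id} has no exonic flank around the intron"
            )
        intervals = ((1, lo - 1), (lo, hi), (hi + 1, length))
        junction_positions = (lo - 1, hi)
    else:
        pos = context.cts_junc_pos
        if pos is None or pos <= 0 or pos >= length:
            raise ContractViolation(
                f"context {context.cts_id}: junction position {pos} does not "
                f"split the sequence"
            )
        intervals = ((1, pos), (pos + 1, length))
        junction_positions = (pos,)
    return IntervalPartition(
        cts_id=context.cts_id,
        intervals=intervals,
        junction_positions=junction_positions,
    )


def _overlaps_position(aln: Alignment, pos: int, min_overlap: int) -> bool:
    """>= min_overlap aligned bases on each side of the breakpoint after pos."""
    return aln.start <= pos - min_overlap + 1 and aln.end >= pos + min_overlap


def count_reads(
    alignments: Iterable[Alignment],
    partition: IntervalPartition,
    min_overlap: int = 10,
) -> RequantResult:
    """Classify alignments into the per-interval and per-junction counters."""
    alignments = list(alignments)
    length = partition.length
    intervals = partition.intervals
    n = len(intervals)
    for aln in alignments:
        if aln.start < 1 or aln.end > length or aln.start > aln.end:
            raise SpliceTargetError(
                f"alignment {aln.read_id} ({aln.start}-{aln.end}) outside "
                f"context of length {length}"
            )
    junction_reads = {
        pos: sum(_overlaps_position(a, pos, min_overlap) for a in alignments)
        for pos in partition.junction_positions
    }
    overlap_end = [
        sum(_overlaps_position(a, hi, min_overlap) for a in alignments)
        if i < n - 1
        else 0
        for i, (lo, hi) in enumerate(intervals)
    ]
    within = [
        sum(lo <= a.start and a.end <= hi for a in alignments)
        for lo, hi in intervals
    ]

    def interval_of(aln: Alignment) -> int | None:
        for i, (lo, hi) in enumerate(intervals):
            if lo <= aln.start and aln.end <= hi:
                return i
        return None

    span = [0] * n
    pairs: dict[str, list[Alignment]] = {}
    for aln in alignments:
        if aln.mate_id is not None:
            pairs.setdefault(aln.mate_id, []).append(aln)
    for mates in pairs.values():
        if len(mates) != 2:
            continue
        i, j = interval_of(mates[0]), interval_of(mates[1])
        if i is not None and j is not None and i != j:
            span[i] += 1
            span[j] += 1

    depth = []
    for lo, hi in intervals:
        d = np.zeros(hi - lo + 1, dtype=np.int64)
        for aln in alignments:
            a, b = max(aln.start, lo), min(aln.end, hi)
            if a <= b:
                d[a - lo : b - lo + 1] += 1
        depth.append(d)

    return RequantResult(
        cts_id=partition.cts_id,
        partition=partition,
        junction_reads=junction_reads,
        overlap_interval_end_reads=overlap_end,
        span_interval_end_pairs=span,
        within_interval=within,
        depth=depth,
    )


def merge_replicates(results: Sequence[RequantResult]) -> RequantResult:
    """Sum counters and depth arrays across replicates of one context."""
    if not results:
        raise SpliceTargetError("merge_replicates requires at least one result")
    first = results[0]
    for r in results[1:]:
        if r.cts_id != first.cts_id:
            raise SpliceTargetError(
                f"cannot merge requant results of different contexts: "
                f"{first.cts_id} vs {r.cts_id}"
            )
    merged = RequantResult(
        cts_id=first.cts_id,
        partition=first.partition,
        junction_reads={
            pos: sum(r.junction_reads[pos] for r in results)
            for pos in first.partition.junction_positions
        },
        overlap_interval_end_reads=[
            sum(vals) for vals in zip(*(r.overlap_interval_end_reads for r in results))
        ],
        span_interval_end_pairs=[
            sum(vals) for vals in zip(*(r.span_interval_end_pairs for r in results))
        ],
        within_interval=[
            sum(vals) for vals in zip(*(r.within_interval for r in results))
        ],
        depth=[sum(ds) for ds in zip(*(r.depth for r in results))],
    )
    return merged


def ir_support(result: RequantResult) -> bool:
    """Intron-retention support: median coverage of the intron interval > 0."""
    if len(result.partition.intervals) != 3:
        raise ContractViolation("ir_support requires a 3-interval (IR) partition")
    return result.coverage_median[1] > 0


def naive_align(
    reads: Iterable[Read],
    cts_seq: str,
    mismatch_ratio: float = 0.015,
) -> list[Alignment]:
    """End-to-end exact scan of reads against one context sequence.

    A read is placed where its mismatch fraction is minimal and within
    ``mismatch_ratio``; both orientations are tried, indels are not allowed
    (mirroring an end-to-end aligner with prohibitive gap penalties).  One
    (best, leftmost) placement per read is reported.
    """
    cts = cts_seq.upper()
    cts_arr = np.frombuffer(cts.encode("ascii"), dtype=np.uint8)
    windows_cache: dict[int, np.ndarray] = {}
    out = []
    for read in reads:
        seq = read.seq.upper()
        rl = len(seq)
        if rl > len(cts) or rl == 0:
            continue
        budget = int(mismatch_ratio * rl)  # max mismatches allowed
        if rl not in windows_cache:
            windows_cache[rl] = np.lib.stride_tricks.sliding_window_view(cts_arr, rl)
        windows = windows_cache[rl]
        best: tuple[int, int] | None = None  # (mismatches, offset)
        for candidate in (seq, reverse_complement(seq)):
            cand_arr = np.frombuffer(candidate.encode("ascii"), dtype=np.uint8)
            mism = (windows != cand_arr).sum(axis=1)
            off = int(mism.argmin())
            if mism[off] <= budget and (best is None or mism[off] < best[0]):
                best = (int(mism[off]), off)
        if best is not None:
            out.append(
                Alignment(
                    read_id=read.read_id,
                    mate_id=read.mate_id,
                    start=best[1] + 1,
                    end=best[1] + rl,
                )
            )
    return out


def read_fastq(path: str, mate: int | None = None) -> list[Read]:
    """Load reads from a (plain-text) FASTQ file.

    ``mate`` tags reads of one file of a pair; the fragment name becomes the
    ``mate_id`` so pair spanning can be detected after alignment.
    """
    import pysam

    reads = []
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            name = entry.name
            read_id = f"{name}/{mate}" if mate is not None else name
            reads.append(Read(read_id=read_id, seq=entry.sequence, mate_id=name))
    return reads


def read_sam(path: str) -> dict[str, list[Alignment]]:
    """Load pre-aligned reads from SAM, grouped by context (reference) name."""
    import pysam

    by_ref: dict[str, list[Alignment]] = {}
    with pysam.AlignmentFile(path, "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            by_ref.setdefault(rec.reference_name, []).append(
                Alignment(
                    read_id=rec.query_name or "",
                    mate_id=rec.query_name,
                    start=rec.reference_start + 1,
                    end=rec.reference_end or rec.reference_start + 1,
                )
            )
    return by_ref


def requantify(
    contexts: Iterable[ContextSequence],
    reads: Sequence[Read],
    min_overlap: int = 10,
    mismatch_ratio: float = 0.015,
) -> dict[str, RequantResult]:
    """Align reads against every context and count support, keyed by cts_id.

    A read aligning to several contexts counts once per context: the engine
    quantifies per-candidate evidence, not a global read assignment.
    """
    results = {}
    for context in contexts:
        partition = build_intervals(context)
        alignments = naive_align(reads, context.cts_seq, mismatch_ratio)
        results[context.cts_id] = count_reads(alignments, partition, min_overlap)
    return results
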