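"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive expected results from first principles — an
explicit case table per strand for the effect-to-junction rules, a
per-read classifier for requantification and base-set arithmetic for CDS
splicing — and share no code with the package internals they verify.
"""

from __future__ import annotations


def table1_junctions(kind: str, pos: int, tx: dict) -> set[tuple[str, int, int]]:
    """Expected junctions for one effect on one transcript.

    ``tx`` is a plain dict: ``{"strand": "+", "exons": [(lo, hi), ...]}``
    with exons sorted in genomic order.  Returns tuples of
    ``(event_class, start, end)`` with start < end.
    """
    strand = tx["strand"]
    exons = sorted(tuple(e) for e in tx["exons"])
    span_lo, span_hi = exons[0][0], exons[-1][1]
    if not (span_lo <= pos <= span_hi):
        return set()

    def exonic(p: int) -> bool:
        return any(lo <= p <= hi for lo, hi in exons)

    out: set[tuple[str, int, int]] = set()
    if strand == "+":
        order = exons
        donor = {i: e[1] for i, e in enumerate(order)}
        acceptor = {i: e[0] for i, e in enumerate(order)}
        offset = 1
    else:
        order = list(reversed(exons))
        donor = {i: e[0] for i, e in enumerate(order)}
        acceptor = {i: e[1] for i, e in enumerate(order)}
        offset = -1

    def add(event, a, b):
        if a != b:
            out.add((event, min(a, b), max(a, b)))

    def add_ir(a, b):
        lo, hi = min(a, b), max(a, b)
        if exonic(lo) != exonic(hi):
            out.add(("IR", lo, hi))

    n = len(order)
    if kind == "donor_loss":
        for k in range(n):
            if donor[k] == pos:
                add_ir(pos, pos + offset)
                if 1 <= k <= n - 2:
                    add("ES", donor[k - 1], acceptor[k + 1])
    elif kind == "acceptor_loss":
        for k in range(n):
            if acceptor[k] == pos:
                add_ir(pos - offset, pos)
                if 1 <= k <= n - 2:
                    add("ES", donor[k - 1], acceptor[k + 1])
    elif kind == "donor_gain":
        if strand == "+":
            starts = [lo for lo, hi in exons if lo > pos]
            if starts:
                add("A5SS", pos, min(starts))
        else:
            ends = [hi for lo, hi in exons if hi < pos]
            if ends:
                add("A5SS", pos, max(ends))
    elif kind == "acceptor_gain":
        if strand == "+":
            ends = [hi for lo, hi in exons if hi < pos]
            if ends:
                add("A3SS", ends[-1], pos)
        else:
            starts = [lo for lo, hi in exons if lo > pos]
            if starts:
                add("A3SS", pos, starts[0])
    else:
        raise ValueError(kind)
    return out


def classify_reads(
    alignments: list[tuple[str, str | None, int, int]],
    intervals: list[tuple[int, int]],
    junction_positions: list[int],
    min_overlap: int = 10,
) -> dict:
    """Per-read brute-force classification into the requant counters."""
    n = len(intervals)
    length = intervals[-1][1]

    def covers(start, end, p):
        left = p - start + 1
        right = end - p
        return left >= min_overlap and right >= min_overlap

    junction_reads = {
        p: sum(covers(s, e, p) for (_, _, s, e) in alignments)
        for p in junction_positions
    }
    overlap_end = []
    for i, (lo, hi) in enumerate(intervals):
        if i == n - 1:
            overlap_end.append(0)
        else:
            overlap_end.append(sum(covers(s, e, hi) for (_, _, s, e) in alignments))
    within = [
        sum(lo <= s and e <= hi for (_, _, s, e) in alignments)
        for lo, hi in intervals
    ]

    def home(s, e):
        for i, (lo, hi) in enumerate(intervals):
            if lo <= s and e <= hi:
                return i
        return None

    span = [0] * n
    mates: dict[str, list] = {}
    for rid, mid, s, e in alignments:
        if mid is not None:
            mates.setdefault(mid, []).append((s, e))
    for group in mates.values():
        if len(group) == 2:
            i, j = home(*group[0]), home(*group[1])
            if i is not None and j is not None and i != j:
                span[i] += 1
                span[j] += 1

    depth = [0] * length
    for _, _, s, e in alignments:
        for p in range(s, e + 1):
            depth[p - 1] += 1
    cov = []
    for lo, hi in intervals:
        d = sorted(depth[lo - 1 : hi])
        cov.append(
            {
                "perc": 100.0 * sum(x > 0 for x in d) / len(d),
                "mean": sum(d) / len(d),
                "median": float(d[(len(d) - 1) // 2]),
            }
        )
    return {
        "junction_reads": junction_reads,
        "overlap_interval_end_reads": overlap_end,
        "within_interval": within,
        "span_interval_end_pairs": span,
        "coverage": cov,
    }


def excised_cds_length(
    cds: list[tuple[int, int]], start: int, end: int
) -> tuple[int, int]:
    """Wild-type and modified CDS lengths for an exonic-anchor junction.

    The junction keeps coding bases at positions <= start and >= end; the
    open interval between the anchors is excised.  Valid for junctions whose
    anchors both lie on (modified) exonic sequence.
    """
    coding = set()
    for lo, hi in cds:
        coding.update(range(lo, hi + 1))
    wt = len(coding)
    mod = sum(1 for p in coding if p <= start or p >= end)
    return wt, mod
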