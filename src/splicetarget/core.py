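"""Unified splice-junction model and coordinate conventions.

A splice junction is identified by the chromosome, the last genomic base of
the left exon (``start``), the first genomic base of the right exon
(``end``) and the strand, encoded as the string ``"chrom:start-end:strand"``.
Coordinates are 1-based inclusive and genomically ordered (``start < end``)
regardless of strand; transcript-oriented notions ("upstream", "downstream")
are handled by :class:`TranscriptModel`.

Intron-retention (IR) events are represented as width-1 pseudo-junctions
(``end == start + 1``) that straddle an exon-intron boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

EVENT_CLASSES = ("A3SS", "A5SS", "ES", "IR", "canonical", "unknown")

_JUNCTION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+-])$")


class SpliceTargetError(Exception):
    """Base class for errors raised by this package."""


class InvalidJunctionError(SpliceTargetError):
    """A junction with degenerate or impossible coordinates."""


class JunctionParseError(SpliceTargetError):
    """A junction string that does not follow ``chrom:start-end:strand``."""


class ContractViolation(SpliceTargetError):
    """An operation was called with input outside its contract."""


def encode_junction(chrom: str, start: int, end: int, strand: str) -> str:
    """Encode a junction as ``"chrom:start-end:strand"``.

    Coordinates arriving in descending (transcript) order are swapped so the
    encoded string is always genomically ordered.  A zero-length junction
    (``start == end``) is rejected.
    """
    if strand not in ("+", "-"):
        raise InvalidJunctionError(f"strand must be '+' or '-', got {strand!r}")
    if start <= 0 or end <= 0:
        raise InvalidJunctionError(f"positions must be positive: {start}, {end}")
    if start == end:
        raise InvalidJunctionError(
            f"zero-length junction {chrom}:{start}-{end}:{strand}"
        )
    if start > end:
        start, end = end, start
    return f"{chrom}:{start}-{end}:{strand}"


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """One splice junction in the unified representation."""

    chrom: str
    start: int
    end: int
    strand: str
    event_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise InvalidJunctionError(f"unknown event class {self.event_class!r}")
        if self.start >= self.end:
            raise InvalidJunctionError(
                f"junction coordinates must satisfy start < end: "
                f"{self.chrom}:{self.start}-{self.end}:{self.strand}"
            )
        if self.event_class == "IR" and self.end != self.start + 1:
            raise InvalidJunctionError(
                f"IR junction must have end == start + 1: {self.junction_id}"
            )
        encode_junction(self.chrom, self.start, self.end, self.strand)

    @property
    def junction_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def is_ir_shaped(self) -> bool:
        return self.end == self.start + 1

    def with_event_class(self, event_class: str) -> "SpliceJunction":
        return replace(self, event_class=event_class)


def parse_junction_id(junction_id: str, event_class: str = "unknown") -> SpliceJunction:
    """Parse a ``"chrom:start-end:strand"`` string into a :class:`SpliceJunction`."""
    m = _JUNCTION_RE.match(junction_id)
    if m is None:
        raise JunctionParseError(f"malformed junction id {junction_id!r}")
    start, end = int(m["start"]), int(m["end"])
    if start >= end:
        raise JunctionParseError(
            f"junction id {junction_id!r} has start >= end ({start} >= {end})"
        )
    return SpliceJunction(m["chrom"], start, end, m["strand"], event_class)


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exon (and optional CDS) structure of one transcript.

    ``exons`` and ``cds`` are 1-based inclusive genomic intervals sorted by
    genomic coordinate.  "Upstream"/"downstream" refer to transcript
    orientation: on the minus strand that is descending genomic order.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SpliceTargetError(f"bad strand {self.strand!r} for {self.transcript_id}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", tuple(sorted(tuple(c) for c in self.cds)))
        prev_end = None
        for lo, hi in exons:
            if lo > hi:
                raise SpliceTargetError(f"inverted exon {lo}-{hi} in {self.transcript_id}")
            if prev_end is not None and lo <= prev_end + 1:
                raise SpliceTargetError(
                    f"exons overlap or touch in {self.transcript_id}: "
                    f"...{prev_end} / {lo}..."
                )
            prev_end = hi
        for lo, hi in self.cds:
            if not any(elo <= lo and hi <= ehi for elo, ehi in exons):
                raise SpliceTargetError(
                    f"CDS interval {lo}-{hi} not contained in an exon of "
                    f"{self.transcript_id}"
                )

    # -- transcript-oriented views ------------------------------------

    @property
    def exons_tx_order(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def tx_start(self) -> int:
        """Genomic position of the transcript's first (5') base."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def tx_end(self) -> int:
        """Genomic position of the transcript's last (3') base."""
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    def donor_site(self, exon: tuple[int, int]) -> int:
        """Genomic position of the exon's donor base (transcript 3' end of exon)."""
        return exon[1] if self.strand == "+" else exon[0]

    def acceptor_site(self, exon: tuple[int, int]) -> int:
        """Genomic position of the exon's acceptor base (transcript 5' end)."""
        return exon[0] if self.strand == "+" else exon[1]

    def is_exonic(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.exons)

    def exon_at(self, pos: int) -> tuple[int, int] | None:
        for lo, hi in self.exons:
            if lo <= pos <= hi:
                return (lo, hi)
        return None

    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals between consecutive exons."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )


def is_exon_intron_boundary(junction: SpliceJunction, transcript: TranscriptModel) -> bool:
    """True iff an IR-shaped junction straddles an exon-intron boundary.

    Exactly one of the two junction bases must be exonic in the given
    transcript.  Raises :class:`ContractViolation` for non-IR-shaped input.
    """
    if not junction.is_ir_shaped:
        raise ContractViolation(
            f"is_exon_intron_boundary requires an IR-shaped junction, got "
            f"{junction.junction_id}"
        )
    return transcript.is_exonic(junction.start) != transcript.is_exonic(junction.end)


def load_transcripts(gtf_path: str) -> dict[str, TranscriptModel]:
    """Read transcript models (exon + CDS features) from a GTF file.

    Uses an in-memory gffutils database; attribute keys ``transcript_id``
    and ``gene_id`` are required on exon features.  Chromosome names are
    taken verbatim.
    """
    import gffutils

    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start, feat.end))
    models = {}
    for tid, (gid, chrom, strand) in meta.items():
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=tuple(exons.get(tid, ())),
            cds=tuple(cds.get(tid, ())),
        )
    return models
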