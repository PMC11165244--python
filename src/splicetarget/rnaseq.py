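"""Ingest RNA-seq derived junction calls and junction databases.

Junction callers disagree on coordinate dialects.  The unified format used
here stores the last exonic base of the left flank and the first exonic base
of the right flank (1-based, genomic order).  Readers convert explicitly:

* LeafCutter/regtools-like tables report intron coordinates; with the
  default ``intronic_1based`` dialect an intron ``s..e`` becomes the
  junction ``(s - 1, e + 1)``.  The ``bed0`` dialect accepts 0-based
  half-open intron coordinates instead.
* SplAdder-like event tables report exonic boundary coordinates per event
  type; every junction implied by an event is emitted, including canonical
  inclusion junctions (they are removed later against the canonical
  database, not at parse time).

Canonical and "normal" junction databases are exact string-match sets of
normalised junction ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .core import (
    InvalidJunctionError,
    SpliceJunction,
    SpliceTargetError,
    TranscriptModel,
    parse_junction_id,
)

logger = logging.getLogger(__name__)

LEAFCUTTER_DIALECTS = ("intronic_1based", "bed0")


@dataclass
class JunctionSet:
    """Junctions observed in one sample, with read counts and source tools."""

    sample_id: str
    junctions: dict[str, SpliceJunction] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    tools: dict[str, set[str]] = field(default_factory=dict)

    def add(self, junction: SpliceJunction, count: int = 0, tool: str = "unknown") -> None:
        if count < 0:
            raise SpliceTargetError(f"negative junction count {count}")
        jid = junction.junction_id
        if jid in self.junctions:
            self.counts[jid] += count
        else:
            self.junctions[jid] = junction
            self.counts[jid] = count
        self.tools.setdefault(jid, set()).add(tool)

    def __contains__(self, junction_id: str) -> bool:
        return junction_id in self.junctions

    def __len__(self) -> int:
        return len(self.junctions)

    def ids(self) -> set[str]:
        return set(self.junctions)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": self.sample_id,
                "junction_id": jid,
                "event_class": j.event_class,
                "count": self.counts[jid],
                "tools": ",".join(sorted(self.tools[jid])),
            }
            for jid, j in sorted(self.junctions.items())
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "junction_id", "event_class", "count", "tools"]
        )


@dataclass(frozen=True)
class JunctionDatabase:
    """A labelled set of junction ids (canonical / normal / healthy tissue)."""

    label: str
    junctions: frozenset[str]

    def __contains__(self, junction_id: str) -> bool:
        return junction_id in self.junctions

    def __len__(self) -> int:
        return len(self.junctions)

    @classmethod
    def from_file(cls, path: str, label: str) -> "JunctionDatabase":
        """Load a flat junction-id list, one ``chrom:start-end:strand`` per line."""
        ids = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                ids.add(parse_junction_id(line).junction_id)
        return cls(label=label, junctions=frozenset(ids))

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            for jid in sorted(self.junctions):
                fh.write(jid + "\n")


class FilterResult(NamedTuple):
    kept: "JunctionSet"
    removed: dict[str, str]  # junction_id -> database label that matched


def _resolve_strands(
    chrom: str,
    start: int,
    end: int,
    transcripts: Iterable[TranscriptModel] | None,
) -> list[str]:
    """Infer junction strand(s) from transcript overlap; both if ambiguous."""
    if transcripts is None:
        raise SpliceTargetError(
            f"no strand column and no annotation to infer strand for "
            f"{chrom}:{start}-{end}"
        )
    strands = set()
    for tx in transcripts:
        lo, hi = tx.span()
        if tx.chrom == chrom and lo <= start and end <= hi:
            strands.add(tx.strand)
    if not strands:
        logger.warning(
            "junction %s:%d-%d overlaps no transcript; emitted on both strands",
            chrom,
            start,
            end,
        )
        return ["+", "-"]
    if len(strands) == 2:
        logger.info("junction %s:%d-%d strand is ambiguous", chrom, start, end)
    return sorted(strands)


def parse_leafcutter(
    counts_table: str | pd.DataFrame,
    sample_id: str,
    dialect: str = "intronic_1based",
    transcripts: Iterable[TranscriptModel] | None = None,
) -> JunctionSet:
    """Parse a LeafCutter/regtools-like intron count table.

    Expects columns ``intron`` (``chrom:start:end:cluster``) and ``count``,
    plus an optional ``strand`` column.  Without a strand column the strand
    is inferred from transcript overlap; ambiguous junctions are emitted
    once per strand.  Zero-count rows are retained (presence != support).
    """
    if dialect not in LEAFCUTTER_DIALECTS:
        raise SpliceTargetError(
            f"unknown LeafCutter dialect {dialect!r}; supported: "
            f"{', '.join(LEAFCUTTER_DIALECTS)}"
        )
    if isinstance(counts_table, (str, bytes)):
        counts_table = pd.read_csv(counts_table, sep="\t")
    jset = JunctionSet(sample_id=sample_id)
    has_strand = "strand" in counts_table.columns
    for row in counts_table.to_dict("records"):
        chrom, s, e = str(row["intron"]).split(":")[:3]
        s, e = int(s), int(e)
        if dialect == "intronic_1based":
            start, end = s - 1, e + 1
        else:  # bed0: 0-based half-open intron
            start, end = s, e + 1
        strands = [str(row["strand"])] if has_strand else _resolve_strands(
            chrom, start, end, transcripts
        )
        for strand in strands:
            jset.add(
                SpliceJunction(chrom, start, end, strand),
                count=int(row["count"]),
                tool="leafcutter",
            )
    return jset


def parse_spladder(
    event_table: str | pd.DataFrame, sample_id: str
) -> JunctionSet:
    """Parse a SplAdder-like event table into all implied junctions.

    One row per event; the ``event_type`` column selects the coordinate
    columns.  An ES event emits the skip junction and both inclusion
    junctions; an IR event emits the IR-shaped junctions at both intron
    boundaries; A3SS/A5SS events emit both alternative junctions.
    Malformed rows are skipped with a warning.
    """
    if isinstance(event_table, (str, bytes)):
        event_table = pd.read_csv(event_table, sep="\t")
    jset = JunctionSet(sample_id=sample_id)
    n_skipped = 0
    for row in event_table.to_dict("records"):
        try:
            chrom, strand = str(row["chrom"]), str(row["strand"])
            etype = str(row["event_type"])
            raw_count = row.get("count")
            count = 0 if raw_count is None or pd.isna(raw_count) else int(raw_count)
            if etype == "ES":
                e1, s2, e2, s3 = (
                    int(row["e1_end"]),
                    int(row["e2_start"]),
                    int(row["e2_end"]),
                    int(row["e3_start"]),
                )
                pairs = [("ES", e1, s3), ("canonical", e1, s2), ("canonical", e2, s3)]
            elif etype == "A5SS":
                pairs = [
                    ("A5SS", int(row["alt1_end"]), int(row["e2_start"])),
                    ("A5SS", int(row["alt2_end"]), int(row["e2_start"])),
                ]
            elif etype == "A3SS":
                pairs = [
                    ("A3SS", int(row["e1_end"]), int(row["alt1_start"])),
                    ("A3SS", int(row["e1_end"]), int(row["alt2_start"])),
                ]
            elif etype == "IR":
                s, e = int(row["intron_start"]), int(row["intron_end"])
                pairs = [("IR", s - 1, s), ("IR", e, e + 1)]
            else:
                raise ValueError(f"unknown event type {etype!r}")
            for event_class, a, b in pairs:
                jset.add(
                    SpliceJunction(chrom, min(a, b), max(a, b), strand, event_class),
                    count=count,
                    tool="spladder",
                )
        except (ValueError, TypeError, KeyError, InvalidJunctionError) as exc:
            n_skipped += 1
            logger.warning("skipped malformed SplAdder row: %s", exc)
    if n_skipped:
        logger.warning("parse_spladder: skipped %d malformed rows", n_skipped)
    return jset


def union_replicates(sets: Iterable[JunctionSet]) -> JunctionSet:
    """Union junctions across replicates of one sample, summing counts."""
    sets = list(sets)
    if not sets:
        raise SpliceTargetError("union_replicates requires at least one set")
    sample_ids = {s.sample_id for s in sets}
    if len(sample_ids) > 1:
        raise SpliceTargetError(
            f"cannot union junction sets from different samples: {sorted(sample_ids)}"
        )
    out = JunctionSet(sample_id=sets[0].sample_id)
    for s in sets:
        for jid, junction in s.junctions.items():
            for tool in s.tools[jid]:
                out.add(junction, count=0, tool=tool)
            out.counts[jid] += s.counts[jid]
    return out


def build_canonical_db(
    transcripts: Iterable[TranscriptModel] | Mapping[str, TranscriptModel],
) -> JunctionDatabase:
    """All consecutive-exon junctions of all transcripts."""
    if isinstance(transcripts, Mapping):
        transcripts = transcripts.values()
    ids = set()
    for tx in transcripts:
        for i in range(len(tx.exons) - 1):
            start = tx.exons[i][1]
            end = tx.exons[i + 1][0]
            ids.add(SpliceJunction(tx.chrom, start, end, tx.strand).junction_id)
    return JunctionDatabase(label="canonical", junctions=frozenset(ids))


def filter_novel(
    junctions: JunctionSet,
    canonical_db: JunctionDatabase | None = None,
    normal_db: JunctionDatabase | None = None,
) -> FilterResult:
    """Remove junctions present in the canonical or normal databases.

    Returns the surviving set plus a map of removed junction ids to the
    label of the database that matched (canonical checked first).
    """
    kept = JunctionSet(sample_id=junctions.sample_id)
    removed: dict[str, str] = {}
    for jid, junction in junctions.junctions.items():
        hit = None
        for db in (canonical_db, normal_db):
            if db is not None and jid in db:
                hit = db.label
                break
        if hit is None:
            for tool in junctions.tools[jid]:
                kept.add(junction, count=0, tool=tool)
            kept.counts[jid] = junctions.counts[jid]
        else:
            removed[jid] = hit
    return FilterResult(kept=kept, removed=removed)
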