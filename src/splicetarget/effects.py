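"""Convert mutation splice-effect predictions into splice junctions.

Two predictor dialects are supported:

* SpliceAI-style VCF annotations: per variant, delta scores for acceptor
  gain/loss and donor gain/loss (``DS_*`` in [0, 1]) with genomic offsets
  (``DP_*``) locating the affected position relative to the variant.
* MMSplice-style per-exon tables: a ``delta_logit_psi`` score per
  (variant, transcript, exon); values <= 0 predict increased exon skipping
  and are turned into exon-skipping (ES) effects.

Each effect is resolved against every overlapping transcript to concrete
junctions:

====================  =====  ==========================================
effect                class  junction (transcript-oriented, normalised)
====================  =====  ==========================================
donor loss            IR     (pos, pos + strand_offset)
donor loss            ES     (upstream exon end, downstream exon start)
donor gain            A5SS   (pos, downstream exon start)
acceptor loss         IR     (pos - strand_offset, pos)
acceptor loss         ES     (upstream exon end, downstream exon start)
acceptor gain         A3SS   (upstream exon end, pos)
====================  =====  ==========================================

``strand_offset`` is +1 on the plus strand and -1 on the minus strand.
Loss effects must hit an annotated donor/acceptor base of the transcript
(exact match); IR junctions that do not straddle an exon-intron boundary
are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    ContractViolation,
    InvalidJunctionError,
    SpliceJunction,
    SpliceTargetError,
    TranscriptModel,
    is_exon_intron_boundary,
)

logger = logging.getLogger(__name__)

SPLICEAI_KINDS = ("acceptor_gain", "acceptor_loss", "donor_gain", "donor_loss")

# SpliceAI INFO annotation: ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL
_SPLICEAI_FIELDS = 10


class EffectParseError(SpliceTargetError):
    """Malformed predictor output."""


@dataclass(frozen=True)
class MutationEffect:
    """One predicted splicing change of one somatic variant."""

    variant_id: str
    effect_kind: str  # donor/acceptor x gain/loss, or exon_skip
    score: float
    affected_pos: int | None = None  # SpliceAI kinds: variant POS + DP offset
    gene_label: str | None = None
    chrom: str | None = None
    exon: tuple[int, int] | None = None  # exon_skip only
    transcript_id: str | None = None  # exon_skip: transcript of the exon

    def __post_init__(self) -> None:
        if self.effect_kind in SPLICEAI_KINDS:
            if not (0.0 <= self.score <= 1.0):
                raise EffectParseError(
                    f"SpliceAI delta score out of [0,1]: {self.score} "
                    f"({self.variant_id})"
                )
            if self.affected_pos is None:
                raise EffectParseError(f"missing affected_pos for {self.variant_id}")
        elif self.effect_kind == "exon_skip":
            if self.exon is None:
                raise EffectParseError(
                    f"exon_skip effect without exon interval ({self.variant_id})"
                )
        else:
            raise EffectParseError(f"unknown effect kind {self.effect_kind!r}")


@dataclass(frozen=True)
class EffectJunction:
    """A junction derived from one (mutation effect, transcript) pair."""

    junction: SpliceJunction
    transcript_id: str
    event_class: str
    score: float
    variant_id: str
    tool: str  # "spliceai" or "mmsplice"


def parse_spliceai_record(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    info_value: str,
    min_emit_score: float = 0.0,
) -> list[MutationEffect]:
    """Parse one SpliceAI INFO value (possibly comma-separated) into effects.

    Effects with score strictly greater than ``min_emit_score`` are emitted;
    the default suppresses zero-score entries, which encode "no predicted
    change".  Set ``min_emit_score`` to a negative value to emit everything.
    """
    effects = []
    variant_id = f"{chrom}:{pos}:{ref}>{alt}"
    for ann in str(info_value).split(","):
        fields = ann.split("|")
        if len(fields) != _SPLICEAI_FIELDS:
            raise EffectParseError(
                f"malformed SpliceAI annotation at {chrom}:{pos} "
                f"({len(fields)} fields, expected {_SPLICEAI_FIELDS}): {ann!r}"
            )
        symbol = fields[1]
        for kind, ds_raw, dp_raw in zip(
            SPLICEAI_KINDS, fields[2:6], fields[6:10]
        ):
            if ds_raw in ("", "."):
                continue
            try:
                score = float(ds_raw)
                offset = int(dp_raw)
            except ValueError as exc:
                raise EffectParseError(
                    f"malformed SpliceAI score/offset at {chrom}:{pos}: "
                    f"{ds_raw!r}/{dp_raw!r}"
                ) from exc
            if score > min_emit_score:
                effects.append(
                    MutationEffect(
                        variant_id=variant_id,
                        effect_kind=kind,
                        score=score,
                        affected_pos=pos + offset,
                        gene_label=symbol,
                        chrom=chrom,
                    )
                )
    return effects


def parse_spliceai_vcf(vcf_path: str, min_emit_score: float = 0.0) -> list[MutationEffect]:
    """Read a VCF annotated with the SpliceAI INFO field.

    Records lacking the ``SpliceAI`` INFO key are skipped with a warning;
    malformed annotations raise :class:`EffectParseError` naming the record.
    """
    import pysam

    effects: list[MutationEffect] = []
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            if "SpliceAI" not in rec.info:
                logger.warning(
                    "record %s:%s lacks SpliceAI INFO field; skipped",
                    rec.chrom,
                    rec.pos,
                )
                continue
            raw = rec.info["SpliceAI"]
            if isinstance(raw, (tuple, list)):
                raw = ",".join(str(x) for x in raw)
            for alt in rec.alts or ("N",):
                effects.extend(
                    parse_spliceai_record(
                        rec.chrom, rec.pos, rec.ref, alt, raw, min_emit_score
                    )
                )
                break  # annotations list all alleles already
    return effects


def parse_mmsplice(table: str | pd.DataFrame) -> list[MutationEffect]:
    """Parse an MMSplice-style per-exon effect table.

    Requires columns ``variant``, ``transcript_id``, ``exon_start``,
    ``exon_end`` and ``delta_logit_psi``.  Rows with ``delta_logit_psi <= 0``
    become exon-skip effects scored by ``delta_logit_psi``; positive rows
    (predicted increased inclusion) are dropped.
    """
    if isinstance(table, (str, bytes)):
        table = pd.read_csv(table, sep="\t")
    required = ["variant", "transcript_id", "exon_start", "exon_end", "delta_logit_psi"]
    for col in required:
        if col not in table.columns:
            raise EffectParseError(f"MMSplice table missing column {col!r}")
    effects = []
    for row in table.itertuples(index=False):
        if row.delta_logit_psi > 0:
            continue
        effects.append(
            MutationEffect(
                variant_id=str(row.variant),
                effect_kind="exon_skip",
                score=float(row.delta_logit_psi),
                exon=(int(row.exon_start), int(row.exon_end)),
                transcript_id=str(row.transcript_id),
            )
        )
    return effects


# ---------------------------------------------------------------------------
# effect -> junction rules
# ---------------------------------------------------------------------------


def _skip_junction(
    tx: TranscriptModel, k: int
) -> tuple[int, int] | None:
    """ES junction coordinates for skipping exon ``k`` (transcript order)."""
    exons = tx.exons_tx_order
    if k <= 0 or k >= len(exons) - 1:
        return None
    upstream_end = tx.donor_site(exons[k - 1])
    downstream_start = tx.acceptor_site(exons[k + 1])
    return upstream_end, downstream_start


def _next_acceptor_after(tx: TranscriptModel, pos: int) -> int | None:
    """Acceptor base of the next exon strictly downstream of ``pos``."""
    if tx.strand == "+":
        starts = [lo for lo, hi in tx.exons if lo > pos]
        return min(starts) if starts else None
    ends = [hi for lo, hi in tx.exons if hi < pos]
    return max(ends) if ends else None


def _prev_donor_before(tx: TranscriptModel, pos: int) -> int | None:
    """Donor base of the nearest exon strictly upstream of ``pos``."""
    if tx.strand == "+":
        ends = [hi for lo, hi in tx.exons if hi < pos]
        return max(ends) if ends else None
    starts = [lo for lo, hi in tx.exons if lo > pos]
    return min(starts) if starts else None


def effects_to_junctions(
    effect: MutationEffect,
    transcripts: Iterable[TranscriptModel] | Mapping[str, TranscriptModel],
    restrict_to_gene: bool = False,
) -> list[EffectJunction]:
    """Apply the donor/acceptor gain/loss rules per overlapping transcript.

    For loss effects, the affected position must coincide exactly with an
    annotated donor/acceptor boundary base of the transcript, otherwise the
    transcript is skipped.  IR junctions that do not straddle an exon-intron
    boundary are dropped.  With ``restrict_to_gene``, only transcripts whose
    gene matches the predictor's gene label are considered.
    """
    if effect.effect_kind == "exon_skip":
        raise ContractViolation(
            "exon_skip effects are handled by mmsplice_to_junctions"
        )
    if isinstance(transcripts, Mapping):
        transcripts = transcripts.values()
    pos = effect.affected_pos
    assert pos is not None
    offset_by_strand = {"+": 1, "-": -1}
    out: list[EffectJunction] = []
    for tx in transcripts:
        if effect.chrom is not None and tx.chrom != effect.chrom:
            continue
        lo, hi = tx.span()
        if not (lo <= pos <= hi):
            continue
        if restrict_to_gene and effect.gene_label is not None:
            if tx.gene_id != effect.gene_label:
                continue
        strand_offset = offset_by_strand[tx.strand]
        pairs: list[tuple[str, tuple[int, int]]] = []
        if effect.effect_kind in ("donor_loss", "acceptor_loss"):
            exons = tx.exons_tx_order
            site = (
                tx.donor_site if effect.effect_kind == "donor_loss" else tx.acceptor_site
            )
            matches = [k for k, exon in enumerate(exons) if site(exon) == pos]
            if not matches:
                logger.debug(
                    "%s at %s:%d matches no annotated site of %s; skipped",
                    effect.effect_kind,
                    tx.chrom,
                    pos,
                    tx.transcript_id,
                )
                continue
            k = matches[0]
            if effect.effect_kind == "donor_loss":
                pairs.append(("IR", (pos, pos + strand_offset)))
            else:
                pairs.append(("IR", (pos - strand_offset, pos)))
            skip = _skip_junction(tx, k)
            if skip is not None:
                pairs.append(("ES", skip))
        elif effect.effect_kind == "donor_gain":
            downstream_start = _next_acceptor_after(tx, pos)
            if downstream_start is not None:
                pairs.append(("A5SS", (pos, downstream_start)))
        elif effect.effect_kind == "acceptor_gain":
            upstream_end = _prev_donor_before(tx, pos)
            if upstream_end is not None:
                pairs.append(("A3SS", (upstream_end, pos)))
        for event_class, (a, b) in pairs:
            try:
                junction = SpliceJunction(
                    tx.chrom, min(a, b), max(a, b), tx.strand, event_class
                )
            except InvalidJunctionError:
                continue
            if event_class == "IR" and not is_exon_intron_boundary(junction, tx):
                continue
            out.append(
                EffectJunction(
                    junction=junction,
                    transcript_id=tx.transcript_id,
                    event_class=event_class,
                    score=effect.score,
                    variant_id=effect.variant_id,
                    tool="spliceai",
                )
            )
    return out


def mmsplice_to_junctions(
    effect: MutationEffect,
    transcripts: Mapping[str, TranscriptModel],
) -> list[EffectJunction]:
    """Build the ES junction skipping the affected exon of an exon-skip effect.

    The junction joins the end of the upstream exon to the start of the
    downstream exon (transcript orientation).  First/last exons have no
    skip partner and yield nothing.
    """
    if effect.effect_kind != "exon_skip":
        raise ContractViolation("mmsplice_to_junctions handles exon_skip effects only")
    assert effect.exon is not None
    if effect.transcript_id is not None:
        if effect.transcript_id not in transcripts:
            logger.warning(
                "transcript %s not in annotation; effect %s skipped",
                effect.transcript_id,
                effect.variant_id,
            )
            return []
        candidates = [transcripts[effect.transcript_id]]
    else:
        candidates = [tx for tx in transcripts.values() if effect.exon in tx.exons]
    out = []
    exon = tuple(effect.exon)
    for tx in candidates:
        exons = tx.exons_tx_order
        if exon not in exons:
            logger.warning(
                "exon %s-%s not annotated in %s; effect %s skipped",
                exon[0],
                exon[1],
                tx.transcript_id,
                effect.variant_id,
            )
            continue
        k = exons.index(exon)
        skip = _skip_junction(tx, k)
        if skip is None:
            logger.info(
                "exon %s-%s is terminal in %s; no skip junction",
                exon[0],
                exon[1],
                tx.transcript_id,
            )
            continue
        a, b = skip
        out.append(
            EffectJunction(
                junction=SpliceJunction(tx.chrom, min(a, b), max(a, b), tx.strand, "ES"),
                transcript_id=tx.transcript_id,
                event_class="ES",
                score=effect.score,
                variant_id=effect.variant_id,
                tool="mmsplice",
            )
        )
    return out


def collapse_junctions(records: Iterable[EffectJunction]) -> pd.DataFrame:
    """Deduplicate effect junctions per (junction, tool).

    Keeps the score with maximum absolute value and lists all supporting
    transcript and variant ids.  Returns a table with columns
    ``junction_id, event_class, tool, score, transcript_ids, variant_ids``.
    """
    groups: dict[tuple[str, str], list[EffectJunction]] = {}
    for rec in records:
        groups.setdefault((rec.junction.junction_id, rec.tool), []).append(rec)
    rows = []
    for (junction_id, tool), recs in sorted(groups.items()):
        best = max(recs, key=lambda r: abs(r.score))
        rows.append(
            {
                "junction_id": junction_id,
                "event_class": best.event_class,
                "tool": tool,
                "score": best.score,
                "transcript_ids": ",".join(sorted({r.transcript_id for r in recs})),
                "variant_ids": ",".join(sorted({r.variant_id for r in recs})),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "junction_id",
            "event_class",
            "tool",
            "score",
            "transcript_ids",
            "variant_ids",
        ],
    )
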