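"""Transcript context sequences, CDS modification and peptide extraction.

For every (junction, transcript) pair the modified transcript is modelled
as a chain of genomic intervals: the wild-type exon chain truncated at the
junction's left anchor, joined to the chain truncated at the right anchor.
A junction anchor inside an intron extends the neighbouring exon, so
retained intronic sequence created by alternative splice sites is included
naturally.

The context sequence (``cts_seq``) is the transcript-oriented nucleotide
sequence around the breakpoint (default 200 exonic bases per side,
truncated at transcript ends); for intron retention it spans the complete
intron plus flanks.  Each context gets a deterministic 128-bit xxHash id
(``cts_id``) over ``"<cts_seq>|<position descriptor>"``.

CDS modification splices the coding sequence through the same modified
chain; a frameshift is flagged when wild-type and modified CDS lengths
differ by a non-multiple of three.  Peptide contexts carry the junction
residues flanked by wild-type residues (default 13 per side); frameshift
peptides run to the next stop codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import (
    ContractViolation,
    SpliceJunction,
    SpliceTargetError,
    TranscriptModel,
)
from .xxh3 import xxh3_128_hexdigest

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _fetch(genome, chrom: str, lo: int, hi: int) -> str:
    """1-based inclusive genomic substring from a FASTA handle or dict."""
    if hi < lo:
        return ""
    return str(genome[chrom][lo - 1 : hi]).upper()


@dataclass(frozen=True)
class ContextSequence:
    """Transcript context of one junction, used as requantification reference."""

    junction_id: str
    transcript_id: str
    event_class: str
    cts_seq: str
    cts_junc_pos: int | None  # bases preceding the breakpoint (non-IR)
    intron_interval: tuple[int, int] | None  # 1-based positions in cts_seq (IR)
    cts_id: str

    def __post_init__(self) -> None:
        if (self.intron_interval is not None) != (self.event_class == "IR"):
            raise SpliceTargetError(
                "intron_interval must be present exactly for IR contexts"
            )


@dataclass(frozen=True)
class PeptideContext:
    """Peptide neighbourhood of a junction in the mutated protein."""

    mutated_peptide: str
    wildtype_peptide: str | None
    frameshift: bool
    junction_aa_pos: int  # last wild-type residue left of the event
    reading_frame_offset: int  # 0: between codons; 1/2: chimeric junction codon
    no_stop_flag: bool = False


@dataclass(frozen=True)
class CdsModification:
    """Outcome of splicing a wild-type CDS through a junction."""

    modified_cds_seq: str
    wildtype_cds_seq: str
    frameshift: bool
    junc_pos_in_cds: int  # modified-CDS bases preceding the breakpoint


def context_id(cts_seq: str, position_descriptor: str) -> str:
    """Deterministic 128-bit hash id over sequence and position."""
    if not cts_seq:
        raise SpliceTargetError("context_id requires a non-empty sequence")
    return xxh3_128_hexdigest(f"{cts_seq}|{position_descriptor}")


# ---------------------------------------------------------------------------
# modified transcript chains
# ---------------------------------------------------------------------------


def _left_chain(exons, pos: int) -> list[list[int]]:
    """Transcript-structure bases genomically <= pos (intron anchors extend)."""
    out: list[list[int]] = []
    for lo, hi in exons:
        if hi < pos:
            out.append([lo, hi])
        elif lo <= pos <= hi:
            out.append([lo, pos])
            return out
        else:
            break
    if out and out[-1][1] < pos:
        out[-1][1] = pos  # pos is intronic: retain intron bases up to pos
    return out


def _right_chain(exons, pos: int) -> list[list[int]]:
    out: list[list[int]] = []
    for lo, hi in reversed(exons):
        if lo > pos:
            out.insert(0, [lo, hi])
        elif lo <= pos <= hi:
            out.insert(0, [pos, hi])
            return out
        else:
            break
    if out and out[0][0] > pos:
        out[0][0] = pos
    return out


def _chain_seq(genome, chrom: str, chain) -> str:
    return "".join(_fetch(genome, chrom, lo, hi) for lo, hi in chain)


def _chain_len(chain) -> int:
    return sum(hi - lo + 1 for lo, hi in chain)


def _modified_chain(
    tx: TranscriptModel, junction: SpliceJunction
) -> tuple[list[list[int]], int]:
    """Modified exon chain and genomic-orientation breakpoint offset.

    The breakpoint lies after ``offset`` chain bases counted from the
    genomic left end of the chain.
    """
    left = _left_chain(tx.exons, junction.start)
    right = _right_chain(tx.exons, junction.end)
    if not left or not right:
        raise SpliceTargetError(
            f"junction {junction.junction_id} has an anchor outside transcript "
            f"{tx.transcript_id}"
        )
    return left + right, _chain_len(left)


def _ir_chain(
    tx: TranscriptModel, junction: SpliceJunction
) -> tuple[list[list[int]], tuple[int, int]]:
    """Exon chain with the retained intron merged in; returns (chain, intron)."""
    intronic = junction.end if tx.is_exonic(junction.start) else junction.start
    for ilo, ihi in tx.introns():
        if ilo <= intronic <= ihi:
            chain = []
            for lo, hi in tx.exons:
                if chain and chain[-1][1] == ilo - 1 and lo == ihi + 1:
                    chain[-1][1] = hi  # merge across the retained intron
                else:
                    chain.append([lo, hi])
            return chain, (ilo, ihi)
    raise SpliceTargetError(
        f"IR junction {junction.junction_id} does not hit an intron of "
        f"{tx.transcript_id}"
    )


def add_context_seq(
    junction: SpliceJunction,
    transcript: TranscriptModel,
    genome,
    flank: int = 200,
) -> ContextSequence:
    """Build the transcript context sequence of a junction.

    ES/A3SS/A5SS: up to ``flank`` exonic bases on each side of the
    breakpoint in the modified transcript, truncated at transcript ends.
    IR: the complete intron plus up to ``flank`` exonic bases per side;
    ``intron_interval`` locates the intron within ``cts_seq``.
    Sequences read 5'->3' of the transcript (reverse-complemented on the
    minus strand).
    """
    tx = transcript
    if junction.chrom != tx.chrom:
        raise SpliceTargetError(
            f"junction {junction.junction_id} on different chromosome than "
            f"{tx.transcript_id}"
        )
    if junction.event_class == "IR" or (
        junction.event_class == "unknown" and junction.is_ir_shaped
    ):
        _, (ilo, ihi) = _ir_chain(tx, junction)
        # flanks come from the intron's adjacent exons only: the context
        # represents locally unspliced pre-mRNA, so it stays contiguous
        # on the genome
        exon_before = next(e for e in tx.exons if e[1] == ilo - 1)
        exon_after = next(e for e in tx.exons if e[0] == ihi + 1)
        up_take = min(flank, exon_before[1] - exon_before[0] + 1)
        down_take = min(flank, exon_after[1] - exon_after[0] + 1)
        intron_len = ihi - ilo + 1
        window = _fetch(genome, tx.chrom, ilo - up_take, ihi + down_take)
        if tx.strand == "+":
            lo_pos = up_take + 1
        else:
            window = reverse_complement(window)
            lo_pos = down_take + 1
        interval = (lo_pos, lo_pos + intron_len - 1)
        descriptor = f"intron:{interval[0]}-{interval[1]}"
        return ContextSequence(
            junction_id=junction.junction_id,
            transcript_id=tx.transcript_id,
            event_class="IR",
            cts_seq=window,
            cts_junc_pos=None,
            intron_interval=interval,
            cts_id=context_id(window, descriptor),
        )

    chain, break_at = _modified_chain(tx, junction)
    seq = _chain_seq(genome, tx.chrom, chain)
    total = len(seq)
    if tx.strand == "+":
        up_take = min(flank, break_at)
        down_take = min(flank, total - break_at)
        window = seq[break_at - up_take : break_at + down_take]
        junc_pos = up_take
    else:
        up_take = min(flank, total - break_at)  # transcript-upstream
        down_take = min(flank, break_at)
        window = reverse_complement(seq[break_at - down_take : break_at + up_take])
        junc_pos = up_take
    if junc_pos <= 0 or junc_pos >= len(window):
        raise SpliceTargetError(
            f"degenerate context for {junction.junction_id} on {tx.transcript_id}"
        )
    return ContextSequence(
        junction_id=junction.junction_id,
        transcript_id=tx.transcript_id,
        event_class=junction.event_class,
        cts_seq=window,
        cts_junc_pos=junc_pos,
        intron_interval=None,
        cts_id=context_id(window, f"junc:{junc_pos}"),
    )


# ---------------------------------------------------------------------------
# CDS modification and translation
# ---------------------------------------------------------------------------


def _chain_pos(chain, strand: str, g: int) -> int | None:
    """Transcript-oriented 1-based position of genomic base ``g`` in chain."""
    offset = 0
    total = _chain_len(chain)
    for lo, hi in chain:
        if lo <= g <= hi:
            genomic_pos = offset + (g - lo) + 1
            return genomic_pos if strand == "+" else total - genomic_pos + 1
        offset += hi - lo + 1
    return None


def modify_cds(
    junction: SpliceJunction,
    transcript: TranscriptModel,
    genome,
) -> CdsModification | None:
    """Splice the wild-type CDS through the junction.

    Returns ``None`` when the transcript has no CDS, the junction leaves the
    coding sequence unchanged (e.g. UTR-only events), or the start codon is
    removed.  IR junctions are not translated (their peptide products are
    excluded downstream) and also return ``None``.

    On a frameshift, the returned modified CDS extends to the 3' end of the
    modified transcript so translation can run to the true stop codon.
    """
    tx = transcript
    if not tx.cds:
        return None
    if junction.event_class == "IR" or junction.is_ir_shaped:
        logger.debug("IR junction %s not translated", junction.junction_id)
        return None
    wt_cds_seq = _chain_seq(genome, tx.chrom, tx.cds)
    if tx.strand == "-":
        wt_cds_seq = reverse_complement(wt_cds_seq)
    g_start = tx.cds[0][0] if tx.strand == "+" else tx.cds[-1][1]
    g_end = tx.cds[-1][1] if tx.strand == "+" else tx.cds[0][0]
    chain, break_at = _modified_chain(tx, junction)
    seq = _chain_seq(genome, tx.chrom, chain)
    if tx.strand == "-":
        seq = reverse_complement(seq)
    total = len(seq)
    b_tx = break_at if tx.strand == "+" else total - break_at
    pos_start = _chain_pos(chain, tx.strand, g_start)
    if pos_start is None:
        logger.info(
            "junction %s removes the start codon of %s",
            junction.junction_id,
            tx.transcript_id,
        )
        return None
    pos_end = _chain_pos(chain, tx.strand, g_end)
    if pos_end is not None and pos_end >= pos_start:
        core = seq[pos_start - 1 : pos_end]
    else:
        core = seq[pos_start - 1 :]
    if core == wt_cds_seq:
        return None  # junction does not affect the CDS
    frameshift = (len(core) - len(wt_cds_seq)) % 3 != 0
    junc_pos_in_cds = b_tx - (pos_start - 1)
    modified = seq[pos_start - 1 :] if frameshift or pos_end is None else core
    return CdsModification(
        modified_cds_seq=modified,
        wildtype_cds_seq=wt_cds_seq,
        frameshift=frameshift,
        junc_pos_in_cds=junc_pos_in_cds,
    )


def translate_cds(seq: str) -> tuple[str, bool]:
    """Standard-code translation up to (excluding) the first stop codon.

    Returns ``(protein, no_stop)``; ``no_stop`` is True when no stop codon
    was encountered.  Non-ACGT characters raise an error.
    """
    if len(seq) < 3:
        raise SpliceTargetError(f"sequence too short to translate ({len(seq)} nt)")
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise SpliceTargetError(f"non-ACGT characters in CDS: {sorted(bad)}")
    table = _codon_table()
    protein = []
    for i in range(0, len(seq) - 2, 3):
        aa = table[seq[i : i + 3]]
        if aa == "*":
            return "".join(protein), False
        protein.append(aa)
    return "".join(protein), True  # fell off the end without a stop


def extract_peptide_context(
    wt_protein: str,
    mut_protein: str,
    junc_pos_in_cds: int,
    frameshift: bool,
    flank: int = 13,
    no_stop: bool = False,
) -> PeptideContext | None:
    """Extract the peptide neighbourhood of the junction.

    ``junction_aa_pos`` (the last wild-type residue left of the event) is
    ``(junc_pos_in_cds - 1) // 3 + 1``; the reading-frame offset
    ``junc_pos_in_cds mod 3`` tells whether the junction codon is chimeric.
    In-frame events keep the junction residues plus up to ``flank``
    wild-type residues per side; frameshift peptides keep the upstream
    wild-type flank and the entire novel C-terminus.  Returns ``None`` when
    the mutated protein is just a (possibly truncated) copy of the
    wild type.
    """
    if mut_protein == wt_protein or wt_protein.startswith(mut_protein):
        return None
    junction_aa_pos = (junc_pos_in_cds - 1) // 3 + 1
    frame_offset = junc_pos_in_cds % 3
    if junction_aa_pos < 1 or junction_aa_pos > len(mut_protein) + 1:
        raise ContractViolation(
            f"junction position {junction_aa_pos} outside mutated protein "
            f"(length {len(mut_protein)})"
        )
    left_lo = max(1, junction_aa_pos - flank + 1)
    if frameshift:
        mutated = mut_protein[left_lo - 1 :]
    else:
        inserted = max(0, len(mut_protein) - len(wt_protein))
        novel = inserted + (1 if frame_offset else 0)
        right_hi = min(len(mut_protein), junction_aa_pos + novel + flank)
        mutated = mut_protein[left_lo - 1 : right_hi]
    wt_hi = min(len(wt_protein), junction_aa_pos + flank)
    wildtype = wt_protein[left_lo - 1 : wt_hi] or None
    return PeptideContext(
        mutated_peptide=mutated,
        wildtype_peptide=wildtype,
        frameshift=frameshift,
        junction_aa_pos=junction_aa_pos,
        reading_frame_offset=frame_offset,
        no_stop_flag=no_stop,
    )


def annotate_peptide(
    junction: SpliceJunction,
    transcript: TranscriptModel,
    genome,
    flank: int = 13,
) -> PeptideContext | None:
    """Full junction -> peptide pipeline for one transcript."""
    mod = modify_cds(junction, transcript, genome)
    if mod is None:
        return None
    wt_protein, _ = translate_cds(mod.wildtype_cds_seq)
    mut_protein, had_stop_info = translate_cds(mod.modified_cds_seq)
    return extract_peptide_context(
        wt_protein,
        mut_protein,
        mod.junc_pos_in_cds,
        mod.frameshift,
        flank=flank,
        no_stop=had_stop_info,
    )
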