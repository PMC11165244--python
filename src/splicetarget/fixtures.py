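"""Synthetic reference, mutation-effect and RNA-seq fixtures.

Generates every input the pipeline consumes — toy genome FASTA, transcript
GTF, SpliceAI-annotated VCFs, MMSplice tables, junction-caller tables,
FASTQ reads and a multi-sample cohort manifest — with planted ground truth,
so the full workflow can be exercised end to end without downloads.

The generator is deterministic per seed.  Splice-site dinucleotides (GT/AG)
are planted at intron boundaries so sequences look splice-plausible, coding
sequences are built from stop-free codons with a terminal stop, and the
rest of the genome is uniform random.

Cohort design: *true* junctions are caused by a planted somatic variant and
receive RNA-seq support only in their carrier sample, with strong effect
scores; *decoy* junctions carry weak effect scores and additionally appear
in the junction-caller output of other samples of the same study group, so
the permutation analysis should label exactly the decoys as false
positives.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .annotate import ContextSequence, add_context_seq
from .core import SpliceJunction, SpliceTargetError, TranscriptModel
from .effects import EffectJunction
from .requant import Read

_BASES = "ACGT"
# codons that cannot terminate translation, used to build clean ORFs
_SAFE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# default cohort conditions: strong planted effects are well separated from
# weak decoys so the detection-rule search has a recoverable optimum
TRUE_SCORE_RANGE = (0.5, 1.0)
DECOY_SCORE_RANGE = (0.01, 0.1)


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions of a simulated cohort."""

    seed: int = 0
    n_samples: int = 6
    n_true_junctions: int = 8
    n_decoy_junctions: int = 8
    read_length: int = 50
    depth: int = 5
    event_mix: tuple[tuple[str, float], ...] = (
        ("ES", 0.4),
        ("A3SS", 0.2),
        ("A5SS", 0.2),
        ("IR", 0.2),
    )
    n_groups: int = 2

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise SpliceTargetError(
                "a cohort needs >= 2 samples for the permutation analysis"
            )


@dataclass
class ToyReference:
    """In-memory toy genome and annotation."""

    genome: dict[str, str]
    transcripts: dict[str, TranscriptModel]

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def write_gtf(self, path: str) -> None:
        lines = []
        for tid in sorted(self.transcripts):
            tx = self.transcripts[tid]
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            lo, hi = tx.span()
            lines.append(
                f"{tx.chrom}\ttoy\ttranscript\t{lo}\t{hi}\t.\t{tx.strand}\t.\t{attrs}"
            )
            for elo, ehi in tx.exons:
                lines.append(
                    f"{tx.chrom}\ttoy\texon\t{elo}\t{ehi}\t.\t{tx.strand}\t.\t{attrs}"
                )
            for clo, chi in tx.cds:
                lines.append(
                    f"{tx.chrom}\ttoy\tCDS\t{clo}\t{chi}\t.\t{tx.strand}\t0\t{attrs}"
                )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, size=n)]


def _plant_cds(
    genome: list[str],
    rng: np.random.Generator,
    cds: tuple[tuple[int, int], ...],
    strand: str,
) -> None:
    """Write a stop-free ORF (ATG ... stop) along the CDS intervals."""
    total = sum(hi - lo + 1 for lo, hi in cds)
    assert total % 3 == 0
    n_codons = total // 3
    codons = ["ATG"] + [
        _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), size=n_codons - 2)
    ] + ["TAA"]
    seq = "".join(codons)
    if strand == "-":
        seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    i = 0
    for lo, hi in cds:
        for pos in range(lo, hi + 1):
            genome[pos - 1] = seq[i]
            i += 1


def _plant_splice_sites(genome: list[str], tx: TranscriptModel) -> None:
    for ilo, ihi in tx.introns():
        if tx.strand == "+":
            genome[ilo - 1], genome[ilo] = "G", "T"
            genome[ihi - 2], genome[ihi - 1] = "A", "G"
        else:
            genome[ilo - 1], genome[ilo] = "C", "T"
            genome[ihi - 2], genome[ihi - 1] = "A", "C"


def make_toy_reference(seed: int = 0, out_dir: str | None = None) -> ToyReference:
    """Toy genome with three multi-exon transcripts on both strands.

    TX1 (chrT, +) carries the canonical fixture structure: exons 101-200,
    301-400 and 501-600 with a CDS; TX2 is its minus-strand twin on chrTn;
    TX3 is a four-exon plus-strand transcript on chrT2.  Writes FASTA and
    GTF when ``out_dir`` is given.
    """
    rng = np.random.default_rng(seed)
    transcripts = {
        "TX1": TranscriptModel(
            "TX1", "GENE1", "chrT", "+",
            exons=((101, 200), (301, 400), (501, 600)),
            cds=((132, 200), (301, 400), (501, 562)),
        ),
        "TX2": TranscriptModel(
            "TX2", "GENE2", "chrTn", "-",
            exons=((101, 200), (301, 400), (501, 600)),
            cds=((139, 200), (301, 400), (501, 569)),
        ),
        "TX3": TranscriptModel(
            "TX3", "GENE3", "chrT2", "+",
            exons=((151, 250), (351, 450), (551, 650), (751, 850)),
            cds=((181, 250), (351, 450), (551, 650), (751, 789)),
        ),
    }
    lengths = {"chrT": 800, "chrTn": 800, "chrT2": 1000}
    genome = {}
    for chrom, n in lengths.items():
        seq = _random_seq(rng, n)
        for tx in transcripts.values():
            if tx.chrom != chrom:
                continue
            if tx.cds:
                _plant_cds(seq, rng, tx.cds, tx.strand)
            _plant_splice_sites(seq, tx)
        genome[chrom] = "".join(seq)
    ref = ToyReference(genome=genome, transcripts=transcripts)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        ref.write_fasta(os.path.join(out_dir, "genome.fa"))
        ref.write_gtf(os.path.join(out_dir, "annotation.gtf"))
    return ref


# ---------------------------------------------------------------------------
# planted mutation effects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlannedEvent:
    """One splice event to plant, with its causative variant."""

    kind: str  # A3SS | A5SS | ES | IR
    transcript_id: str
    chrom: str
    variant_pos: int
    ref: str
    alt: str
    score: float
    junction: SpliceJunction  # the junction the converters must reproduce
    affected_pos: int | None = None  # SpliceAI kinds
    spliceai_channel: str | None = None  # AG | AL | DG | DL
    exon: tuple[int, int] | None = None  # ES via MMSplice

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.variant_pos}:{self.ref}>{self.alt}"


def _event_pool(reference: ToyReference) -> list[dict]:
    """Enumerate distinct plantable events across the toy transcripts."""
    pool = []
    for tx in reference.transcripts.values():
        exons = tx.exons_tx_order
        # exon skipping via per-exon effect (internal exons only)
        for k in range(1, len(exons) - 1):
            up_end = tx.donor_site(exons[k - 1])
            down_start = tx.acceptor_site(exons[k + 1])
            pool.append(
                {
                    "kind": "ES",
                    "tx": tx,
                    "exon": tuple(sorted(exons[k])),
                    "junction": SpliceJunction(
                        tx.chrom, min(up_end, down_start), max(up_end, down_start),
                        tx.strand, "ES",
                    ),
                }
            )
        # alternative splice sites: new site shifted into the exon
        sign = 1 if tx.strand == "+" else -1
        for k in range(len(exons) - 1):
            up_end = tx.donor_site(exons[k])
            down_start = tx.acceptor_site(exons[k + 1])
            for delta in (4, 9, 14, 19):
                a3_pos = down_start + sign * delta  # acceptor moves into exon
                pool.append(
                    {
                        "kind": "A3SS",
                        "tx": tx,
                        "affected_pos": a3_pos,
                        "channel": "AG",
                        "junction": SpliceJunction(
                            tx.chrom, min(up_end, a3_pos), max(up_end, a3_pos),
                            tx.strand, "A3SS",
                        ),
                    }
                )
                a5_pos = up_end - sign * delta  # donor moves into exon
                pool.append(
                    {
                        "kind": "A5SS",
                        "tx": tx,
                        "affected_pos": a5_pos,
                        "channel": "DG",
                        "junction": SpliceJunction(
                            tx.chrom, min(a5_pos, down_start), max(a5_pos, down_start),
                            tx.strand, "A5SS",
                        ),
                    }
                )
        # intron retention: loss of the first exon's donor (no skip partner)
        donor = tx.donor_site(exons[0])
        start, end = sorted((donor, donor + sign))
        pool.append(
            {
                "kind": "IR",
                "tx": tx,
                "affected_pos": donor,
                "channel": "DL",
                "junction": SpliceJunction(tx.chrom, start, end, tx.strand, "IR"),
            }
        )
    return pool


def _draw_events(
    reference: ToyReference,
    rng: np.random.Generator,
    n: int,
    event_mix: Mapping[str, float],
    score_range: tuple[float, float],
    exclude: set[str],
) -> list[PlannedEvent]:
    pool = [e for e in _event_pool(reference) if e["junction"].junction_id not in exclude]
    by_kind: dict[str, list[dict]] = {}
    for e in pool:
        by_kind.setdefault(e["kind"], []).append(e)
    kinds = [k for k, _ in event_mix]
    weights = np.array([w for _, w in event_mix], dtype=float)
    weights /= weights.sum()
    events = []
    used_variant_pos: set[tuple[str, int]] = set()
    for _ in range(n):
        for kind in rng.choice(kinds, size=len(kinds), replace=False, p=weights):
            if by_kind.get(kind):
                break
        else:
            raise SpliceTargetError("event pool exhausted; reduce n_true/n_decoy")
        choice = by_kind[kind].pop(int(rng.integers(len(by_kind[kind]))))
        tx = choice["tx"]
        score = float(rng.uniform(*score_range))
        for _attempt in range(50):
            if choice["kind"] == "ES":
                # variant near the skipped exon's acceptor
                variant_pos = int(min(choice["exon"]) + rng.integers(0, 3))
            else:
                offset = int(rng.integers(-8, 9))
                variant_pos = choice["affected_pos"] - offset
            if (tx.chrom, variant_pos) not in used_variant_pos:
                break
        used_variant_pos.add((tx.chrom, variant_pos))
        ref_base = reference.genome[tx.chrom][variant_pos - 1]
        alt_base = _BASES[(_BASES.index(ref_base) + 1) % 4]
        events.append(
            PlannedEvent(
                kind=choice["kind"],
                transcript_id=tx.transcript_id,
                chrom=tx.chrom,
                variant_pos=variant_pos,
                ref=ref_base,
                alt=alt_base,
                score=round(score, 2),
                junction=choice["junction"],
                affected_pos=choice.get("affected_pos"),
                spliceai_channel=choice.get("channel"),
                exon=choice.get("exon"),
            )
        )
        exclude.add(choice["junction"].junction_id)
    return events


def write_vcf(events: list[PlannedEvent], reference: ToyReference, path: str) -> None:
    """Write events (SpliceAI channels) as an annotated VCF."""
    header = ["##fileformat=VCFv4.2"]
    for chrom in sorted(reference.genome):
        header.append(f"##contig=<ID={chrom},length={len(reference.genome[chrom])}>")
    header.append(
        '##INFO=<ID=SpliceAI,Number=.,Type=String,Description="SpliceAIv1.3 '
        "variant annotation. Format: "
        'ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL">'
    )
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    records = []
    for ev in sorted(events, key=lambda e: (e.chrom, e.variant_pos)):
        if ev.spliceai_channel is None:
            continue
        ds = {"AG": "0.00", "AL": "0.00", "DG": "0.00", "DL": "0.00"}
        dp = {"AG": "0", "AL": "0", "DG": "0", "DL": "0"}
        ds[ev.spliceai_channel] = f"{ev.score:.2f}"
        dp[ev.spliceai_channel] = str(ev.affected_pos - ev.variant_pos)
        tx = None
        for cand in reference.transcripts.values():
            if cand.transcript_id == ev.transcript_id:
                tx = cand
        gene = tx.gene_id if tx is not None else "."
        info = (
            f"SpliceAI={ev.alt}|{gene}|{ds['AG']}|{ds['AL']}|{ds['DG']}|{ds['DL']}"
            f"|{dp['AG']}|{dp['AL']}|{dp['DG']}|{dp['DL']}"
        )
        records.append(
            f"{ev.chrom}\t{ev.variant_pos}\t.\t{ev.ref}\t{ev.alt}\t.\tPASS\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(header + records) + "\n")


def write_mmsplice(events: list[PlannedEvent], path: str) -> None:
    """Write ES events as an MMSplice-style per-exon table."""
    rows = [
        {
            "variant": ev.variant_id,
            "transcript_id": ev.transcript_id,
            "exon_start": ev.exon[0],
            "exon_end": ev.exon[1],
            "delta_logit_psi": -ev.score,
        }
        for ev in events
        if ev.kind == "ES"
    ]
    pd.DataFrame(
        rows,
        columns=["variant", "transcript_id", "exon_start", "exon_end", "delta_logit_psi"],
    ).to_csv(path, sep="\t", index=False)


def plant_mutation_effects(
    reference: ToyReference,
    rng: np.random.Generator,
    n_events: int,
    event_mix: Mapping[str, float] | None = None,
    score_range: tuple[float, float] = TRUE_SCORE_RANGE,
    exclude: set[str] | None = None,
) -> list[PlannedEvent]:
    """Draw events whose encoded predictor outputs reproduce known junctions."""
    mix = tuple((event_mix or dict(FixtureSpec().event_mix)).items())
    return _draw_events(
        reference, rng, n_events, mix, score_range, exclude if exclude is not None else set()
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    context: ContextSequence,
    depth: int,
    read_length: int,
    rng: np.random.Generator,
    min_overlap: int = 10,
    negative_control: bool = False,
    prefix: str = "read",
) -> list[Read]:
    """Simulate reads supporting one context sequence.

    Junction contexts get ``depth`` reads spanning the breakpoint with at
    least ``min_overlap`` bases on each side (or exactly ``min_overlap - 1``
    when ``negative_control`` is set); IR contexts get a read tiling that
    covers the whole retained intron ``depth`` times.  Reads are error-free.
    """
    if read_length < 2 * min_overlap:
        raise SpliceTargetError(
            f"read length {read_length} cannot span a junction with "
            f"{min_overlap} bases per side"
        )
    seq = context.cts_seq
    reads = []
    if context.event_class == "IR":
        lo, hi = context.intron_interval
        stride = max(1, read_length // 2)
        starts = list(range(max(1, lo - read_length + 1), hi + 1, stride))
        for d in range(depth):
            for i, s in enumerate(starts):
                s = min(s, len(seq) - read_length + 1)
                if s < 1:
                    continue
                reads.append(
                    Read(
                        read_id=f"{prefix}_ir{d}_{i}",
                        seq=seq[s - 1 : s - 1 + read_length],
                        mate_id=f"{prefix}_ir{d}_{i}",
                    )
                )
    else:
        pos = context.cts_junc_pos
        overlap_lo = min_overlap - 1 if negative_control else min_overlap
        overlap_hi = overlap_lo if negative_control else read_length - min_overlap
        for d in range(depth):
            left = int(rng.integers(overlap_lo, overlap_hi + 1))
            start = pos - left + 1
            start = max(1, min(start, len(seq) - read_length + 1))
            reads.append(
                Read(
                    read_id=f"{prefix}_j{d}",
                    seq=seq[start - 1 : start - 1 + read_length],
                    mate_id=f"{prefix}_j{d}",
                )
            )
    return reads


def write_fastq(reads: list[Read], path: str) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A simulated multi-sample cohort with planted truth, written to disk."""

    root: str
    spec: FixtureSpec
    reference: ToyReference
    manifest: pd.DataFrame
    truth: pd.DataFrame  # junction_id, kind, carrier_sample, variant_id, ...
    events: list[PlannedEvent] = field(default_factory=list)

    @property
    def true_junction_ids(self) -> set[str]:
        return set(self.truth.loc[self.truth["kind"] == "true", "junction_id"])

    @property
    def decoy_junction_ids(self) -> set[str]:
        return set(self.truth.loc[self.truth["kind"] == "decoy", "junction_id"])


def _leafcutter_rows(junction: SpliceJunction, count: int, cluster: int) -> dict:
    return {
        "intron": f"{junction.chrom}:{junction.start + 1}:{junction.end - 1}:clu{cluster}",
        "count": count,
        "strand": junction.strand,
    }


def _spladder_es_row(
    tx: TranscriptModel, junction: SpliceJunction, count: int
) -> dict | None:
    """Reconstruct the SplAdder ES coordinates for a skip junction."""
    for k in range(1, len(tx.exons) - 1):
        if (tx.exons[k - 1][1], tx.exons[k + 1][0]) == (junction.start, junction.end):
            return {
                "event_type": "ES",
                "chrom": tx.chrom,
                "strand": tx.strand,
                "e1_end": tx.exons[k - 1][1],
                "e2_start": tx.exons[k][0],
                "e2_end": tx.exons[k][1],
                "e3_start": tx.exons[k + 1][0],
                "count": count,
            }
    return None


def make_cohort(spec: FixtureSpec, root: str) -> Cohort:
    """Build a complete cohort directory (reference, per-sample inputs, truth).

    True junctions appear only in their carrier sample (variant, reads and
    caller hits); decoys additionally appear in the caller tables of one to
    two other samples of the same group.  Samples are split round-robin
    into ``n_groups`` study groups.
    """
    rng = np.random.default_rng(spec.seed)
    os.makedirs(root, exist_ok=True)
    reference = make_toy_reference(spec.seed, out_dir=root)
    samples = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    groups = {sid: f"study{i % spec.n_groups + 1}" for i, sid in enumerate(samples)}

    mix = dict(spec.event_mix)
    used: set[str] = set()
    true_events = plant_mutation_effects(
        reference, rng, spec.n_true_junctions, mix, TRUE_SCORE_RANGE, used
    )
    # decoys are restricted to classes the detection rule can retain
    decoy_mix = {k: v for k, v in mix.items() if k != "IR"} or {"ES": 1.0}
    decoy_events = plant_mutation_effects(
        reference, rng, spec.n_decoy_junctions, decoy_mix, DECOY_SCORE_RANGE, used
    )

    per_sample_events: dict[str, list[PlannedEvent]] = {sid: [] for sid in samples}
    caller_hits: dict[str, list[PlannedEvent]] = {sid: [] for sid in samples}
    read_support: dict[str, list[PlannedEvent]] = {sid: [] for sid in samples}
    truth_rows = []

    for ev in true_events:
        carrier = samples[int(rng.integers(len(samples)))]
        per_sample_events[carrier].append(ev)
        read_support[carrier].append(ev)
        if ev.kind != "IR" and rng.random() < 0.5:
            caller_hits[carrier].append(ev)
        truth_rows.append(
            {
                "junction_id": ev.junction.junction_id,
                "kind": "true",
                "event_class": ev.kind,
                "carrier_sample": carrier,
                "variant_id": ev.variant_id,
                "score": ev.score,
            }
        )
    for ev in decoy_events:
        carrier = samples[int(rng.integers(len(samples)))]
        per_sample_events[carrier].append(ev)
        caller_hits[carrier].append(ev)
        same_group = [
            s for s in samples if s != carrier and groups[s] == groups[carrier]
        ]
        n_extra = min(len(same_group), int(rng.integers(1, 3)))
        extra = list(rng.choice(same_group, size=n_extra, replace=False))
        for other in extra:
            caller_hits[other].append(ev)
        truth_rows.append(
            {
                "junction_id": ev.junction.junction_id,
                "kind": "decoy",
                "event_class": ev.kind,
                "carrier_sample": carrier,
                "variant_id": ev.variant_id,
                "score": ev.score,
            }
        )

    manifest_rows = []
    for sid in samples:
        sdir = os.path.join(root, sid)
        os.makedirs(sdir, exist_ok=True)
        events = per_sample_events[sid]
        vcf_path = os.path.join(sdir, f"{sid}.vcf")
        write_vcf([e for e in events if e.spliceai_channel], reference, vcf_path)
        mmsplice_path = os.path.join(sdir, f"{sid}.mmsplice.tsv")
        write_mmsplice(events, mmsplice_path)

        lc_rows, sp_rows = [], []
        for i, ev in enumerate(caller_hits[sid]):
            if ev.junction.is_ir_shaped:
                continue
            lc_rows.append(_leafcutter_rows(ev.junction, int(rng.integers(3, 20)), i))
            if ev.kind == "ES":
                tx = reference.transcripts[ev.transcript_id]
                row = _spladder_es_row(tx, ev.junction, int(rng.integers(3, 20)))
                if row is not None:
                    sp_rows.append(row)
        lc_path = os.path.join(sdir, f"{sid}.leafcutter.tsv")
        pd.DataFrame(lc_rows, columns=["intron", "count", "strand"]).to_csv(
            lc_path, sep="\t", index=False
        )
        sp_path = os.path.join(sdir, f"{sid}.spladder.tsv")
        pd.DataFrame(
            sp_rows,
            columns=[
                "event_type", "chrom", "strand",
                "e1_end", "e2_start", "e2_end", "e3_start", "count",
            ],
        ).to_csv(sp_path, sep="\t", index=False)

        reads: list[Read] = []
        for ev in read_support[sid]:
            tx = reference.transcripts[ev.transcript_id]
            context = add_context_seq(ev.junction, tx, reference.genome, flank=200)
            reads.extend(
                simulate_reads(
                    context,
                    depth=spec.depth,
                    read_length=spec.read_length,
                    rng=rng,
                    prefix=f"{sid}_{ev.junction.junction_id.replace(':', '_')}",
                )
            )
        fastq_path = os.path.join(sdir, f"{sid}.R1.fastq")
        write_fastq(reads, fastq_path)

        manifest_rows.append(
            {
                "sample_id": sid,
                "group": groups[sid],
                "vcf": os.path.relpath(vcf_path, root),
                "mmsplice": os.path.relpath(mmsplice_path, root),
                "leafcutter": os.path.relpath(lc_path, root),
                "spladder": os.path.relpath(sp_path, root),
                "fastq": os.path.relpath(fastq_path, root),
            }
        )

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(os.path.join(root, "manifest.tsv"), sep="\t", index=False)
    truth = pd.DataFrame(
        truth_rows,
        columns=["junction_id", "kind", "event_class", "carrier_sample", "variant_id", "score"],
    )
    truth.to_csv(os.path.join(root, "truth.tsv"), sep="\t", index=False)
    with open(os.path.join(root, "normal_junctions.txt"), "w") as fh:
        fh.write("")  # no "normal"-listed junctions planted by default
    return Cohort(
        root=root,
        spec=spec,
        reference=reference,
        manifest=manifest,
        truth=truth,
        events=true_events + decoy_events,
    )


def planted_effect_junctions(cohort: Cohort) -> list[EffectJunction]:
    """The effect junctions a perfect converter should produce (per truth)."""
    out = []
    for ev in cohort.events:
        out.append(
            EffectJunction(
                junction=ev.junction,
                transcript_id=ev.transcript_id,
                event_class=ev.kind,
                score=ev.score if ev.spliceai_channel else -ev.score,
                variant_id=ev.variant_id,
                tool="spliceai" if ev.spliceai_channel else "mmsplice",
            )
        )
    return out
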