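"""End-to-end workflow: manifest-driven cohort analysis.

Chains the library modules into the full target-prediction workflow: parse
mutation effect predictions and RNA-seq junction calls per sample, convert
effects into junctions, remove canonical/normal junctions, build context
sequences, requantify junction support in the sample's own reads and —
for the permutation FDR — in every other sample's reads, assemble
candidates, and search the detection-rule grid.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotate import ContextSequence, add_context_seq
from .core import (
    SpliceTargetError,
    TranscriptModel,
    load_transcripts,
    parse_junction_id,
)
from .detect import (
    READ_GRID,
    SCORE_GRID,
    CandidateRecord,
    DetectionRule,
    SampleEvidence,
    apply_detection_rule,
    assemble_candidates,
    estimate_fdr,
    grid_search,
    label_false_positives,
)
from .effects import (
    collapse_junctions,
    effects_to_junctions,
    mmsplice_to_junctions,
    parse_mmsplice,
    parse_spliceai_vcf,
)
from .requant import Read, read_fastq, requantify
from .rnaseq import (
    JunctionDatabase,
    build_canonical_db,
    filter_novel,
    parse_leafcutter,
    parse_spladder,
    union_replicates,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Workflow parameters; defaults are the published values."""

    flank: int = 200
    peptide_flank: int = 13
    min_overlap: int = 10
    mismatch_ratio: float = 0.015
    score_grid: Sequence[float] = SCORE_GRID
    read_grid: Sequence[int] = READ_GRID
    rule: DetectionRule = field(default_factory=DetectionRule)
    restrict_to_gene: bool = True


@dataclass
class SampleInputs:
    """Parsed per-sample inputs."""

    sample_id: str
    group: str
    mutation_junctions: pd.DataFrame  # collapsed, novel-only
    junction_transcripts: dict[str, str]  # junction_id -> representative tx
    rnaseq: "object"  # JunctionSet (full caller union, unfiltered)
    reads: list[Read]
    variant_ids: set[str]


@dataclass
class CohortResult:
    """Everything the detection stage produced."""

    candidates: list[CandidateRecord]
    baseline_fdr: float
    grid: pd.DataFrame
    best_rule: DetectionRule
    targets: list[CandidateRecord]
    target_fdr: float
    contexts: dict[str, ContextSequence] = field(default_factory=dict)

    def targets_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": t.sample_id,
                "junction_id": t.junction_id,
                "event_class": t.event_class,
                "spliceai_score": t.spliceai_score,
                "mmsplice_score": t.mmsplice_score,
                "tool_detected": t.tool_detected,
                "junction_reads": t.junction_reads,
                "is_false_positive": t.is_false_positive,
            }
            for t in self.targets
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id", "junction_id", "event_class", "spliceai_score",
                "mmsplice_score", "tool_detected", "junction_reads",
                "is_false_positive",
            ],
        )


def load_sample(
    root: str,
    row: Mapping[str, str],
    transcripts: dict[str, TranscriptModel],
    canonical_db: JunctionDatabase,
    normal_db: JunctionDatabase | None,
    config: PipelineConfig,
) -> SampleInputs:
    """Parse one manifest row into junction tables, caller sets and reads."""
    sample_id = str(row["sample_id"])

    effect_junctions = []
    variant_ids: set[str] = set()
    vcf = os.path.join(root, str(row["vcf"]))
    for effect in parse_spliceai_vcf(vcf):
        variant_ids.add(effect.variant_id)
        effect_junctions.extend(
            effects_to_junctions(
                effect, transcripts, restrict_to_gene=config.restrict_to_gene
            )
        )
    mmsplice = os.path.join(root, str(row["mmsplice"]))
    for effect in parse_mmsplice(mmsplice):
        variant_ids.add(effect.variant_id)
        effect_junctions.extend(mmsplice_to_junctions(effect, transcripts))

    collapsed = collapse_junctions(effect_junctions)
    known = set(canonical_db.junctions)
    if normal_db is not None:
        known |= set(normal_db.junctions)
    novel = collapsed[~collapsed["junction_id"].isin(known)].reset_index(drop=True)
    junction_transcripts = {
        row_.junction_id: sorted(str(row_.transcript_ids).split(","))[0]
        for row_ in novel.itertuples(index=False)
    }

    tool_sets = []
    lc = str(row.get("leafcutter", "") or "")
    if lc:
        tool_sets.append(
            parse_leafcutter(
                os.path.join(root, lc), sample_id, transcripts=transcripts.values()
            )
        )
    sp = str(row.get("spladder", "") or "")
    if sp:
        tool_sets.append(parse_spladder(os.path.join(root, sp), sample_id))
    if not tool_sets:
        raise SpliceTargetError(f"sample {sample_id} has no RNA-seq junction table")
    rnaseq = union_replicates(tool_sets)

    reads: list[Read] = []
    for fq in str(row["fastq"]).split(","):
        reads.extend(read_fastq(os.path.join(root, fq.strip())))
    return SampleInputs(
        sample_id=sample_id,
        group=str(row.get("group", "cohort")),
        mutation_junctions=novel,
        junction_transcripts=junction_transcripts,
        rnaseq=rnaseq,
        reads=reads,
        variant_ids=variant_ids,
    )


def build_contexts(
    samples: Sequence[SampleInputs],
    transcripts: dict[str, TranscriptModel],
    genome,
    config: PipelineConfig,
) -> tuple[dict[str, ContextSequence], dict[str, str]]:
    """One context per distinct mutation junction across the cohort.

    Returns contexts keyed by cts_id plus the junction_id -> cts_id map.
    """
    contexts: dict[str, ContextSequence] = {}
    junction_to_cts: dict[str, str] = {}
    for sample in samples:
        for row in sample.mutation_junctions.itertuples(index=False):
            if row.junction_id in junction_to_cts:
                continue
            tx = transcripts[sample.junction_transcripts[row.junction_id]]
            junction = parse_junction_id(row.junction_id, row.event_class)
            try:
                context = add_context_seq(junction, tx, genome, flank=config.flank)
            except SpliceTargetError as exc:
                logger.warning("no context for %s: %s", row.junction_id, exc)
                continue
            contexts[context.cts_id] = context
            junction_to_cts[row.junction_id] = context.cts_id
    return contexts, junction_to_cts


def _support_maps(
    results: Mapping[str, "object"],
    contexts: Mapping[str, ContextSequence],
    junction_to_cts: Mapping[str, str],
) -> tuple[dict[str, int], dict[str, float]]:
    junction_reads: dict[str, int] = {}
    ir_median: dict[str, float] = {}
    for junction_id, cts_id in junction_to_cts.items():
        result = results.get(cts_id)
        if result is None:
            continue
        junction_reads[junction_id] = result.primary_junction_reads
        if contexts[cts_id].event_class == "IR":
            ir_median[junction_id] = result.coverage_median[1]
    return junction_reads, ir_median


def run_cohort(
    root: str,
    config: PipelineConfig | None = None,
    manifest: pd.DataFrame | None = None,
    genome_fasta: str = "genome.fa",
    annotation_gtf: str = "annotation.gtf",
    normal_junctions: str = "normal_junctions.txt",
) -> CohortResult:
    """Run the full workflow on a cohort directory.

    Expects ``manifest.tsv`` (columns ``sample_id, group, vcf, mmsplice,
    leafcutter, spladder, fastq``) with paths relative to ``root``.
    """
    config = config or PipelineConfig()
    if manifest is None:
        manifest = pd.read_csv(os.path.join(root, "manifest.tsv"), sep="\t")
    import pyfaidx

    genome = pyfaidx.Fasta(os.path.join(root, genome_fasta))
    transcripts = load_transcripts(os.path.join(root, annotation_gtf))
    canonical_db = build_canonical_db(transcripts)
    normal_path = os.path.join(root, normal_junctions)
    normal_db = (
        JunctionDatabase.from_file(normal_path, "normal")
        if os.path.exists(normal_path)
        else None
    )

    samples = [
        load_sample(root, row._asdict(), transcripts, canonical_db, normal_db, config)
        for row in manifest.itertuples(index=False)
    ]
    contexts, junction_to_cts = build_contexts(
        samples, transcripts, genome, config
    )

    # requantify every candidate context in every sample (own support and
    # cross-sample permutation evidence in one pass)
    all_contexts = list(contexts.values())
    requant_by_sample = {
        s.sample_id: requantify(
            all_contexts,
            s.reads,
            min_overlap=config.min_overlap,
            mismatch_ratio=config.mismatch_ratio,
        )
        for s in samples
    }

    candidates: list[CandidateRecord] = []
    evidence: dict[str, SampleEvidence] = {}
    groups: dict[str, str] = {}
    for sample in samples:
        junction_reads, ir_median = _support_maps(
            requant_by_sample[sample.sample_id], contexts, junction_to_cts
        )
        candidates.extend(
            assemble_candidates(
                sample.mutation_junctions,
                sample.rnaseq,
                junction_reads,
                ir_median,
                sample_id=sample.sample_id,
            )
        )
        evidence[sample.sample_id] = SampleEvidence(
            sample_id=sample.sample_id,
            rnaseq_junctions=sample.rnaseq.ids(),
            junction_reads=junction_reads,
            ir_median=ir_median,
            variant_ids=sample.variant_ids,
        )
        groups[sample.sample_id] = sample.group

    labelled = label_false_positives(candidates, evidence, groups)
    baseline_fdr = estimate_fdr(labelled)
    grid, best_rule = grid_search(labelled, config.score_grid, config.read_grid)
    targets = [c for c in labelled if apply_detection_rule(c, best_rule)]
    return CohortResult(
        candidates=labelled,
        baseline_fdr=baseline_fdr,
        grid=grid,
        best_rule=best_rule,
        targets=targets,
        target_fdr=estimate_fdr(targets),
        contexts=contexts,
    )
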