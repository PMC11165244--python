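"""Candidate assembly, permutation FDR estimation and detection-rule search.

A *candidate* is a novel mutation-retrieved junction with any RNA-seq
support in its own sample: detection by a junction caller, at least one
requantified junction read, or (for intron retention) median intron
coverage above zero.

The false-discovery estimate is a sample permutation: a candidate is
labelled a false positive when at least one other sample of the same study
group — that does not carry the causative variant — shows the same support
(tool hit, >= 1 junction read, or IR median coverage > 0).  The estimated
FDR is the false-positive fraction of all candidates.

The published detection rule is recovered by a grid search over effect-
score thresholds ``s`` (applied symmetrically: SpliceAI >= s or MMSplice
<= -s) and junction-read thresholds ``r``, choosing the cell with the
lowest FDR (ties: more targets, then smaller s, then smaller r).  The
false-positive labels use the fixed support definition at every grid cell
so FDR estimates stay comparable across cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import SpliceTargetError
from .rnaseq import JunctionDatabase, JunctionSet

logger = logging.getLogger(__name__)

# threshold grids used for the detection-rule search
SCORE_GRID = (0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
READ_GRID = (1, 2, 3, 4)

TARGET_EVENT_CLASSES = frozenset({"ES", "A3SS", "A5SS"})


@dataclass(frozen=True)
class DetectionRule:
    """Thresholds of the target detection rule."""

    score_threshold: float = 0.35
    read_threshold: int = 3
    event_classes: frozenset[str] = TARGET_EVENT_CLASSES

    def __post_init__(self) -> None:
        if self.score_threshold < 0:
            raise SpliceTargetError("score threshold must be >= 0")
        if self.read_threshold < 1:
            raise SpliceTargetError("read threshold must be >= 1")


@dataclass
class CandidateRecord:
    """One mutation-retrieved junction with its RNA-seq evidence."""

    sample_id: str
    junction_id: str
    event_class: str
    spliceai_score: float | None = None
    mmsplice_score: float | None = None
    variant_ids: frozenset[str] = field(default_factory=frozenset)
    tool_detected: bool = False
    junction_reads: int = 0
    ir_median_coverage: float | None = None
    is_false_positive: bool | None = None

    def __post_init__(self) -> None:
        if self.spliceai_score is None and self.mmsplice_score is None:
            raise SpliceTargetError(
                f"candidate {self.junction_id} has no mutation effect score"
            )


def _has_support(
    tool_detected: bool,
    junction_reads: int,
    event_class: str,
    ir_median: float | None,
) -> bool:
    if tool_detected or junction_reads >= 1:
        return True
    return event_class == "IR" and ir_median is not None and ir_median > 0


@dataclass(frozen=True)
class SampleEvidence:
    """Per-sample RNA-seq evidence for cross-sample false-positive checks."""

    sample_id: str
    rnaseq_junctions: set[str]  # junction ids from the caller union
    junction_reads: Mapping[str, int]  # junction_id -> requantified reads
    ir_median: Mapping[str, float]  # junction_id -> intron median coverage
    variant_ids: set[str]  # somatic variants carried by the sample

    def supports(self, junction_id: str, event_class: str) -> bool:
        return _has_support(
            junction_id in self.rnaseq_junctions,
            self.junction_reads.get(junction_id, 0),
            event_class,
            self.ir_median.get(junction_id),
        )


def assemble_candidates(
    mutation_junctions: pd.DataFrame,
    rnaseq_junctions: JunctionSet,
    junction_reads: Mapping[str, int],
    ir_median: Mapping[str, float] | None = None,
    sample_id: str | None = None,
) -> list[CandidateRecord]:
    """Join mutation-retrieved junctions with their same-sample RNA-seq support.

    ``mutation_junctions`` is a collapsed effect-junction table (columns
    ``junction_id, event_class, tool, score, variant_ids``); junctions
    without requantification results are treated as unsupported (zero
    reads), logged at debug level.  Only supported junctions become
    candidates.
    """
    ir_median = ir_median or {}
    sample_id = sample_id or rnaseq_junctions.sample_id
    by_junction: dict[str, dict] = {}
    for row in mutation_junctions.itertuples(index=False):
        rec = by_junction.setdefault(
            row.junction_id,
            {
                "event_class": row.event_class,
                "spliceai": None,
                "mmsplice": None,
                "variants": set(),
            },
        )
        if row.tool == "spliceai":
            rec["spliceai"] = (
                row.score
                if rec["spliceai"] is None
                else max(rec["spliceai"], row.score)
            )
        else:
            rec["mmsplice"] = (
                row.score
                if rec["mmsplice"] is None
                else min(rec["mmsplice"], row.score)
            )
        rec["variants"].update(str(row.variant_ids).split(","))
    candidates = []
    for junction_id, rec in sorted(by_junction.items()):
        if junction_id not in junction_reads:
            logger.debug("no requant result for %s; treated as zero support", junction_id)
        reads = junction_reads.get(junction_id, 0)
        tool_detected = junction_id in rnaseq_junctions
        median = ir_median.get(junction_id)
        if not _has_support(tool_detected, reads, rec["event_class"], median):
            continue
        candidates.append(
            CandidateRecord(
                sample_id=sample_id,
                junction_id=junction_id,
                event_class=rec["event_class"],
                spliceai_score=rec["spliceai"],
                mmsplice_score=rec["mmsplice"],
                variant_ids=frozenset(rec["variants"]),
                tool_detected=tool_detected,
                junction_reads=reads,
                ir_median_coverage=median,
            )
        )
    return candidates


def label_false_positives(
    candidates: Iterable[CandidateRecord],
    evidence: Mapping[str, SampleEvidence],
    sample_groups: Mapping[str, str],
) -> list[CandidateRecord]:
    """Set ``is_false_positive`` by cross-sample permutation.

    A candidate is a false positive when >= 1 other sample of the same
    group, not carrying any of the candidate's variants, supports the
    junction.  Groups with a single sample cannot be evaluated; their
    candidates keep ``is_false_positive = None``.
    """
    labelled = []
    group_sizes: dict[str, int] = {}
    for sid, group in sample_groups.items():
        group_sizes[group] = group_sizes.get(group, 0) + 1
    for cand in candidates:
        group = sample_groups.get(cand.sample_id)
        if group is None:
            raise SpliceTargetError(f"sample {cand.sample_id} not in any group")
        if group_sizes[group] < 2:
            logger.warning(
                "group %s has a single sample; candidate %s cannot be evaluated",
                group,
                cand.junction_id,
            )
            labelled.append(replace_label(cand, None))
            continue
        fp = False
        for other_id, other in evidence.items():
            if other_id == cand.sample_id:
                continue
            if sample_groups.get(other_id) != group:
                continue
            if cand.variant_ids & other.variant_ids:
                continue  # carrier of the causative mutation: excluded
            if other.supports(cand.junction_id, cand.event_class):
                fp = True
                break
        labelled.append(replace_label(cand, fp))
    return labelled


def replace_label(cand: CandidateRecord, value: bool | None) -> CandidateRecord:
    out = CandidateRecord(**{**cand.__dict__, "is_false_positive": value})
    return out


def estimate_fdr(candidates: Sequence[CandidateRecord]) -> float:
    """False positives / all candidates; NaN for an empty candidate list."""
    candidates = [c for c in candidates if c.is_false_positive is not None]
    if not candidates:
        return math.nan
    n_fp = sum(c.is_false_positive for c in candidates)
    return n_fp / len(candidates)


def apply_detection_rule(cand: CandidateRecord, rule: DetectionRule) -> bool:
    """The published three-clause detection rule.

    (i) event class in {ES, A3SS, A5SS} (IR excluded), (ii) SpliceAI score
    >= s or MMSplice score <= -s, (iii) caller detection or >= r junction
    reads.
    """
    if cand.event_class not in rule.event_classes:
        return False
    score_ok = (
        cand.spliceai_score is not None
        and cand.spliceai_score >= rule.score_threshold
    ) or (
        cand.mmsplice_score is not None
        and cand.mmsplice_score <= -rule.score_threshold
    )
    if not score_ok:
        return False
    return cand.tool_detected or cand.junction_reads >= rule.read_threshold


def grid_search(
    candidates: Sequence[CandidateRecord],
    score_grid: Sequence[float] = SCORE_GRID,
    read_grid: Sequence[int] = READ_GRID,
) -> tuple[pd.DataFrame, DetectionRule]:
    """Evaluate every (s, r) threshold pair and pick the lowest-FDR rule.

    Returns the full grid table (columns ``score_threshold, read_threshold,
    n_targets, fdr``) and the best rule.  Ties on FDR are broken by more
    targets, then smaller s, then smaller r; cells with no surviving target
    have FDR NaN and never win.
    """
    if not score_grid or not read_grid:
        raise SpliceTargetError("empty threshold grid")
    rows = []
    best_key = None
    best_rule = None
    for s in score_grid:
        for r in read_grid:
            rule = DetectionRule(score_threshold=s, read_threshold=r)
            targets = [c for c in candidates if apply_detection_rule(c, rule)]
            fdr = estimate_fdr(targets)
            rows.append(
                {
                    "score_threshold": s,
                    "read_threshold": r,
                    "n_targets": len(targets),
                    "fdr": fdr,
                }
            )
            if not math.isnan(fdr):
                key = (fdr, -len(targets), s, r)
                if best_key is None or key < best_key:
                    best_key = key
                    best_rule = rule
    table = pd.DataFrame(
        rows, columns=["score_threshold", "read_threshold", "n_targets", "fdr"]
    )
    if best_rule is None:
        logger.warning("no grid cell retained any evaluable target")
        best_rule = DetectionRule(
            score_threshold=score_grid[0], read_threshold=read_grid[0]
        )
    return table, best_rule


def healthy_tissue_check(
    targets: Sequence[CandidateRecord],
    healthy_db: JunctionDatabase,
) -> tuple[pd.DataFrame, float]:
    """Flag targets found in the healthy-tissue junction database.

    Returns the per-target table and the found fraction (NaN when there are
    no targets).
    """
    rows = [
        {
            "sample_id": t.sample_id,
            "junction_id": t.junction_id,
            "found_in_healthy": t.junction_id in healthy_db,
        }
        for t in targets
    ]
    table = pd.DataFrame(rows, columns=["sample_id", "junction_id", "found_in_healthy"])
    fraction = float(table["found_in_healthy"].mean()) if len(table) else math.nan
    return table, fraction
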