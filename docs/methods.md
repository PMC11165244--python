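# Methods

## Problem and model

Mutation-derived splicing is modelled at the level of *splice junctions*:
`chrom:start-end:strand`, where `start` is the last genomic base of the
left exon and `end` the first genomic base of the right exon, 1-based and
genomically ordered regardless of strand. "Upstream"/"downstream" always
mean transcript orientation (descending genomic order on the minus
strand); the converters work in transcript orientation and normalise to
genomic order afterwards. Intron retention (IR) is represented as a
width-1 pseudo-junction (`end = start + 1`) straddling an exon-intron
boundary. Chromosome names are never rewritten; a `chr`-prefix mismatch
between inputs is an error, not a silent fix.

Donor/acceptor gain and loss effects are resolved per overlapping
transcript by the rule table in the README. Two interpretation points are
deliberate:

* A loss effect must hit an *annotated* boundary base of the transcript
  exactly (tolerance 0 bp); otherwise that transcript is skipped and
  logged. The rules presuppose a lost annotated site, and a deep-intronic
  "loss" position has no defined exon to skip.
* The exon-skipping partner of a loss on exon *k* joins exons *k−1* and
  *k+1* in transcript orientation (single-exon skips only; multi-exon and
  mutually-exclusive-exon events are out of scope). Terminal exons have no
  skip partner and yield the IR junction only.

SpliceAI-style effects with delta score exactly 0 are suppressed by
default — a zero score encodes "no predicted change" — but
`min_emit_score` can be lowered to emit everything. The MMSplice reader
keeps rows with `delta_logit_psi ≤ 0` (predicted increased skipping) and
uses `delta_logit_psi` itself as the effect score.

## Context sequences and identifiers

For ES/A3SS/A5SS junctions the context sequence is built on the *modified
transcript*: the exon chain truncated at the left anchor joined to the
chain truncated at the right anchor, with anchors inside introns extending
the neighbouring exon (this is how alternative splice sites contribute
retained intronic sequence). The context covers up to 200 exonic bases
per side of the breakpoint (spliced across exons, truncated at transcript
ends); `cts_junc_pos` counts the bases preceding the breakpoint. For IR
the context is the complete intron plus up to 200 bases from the intron's
*adjacent* exons only — an IR read measures locally unspliced pre-mRNA,
so the context stays contiguous on the genome; `intron_interval` locates
the intron within the sequence. Minus-strand contexts are
reverse-complemented so sequences read 5'→3' of the transcript.

Context identifiers are XXH3-128 hashes over
`"<cts_seq>|junc:<pos>"` (or `"...|intron:<lo>-<hi>"`), so identical
sequence+position pairs collide by construction and nothing else does in
practice. The hash is implemented in pure Python from the public XXH3
specification (seed 0, default secret) and is pinned against an
independent reference implementation by frozen test vectors covering every
internal length class.

## CDS modification and peptides

The wild-type CDS is spliced through the same modified chain. The
modified CDS runs from the wild-type start codon to the wild-type stop
position mapped into the modified transcript; a junction that leaves this
sequence unchanged (UTR-only events) or removes the start codon yields no
product. A frameshift is flagged when wild-type and modified CDS lengths
differ by a non-multiple of three; frameshifted (or stop-less) products
are translated through the 3' end of the modified transcript so the novel
C-terminus runs to its true stop codon. Products without any stop are
kept and flagged (`no_stop_flag`) rather than dropped, so downstream
filtering stays explicit. IR junctions are never translated — IR events
are excluded from target selection anyway (below).

The junction's protein position is
`junction_aa_pos = (junc_pos_in_cds − 1) // 3 + 1` (the residue at or left
of the event) and `junc_pos_in_cds mod 3` gives the reading-frame offset:
non-zero means the junction codon is chimeric. In-frame peptides keep the
junction residues (chimeric codon product and inserted residues) plus up
to 13 wild-type residues per side — 26 residues in the clean
between-codon case; frameshift peptides keep the upstream wild-type flank
and the entire novel C-terminus. A mutated protein that is merely a
(truncated) copy of the wild type yields no peptide.

## Targeted requantification

Each context is partitioned at its breakpoints: two intervals for
ES/A3SS/A5SS (the end of the first interval is the junction), three for IR
(the middle interval is the retained intron). Reads are placed end-to-end
by exact scan with mismatch fraction ≤ 0.015 and no indels, mirroring an
aligner run with prohibitive gap penalties; pre-aligned SAM against the
context FASTA is accepted equivalently. Counter definitions:

* junction/interval-end overlap counts require ≥ 10 aligned bases on
  *each* side of the position. The two-sided reading is the stricter of
  the possible interpretations of "covering the junction position by at
  least 10 bp" and mirrors anchor-based junction callers.
* spanning pairs: both mates fully inside different intervals.
* coverage summaries use per-position depth; the median is the *lower*
  median, which is conservative for the IR support call
  (intron median > 0).
* a read aligning to several contexts counts once per context — the tool
  quantifies per-candidate evidence, not a global read assignment.

Replicates are merged by summing counters and depth arrays before
recomputing coverage summaries.

## Candidates, permutation FDR and the detection rule

A *candidate* is a novel (non-canonical, non-normal) mutation-retrieved
junction with same-sample RNA-seq support: caller detection, ≥ 1 junction
read, or IR intron median coverage > 0. Per junction, the SpliceAI score
is aggregated as the maximum and the MMSplice score as the minimum over
contributing (variant, transcript) pairs.

False positives are identified by sample permutation within each study
group: a candidate is a false positive if at least one other sample of the
group, not carrying any of the candidate's variants, shows the same
support. Carrier status is defined by the variant, not the junction.
Groups with a single sample cannot be evaluated and stay unlabelled. The
FDR estimate is FP / candidates.

The grid search evaluates score thresholds
{0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9}
(applied symmetrically: SpliceAI ≥ s or MMSplice ≤ −s) against read
thresholds {1, 2, 3, 4}. False-positive labels use the *fixed* support
definition at every cell rather than the cell's own read threshold, so
FDR estimates are comparable across cells. Ties on minimal FDR are broken
by more targets, then smaller s, then smaller r. IR events are excluded
from targets: their cross-sample support rates stay high under
permutation, so no rule controls their FDR. The default operating point
(0.35 / 3 reads) is the published rule.

## Synthetic cohorts

The fixture generator emulates the discovery/verification cohort design at
desk scale. The toy genome carries three multi-exon transcripts on both
strands (100-bp exons, 100-bp introns, GT/AG planted at intron boundaries,
stop-free ORFs with terminal stop); everything else is uniform random with
a fixed seed, and identical seeds give byte-identical files. Default
cohort conditions: 6 samples in 2 study groups, 8 true junctions (effect
scores uniform 0.5–1.0, support only in the carrier sample: the variant,
5 error-free 50-bp junction-spanning reads, and a 50 % chance of a caller
hit) and 8 decoy junctions (scores 0.01–0.1, caller hits in the carrier
plus 1–2 other same-group samples), event mix 40 % ES / 20 % A3SS /
20 % A5SS / 20 % IR, decoys drawn from the non-IR classes. Negative-
control reads with 9-bp overlap exercise the threshold boundary.

What the simulation does *not* model: sequencing errors by default (an
option injects mismatches), expression variability, multi-mapping
ambiguity between genomic loci, overlapping genes, FFPE artifacts and
germline variation. Passing the closed-loop tests therefore shows the
bookkeeping — conversion rules, requantification, permutation labeling,
grid search — is exact under clean separation; it does not certify
performance on real tumor data, where score distributions overlap and
support is noisy.

## Numerical and degenerate-input choices

* Junction codec: descending input coordinates are swapped; `start == end`
  is an error; IR junctions must satisfy `end = start + 1`.
* Alignment acceptance is `mismatches ≤ floor(ratio × read_length)`; ties
  between placements resolve to fewest mismatches, forward orientation,
  leftmost offset.
* `estimate_fdr` of an empty candidate set is NaN, never 0 — absence of
  evidence is not evidence of specificity; grid cells with no surviving
  targets report NaN and cannot win the search.
* Problem sizes in tests (6-sample cohorts, 100-bp exons, depth 5, 20
  seeds for the closed loop) are chosen so the full suite exercises every
  path in seconds while keeping all planted separations recoverable.
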