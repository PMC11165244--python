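# splicetarget

Tumor-specific splice junctions as a source of neoantigen candidates.

Somatic mutations can destroy or create splice donor/acceptor motifs,
producing splice junctions that — unlike most non-canonical junctions seen
in tumor RNA-seq — are genuinely tumor-specific, because the causative
mutation is absent from normal tissue. `splicetarget` turns splice-effect
predictions for somatic variants into concrete junctions, annotates their
transcript and peptide consequences, requantifies junction support in
RNA-seq reads with a targeted mapper, and selects *target* junctions with a
permutation-based, FDR-controlled detection rule. It is written for
computational immuno-oncology groups building individualized cancer-vaccine
pipelines, and every stage reads/writes flat TSV so single stages can be
swapped against real SpliceAI / MMSplice / LeafCutter / SplAdder / STAR
outputs.

## The model

A junction is `chrom:start-end:strand` where `start` is the last base of
the left exon and `end` the first base of the right exon (1-based,
genomic order). Predicted mutation effects are resolved per affected
transcript:

| effect        | class | junction coordinates                        |
|---------------|-------|---------------------------------------------|
| donor loss    | IR    | (pos, pos + strand_offset)                  |
| donor loss    | ES    | (upstream exon end, downstream exon start)  |
| donor gain    | A5SS  | (pos, downstream exon start)                |
| acceptor loss | IR    | (pos − strand_offset, pos)                  |
| acceptor loss | ES    | (upstream exon end, downstream exon start)  |
| acceptor gain | A3SS  | (upstream exon end, pos)                    |

with `strand_offset = +1` on the plus and `−1` on the minus strand; IR
pseudo-junctions must straddle an exon-intron boundary. MMSplice-style
per-exon scores with `delta_logit_psi ≤ 0` become exon-skipping junctions
joining the flanking exons.

Junctions surviving the canonical (annotation-derived) and normal
(e.g. GTEx-derived) exclusion lists get a transcript context sequence
(`cts_seq`, 200 bp exonic flank per side; IR contexts span the whole
intron) identified by an XXH3-128 hash (`cts_id`). Reads are mapped
end-to-end onto the context (mismatch fraction ≤ 0.015, no indels); a
*junction read* covers the breakpoint with ≥ 10 bp on each side.

The false-discovery rate is estimated by sample permutation: a candidate
supported in ≥ 1 other same-study sample that does not carry the causative
variant counts as a false positive; FDR = FP / candidates. A grid search
over score thresholds *s* ∈ {0, 0.05, …, 0.9} and read thresholds
*r* ∈ {1, 2, 3, 4} picks the lowest-FDR detection rule; the published
operating point is: ES/A3SS/A5SS events with (SpliceAI ≥ 0.35 or
MMSplice ≤ −0.35) and (caller detection or ≥ 3 junction reads).

## Worked example

Simulate a six-sample cohort with 8 mutation-caused ("true") and 8 decoy
junctions planted, then run the full workflow:

```bash
splicetarget simulate --seed 7 --out-dir demo/cohort
splicetarget run-all --cohort-dir demo/cohort --out-dir demo/out
```

prints

```json
{
  "n_candidates": 16,
  "baseline_fdr": 0.5,
  "best_rule": {
    "score_threshold": 0.15,
    "read_threshold": 1
  },
  "n_targets": 7,
  "target_fdr": 0.0
}
```

All 16 planted junctions have RNA-seq support and become candidates; half
are decoys that also occur in other samples, so the unfiltered FDR is 0.50.
The grid search finds the first score threshold above the decoy scores
(here 0.15) and retains the 7 non-IR true junctions at an estimated FDR of
0 (IR events never pass the rule). `demo/out/targets.tsv` lists each target
with its scores and evidence, e.g.

```
sample_id  junction_id      event_class  spliceai_score  mmsplice_score  tool_detected  junction_reads  is_false_positive
S01        chrTn:200-501:-  ES                           -0.53           False          5               False
S04        chrT:200-501:+   ES                           -0.79           True           5               False
```

The same workflow is available as a library (`splicetarget.run_cohort`)
and as per-stage subcommands `parse-effects`, `parse-rnaseq`, `annotate`,
`requant` and `detect`.

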