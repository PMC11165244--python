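import numpy as np
import pytest

from splicetarget.annotate import (
    add_context_seq,
    annotate_peptide,
    context_id,
    extract_peptide_context,
    modify_cds,
    reverse_complement,
    translate_cds,
)
from splicetarget.core import (
    SpliceTargetError,
    TranscriptModel,
    parse_junction_id,
)
from splicetarget.xxh3 import xxh3_128_hexdigest

from oracles import excised_cds_length

# frozen reference digests from an independent XXH3-128 implementation,
# covering every internal length class (empty / 1-3 / 4-8 / 9-16 / 17-128 /
# 129-240 / block-sized long inputs)
XXH3_VECTORS = [
    ("", "99aa06d3014798d86001c324468d497f"),
    ("C", "5abe4bc5963a3172616e98f5aa1c80c0"),
    ("GG", "155256ae5ad980b22949833e06243ee5"),
    ("TGC", "e039735b5a8652bde083023edb77b9aa"),
    ("GCCT", "65da36a12fb0c850678cd7d771e5dbf1"),
    ("TGTTC", "474c76a1594fae455e6a9555fcc31f73"),
    ("GTGCTGTT", "4d6d5a5a4adbd864adf1b403abb7dacf"),
    ("CGGCTCGAT", "6e6b590d0d629edef4fbd8363ad67436"),
    ("GCCGCTCTGTTA", "24da203fa0e76c460e2788f69a070914"),
    ("GCTAGAATAACTAGAG", "5d53305fa81eacc6b79b32eb14cf2182"),
    ("CTTATCGTCCCTGTCGA", "ec8db025d7ecc13c395653fe29295f23"),
    ("TCGAATTCGTTTCCTACCATCTGAATCTCTT", "e8c141d0bed49224cbcda92e21e23d41"),
    (
        "AGATGTGCAAATGTTCACATAGACTCGTTATCTTACGCAGCAGGGCGTCCTAAATATGCGTGAG",
        "d82ea56b5fcdf05733d76c28a4ad3f32",
    ),
    (
        "CTCTACTACATCGGTAGTCGTCAGCCTCCACGATAGCCTGTTGACGTCAGGCAACCTTGTGCGT"
        "GGTCATAGCTAGGCAATCTAACTCTTGTGAAG",
        "8b834476ee6dba988f908f2a33669ab0",
    ),
    (
        "ATATGTCAACCATCTAAAGGGGAAAAGGCAAGAGGGGCGCGGGTCCCAGAGGCAGGCGCACTGA"
        "TCTCTTGATTGTGCCACTCGGTGCCTCTTGCTCTTCTGTAAAGTCACCCACCTCTTACTCCTTC",
        "6f0557ca41b6356bc0e183f943fbef67",
    ),
    (
        "GCAGCAAGAAAGGGAGGCCGAGAACGCAAGGCCTCTGGCGCAAAGCGTACCTATATCCACTGAC"
        "TTTCACGAATATTTCTTACTATGACAATTTTATCCGCGAGTCAGAAGCCTCACGCTGGTATCTCA",
        "317ab9b1eaf944a54747e2110aa07f36",
    ),
    (
        "ATTCCGCTGGCGCGTGTCCCGAAATGTTGGTAGCGCAACCACCTTTGTTTTTGCCATGCCACCG"
        "GCGCCCAAAGGGTATACTGGTCACTTTGTGACAGAACTTAGTGTCACGAATTGTCAGGTCGCTC"
        "TGAACTGTACCGGCTAAAAGAATCGTACCCATGATTCGATCCCGTGGCGAGATGTGCTTAAATG"
        "GCCCGCGCAACTGGCCAAGTTTACTTCTACGACGGAAGACGACAAAGG",
        "9ac92a1b4b6aac51cb386d711848db06",
    ),
    (
        "GTCCTCCCACCTGTAATCAGTAACTGATTCATACATTGTCCCTTTCGTGGCCTAGTCAGGCATT"
        "GTCAAGTGAGCATCCTCACCAGTGTTAATGTGATTAATTGGGCCGAGAGGCCCGGATATACTGA"
        "TTAGCGGACCTGTAGTACGTTCCATGGTCCGTTTTACCTGGGACTAGCACAGCGCGAGTACTAA"
        "AAGGAACTATGTAAGATGGACAACGACCGGGCCTTTAACCCCTCACTGG",
        "2d198c6e27d2277d15e866522cca0869",
    ),
    ("ACGT|junc:2", "6e55ab927e27c26e57dbb56fcc9a877b"),
]


class TestXxh3:
    @pytest.mark.parametrize("data,expected", XXH3_VECTORS)
    def test_reference_vectors(self, data, expected):
        assert xxh3_128_hexdigest(data) == expected

    def test_long_input_block_boundaries(self):
        # deterministic long inputs around the 1024-byte block size
        rng = np.random.default_rng(99)
        for n in (241, 400, 1024, 1025, 2500):
            s = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
            assert xxh3_128_hexdigest(s) == xxh3_128_hexdigest(s)
            assert len(xxh3_128_hexdigest(s)) == 32

    def test_context_id_is_position_sensitive(self):
        a = context_id("ACGT", "junc:2")
        assert a == "6e55ab927e27c26e57dbb56fcc9a877b"
        assert context_id("ACGT", "junc:3") != a
        assert context_id("ACGT", "junc:2") == a


class TestContextSequence:
    def test_flank_truncation_at_transcript_start(self, tx1, genome):
        junction = parse_junction_id("chrT:200-501:+", "ES")
        ctx = add_context_seq(junction, tx1, genome)
        assert len(ctx.cts_seq) == 200
        assert ctx.cts_junc_pos == 100

    def test_full_flank_on_long_exons(self):
        tx = TranscriptModel(
            "TXL", "G", "chrL", "+", exons=((1, 500), (701, 1200))
        )
        rng = np.random.default_rng(1)
        genome = {"chrL": "".join("ACGT"[i] for i in rng.integers(0, 4, 1300))}
        junction = parse_junction_id("chrL:500-701:+", "ES")
        ctx = add_context_seq(junction, tx, genome)
        assert len(ctx.cts_seq) == 400
        assert ctx.cts_junc_pos == 200
        assert ctx.cts_seq == genome["chrL"][300:500] + genome["chrL"][700:900]

    def test_ir_context_spans_intron(self, tx1, genome):
        junction = parse_junction_id("chrT:400-401:+", "IR")
        ctx = add_context_seq(junction, tx1, genome)
        assert len(ctx.cts_seq) == 300
        assert ctx.intron_interval == (101, 200)
        assert ctx.cts_junc_pos is None
        # sequence is exon2 + intron2 + exon3, contiguous on the genome
        assert ctx.cts_seq == genome["chrT"][300:600]

    def test_minus_strand_context_is_reverse_complement(self, genome, tx1_minus):
        junction = parse_junction_id("chrT:200-501:-", "ES")
        ctx = add_context_seq(junction, tx1_minus, genome)
        # brute force: exon3 and exon1 joined, then reverse-complemented
        expected = reverse_complement(genome["chrT"][100:200] + genome["chrT"][500:600])
        assert ctx.cts_seq == expected
        assert ctx.cts_junc_pos == 100

    def test_a5ss_context_contains_retained_intron_bases(self, tx1, genome):
        # new donor inside intron 2: retained intronic sequence up to pos
        junction = parse_junction_id("chrT:420-501:+", "A5SS")
        ctx = add_context_seq(junction, tx1, genome)
        left = ctx.cts_seq[: ctx.cts_junc_pos]
        assert left.endswith(genome["chrT"][400:420])  # intron bases retained

    def test_anchor_outside_transcript_raises(self, tx1, genome):
        junction = parse_junction_id("chrT:50-501:+", "ES")
        with pytest.raises(SpliceTargetError):
            add_context_seq(junction, tx1, genome)

    def test_cts_ids_unique_across_fixture_contexts(self, reference):
        seen = set()
        for tid, tx in reference.transcripts.items():
            for junction_id in (
                f"{tx.chrom}:{tx.exons[0][1]}-{tx.exons[2][0]}:{tx.strand}",
                f"{tx.chrom}:{tx.exons[0][1]}-{tx.exons[1][0] + 5}:{tx.strand}",
            ):
                ctx = add_context_seq(
                    parse_junction_id(junction_id, "ES"), tx, reference.genome
                )
                assert ctx.cts_id not in seen
                seen.add(ctx.cts_id)


def _cds_only_transcript(middle_len: int) -> TranscriptModel:
    """Transcript whose exons are exactly its CDS: 60 / middle_len / 60 nt."""
    e2 = (201, 200 + middle_len)
    e3 = (e2[1] + 101, e2[1] + 160)
    return TranscriptModel(
        "TXC", "G", "chrC", "+",
        exons=((101, 160), e2, e3),
        cds=((101, 160), e2, e3),
    )


def _cds_genome(tx: TranscriptModel, rng: np.random.Generator) -> dict[str, str]:
    from splicetarget.fixtures import _plant_cds

    n = tx.span()[1] + 50
    seq = ["ACGT"[i] for i in rng.integers(0, 4, n)]
    total = sum(hi - lo + 1 for lo, hi in tx.cds)
    if total % 3 == 0:
        _plant_cds(seq, rng, tx.cds, tx.strand)
    return {tx.chrom: "".join(seq)}


class TestModifyCds:
    def test_in_frame_exon_skip(self, rng):
        tx = _cds_only_transcript(99)
        genome = _cds_genome(tx, rng)
        junction = parse_junction_id("chrC:160-400:+", "ES")
        mod = modify_cds(junction, tx, genome)
        assert mod is not None
        assert not mod.frameshift
        assert mod.junc_pos_in_cds == 60
        assert len(mod.wildtype_cds_seq) - len(mod.modified_cds_seq) == 99

    def test_frameshift_exon_skip(self, rng):
        tx = _cds_only_transcript(100)
        genome = _cds_genome(tx, rng)
        junction = parse_junction_id("chrC:160-401:+", "ES")
        mod = modify_cds(junction, tx, genome)
        assert mod is not None
        assert mod.frameshift

    def test_utr_only_junction_returns_none(self, rng):
        tx = TranscriptModel(
            "TXU", "G", "chrC", "+",
            exons=((101, 200), (301, 400), (501, 600)),
            cds=((101, 200), (301, 350)),  # exon 3 is pure 3'UTR
        )
        genome = _cds_genome(tx, rng)
        junction = parse_junction_id("chrC:520-560:+", "A5SS")
        assert modify_cds(junction, tx, genome) is None

    def test_no_cds_returns_none(self, tx1_minus, genome):
        junction = parse_junction_id("chrT:200-501:-", "ES")
        assert modify_cds(junction, tx1_minus, genome) is None

    def test_ir_junction_not_translated(self, tx1, genome):
        junction = parse_junction_id("chrT:400-401:+", "IR")
        assert modify_cds(junction, tx1, genome) is None

    def test_frameshift_law_on_random_junctions(self):
        """frameshift <=> CDS length difference not a multiple of three."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 1000:
            middle = int(rng.integers(30, 130))
            tx = _cds_only_transcript(middle)
            genome = _cds_genome(tx, rng)
            # junction with both anchors exonic, strictly inside the CDS
            anchors = sorted(rng.choice(
                [p for lo, hi in tx.exons for p in range(lo, hi + 1)],
                size=2, replace=False,
            ))
            start, end = int(anchors[0]), int(anchors[1])
            if end - start < 2:
                continue
            junction = parse_junction_id(f"chrC:{start}-{end}:+")
            mod = modify_cds(junction, tx, genome)
            wt_len, mod_len = excised_cds_length(list(tx.cds), start, end)
            if mod is None:
                assert wt_len == mod_len
                continue
            assert mod.frameshift == ((mod_len - wt_len) % 3 != 0)
            checked += 1


class TestTranslateCds:
    def test_standard_code(self):
        assert translate_cds("ATGGCTTAA") == ("MA", False)

    def test_missing_stop_flagged(self):
        assert translate_cds("ATGGCT") == ("MA", True)

    def test_non_acgt_rejected(self):
        with pytest.raises(SpliceTargetError):
            translate_cds("ATGNNN")


class TestPeptideContext:
    def test_clean_in_frame_skip_gives_26mer(self):
        wt = "M" + "A" * 50 + "W" + "C" * 50
        mut = "M" + "A" * 19 + "C" * 50  # skip removes 31 wt residues at codon 20
        pep = extract_peptide_context(wt, mut, junc_pos_in_cds=60, frameshift=False)
        assert pep is not None
        assert len(pep.mutated_peptide) == 26
        assert pep.junction_aa_pos == 20
        assert pep.reading_frame_offset == 0
        assert pep.mutated_peptide == mut[7:33]

    def test_frameshift_runs_to_stop(self):
        wt = "M" + "A" * 40
        mut = "M" + "A" * 19 + "V" * 40  # novel C-terminus of 40 residues
        pep = extract_peptide_context(wt, mut, junc_pos_in_cds=60, frameshift=True)
        assert pep is not None
        assert len(pep.mutated_peptide) == 13 + 40
        assert pep.frameshift

    def test_truncated_wildtype_returns_none(self):
        wt = "MAAAAWCCCC"
        assert extract_peptide_context(wt, wt[:6], 18, False) is None
        assert extract_peptide_context(wt, wt, 18, False) is None

    def test_full_pipeline_in_frame_skip(self, rng):
        tx = _cds_only_transcript(99)
        genome = _cds_genome(tx, rng)
        junction = parse_junction_id("chrC:160-400:+", "ES")
        pep = annotate_peptide(junction, tx, genome)
        if pep is not None:  # chimeric junction codon may rarely hit a stop
            assert not pep.frameshift
            assert len(pep.mutated_peptide) <= 26
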