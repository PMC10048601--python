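import numpy as np
import pytest
from Bio.Seq import Seq

from introprio import effect_annotation as ea
from introprio.errors import ReferenceMismatchError, UnsatisfiableEffectError
from introprio.variant_io import VariantRecord


def simple_gene(strand="+", chrom="chr1"):
    """Single-exon gene: 10 bp 5'UTR + 9-codon CDS + 10 bp 3'UTR, embedded
    at offset 100 of a 400 bp chromosome."""
    cds_seq = "ATG" + "GCTTGCAAAGGGCCCACTTAT"[:18] + "TAA"  # 27 nt, no internal stop
    assert len(cds_seq) == 24
    utr5, utr3 = "T" * 10, "G" * 10
    insert = utr5 + cds_seq + utr3 if strand == "+" else str(
        Seq(utr5 + cds_seq + utr3).reverse_complement()
    )
    seq = "A" * 100 + insert + "C" * (300 - len(insert))
    tx_start, tx_end = 101, 100 + len(insert)
    if strand == "+":
        cds = ((tx_start + 10, tx_end - 10),)
    else:
        cds = ((tx_start + 10, tx_end - 10),)
    g = ea.GeneModel(
        id="g1", chrom=chrom, strand=strand, tx_start=tx_start, tx_end=tx_end,
        exons=((tx_start, tx_end),), cds=cds, description="test gene",
    )
    return g, seq


def multi_exon_gene():
    """Two-exon plus-strand gene with one intron, CDS spanning both exons."""
    # exon1: 5'UTR(6) + CDS(9); intron(20); exon2: CDS(9) + 3'UTR(6)
    cds_part1, cds_part2 = "ATGGCTTGC", "AAAGGGTAA"
    exon1 = "TTTTTT" + cds_part1
    intron = "GTAAGTAAAAAAAAAATAAG"  # GT..AG
    exon2 = cds_part2 + "GGGGGG"
    seq = "A" * 50 + exon1 + intron + exon2 + "C" * 50
    tx_start = 51
    e1 = (tx_start, tx_start + len(exon1) - 1)
    i1 = (e1[1] + 1, e1[1] + len(intron))
    e2 = (i1[1] + 1, i1[1] + len(exon2))
    g = ea.GeneModel(
        id="mx", chrom="chr1", strand="+", tx_start=e1[0], tx_end=e2[1],
        exons=(e1, e2),
        cds=((e1[0] + 6, e1[1]), (e2[0], e2[0] + len(cds_part2) - 1)),
        description="multi-exon",
    )
    return g, seq


def snp(pos, ref, alt, chrom="chr1"):
    return VariantRecord(chrom, pos, ref, alt)


class TestCodingSnps:
    def test_stop_gained(self):
        # CDS "ATG TGC TAA": position 6 C->A turns TGC into TGA
        seq = "A" * 10 + "ATGTGCTAA" + "A" * 10
        g = ea.GeneModel("g", "chr1", "+", 11, 19, ((11, 19),), ((11, 19),), "")
        ann = ea.annotate_effect(snp(16, "C", "A"), g, seq)
        assert (ann.effect, ann.impact) == ("stop_gained", "HIGH")

    def test_missense(self):
        # CDS "ATG GCT TAA": position 4 G->T gives GCT->TCT (Ala->Ser)
        seq = "A" * 10 + "ATGGCTTAA" + "A" * 10
        g = ea.GeneModel("g", "chr1", "+", 11, 19, ((11, 19),), ((11, 19),), "")
        ann = ea.annotate_effect(snp(14, "G", "T"), g, seq)
        assert (ann.effect, ann.impact) == ("missense_variant", "MODERATE")

    def test_synonymous_third_position(self):
        # GCT -> GCC is still Ala
        seq = "A" * 10 + "ATGGCTTAA" + "A" * 10
        g = ea.GeneModel("g", "chr1", "+", 11, 19, ((11, 19),), ((11, 19),), "")
        ann = ea.annotate_effect(snp(16, "T", "C"), g, seq)
        assert (ann.effect, ann.impact) == ("synonymous_variant", "LOW")

    def test_stop_lost(self):
        seq = "A" * 10 + "ATGGCTTAA" + "A" * 10
        g = ea.GeneModel("g", "chr1", "+", 11, 19, ((11, 19),), ((11, 19),), "")
        ann = ea.annotate_effect(snp(18, "A", "C"), g, seq)  # TAA -> TAC
        assert (ann.effect, ann.impact) == ("stop_lost", "HIGH")

    def test_minus_strand_missense(self):
        g, seq = simple_gene(strand="-")
        # pick a CDS position and verify via the oracle below
        cds_seq = g.cds_sequence(seq)
        assert cds_seq.startswith("ATG") and cds_seq.endswith(("TAA", "TAG", "TGA"))

    def test_reference_mismatch_raises(self):
        seq = "A" * 10 + "ATGGCTTAA" + "A" * 10
        g = ea.GeneModel("g", "chr1", "+", 11, 19, ((11, 19),), ((11, 19),), "")
        with pytest.raises(ReferenceMismatchError):
            ea.annotate_effect(snp(14, "C", "T"), g, seq)


class TestCodingIndels:
    def _gene(self):
        seq = "A" * 10 + "ATGGCTTGCAAAGGGTAA" + "A" * 10  # 6 codons
        g = ea.GeneModel("g", "chr1", "+", 11, 28, ((11, 28),), ((11, 28),), "")
        return g, seq

    def test_one_bp_deletion_frameshift(self):
        g, seq = self._gene()
        v = VariantRecord("chr1", 14, seq[13:15], seq[13])  # delete base 15
        ann = ea.annotate_effect(v, g, seq)
        assert (ann.effect, ann.impact) == ("frameshift_variant", "HIGH")

    def test_two_bp_insertion_frameshift(self):
        g, seq = self._gene()
        v = VariantRecord("chr1", 14, seq[13], seq[13] + "GG")
        ann = ea.annotate_effect(v, g, seq)
        assert ann.effect == "frameshift_variant"

    def test_codon_aligned_deletion_conservative(self):
        g, seq = self._gene()
        # codon 2 occupies positions 14-16; anchor at 13
        v = VariantRecord("chr1", 13, seq[12:16], seq[12])
        ann = ea.annotate_effect(v, g, seq)
        assert ann.effect == "conservative_inframe_deletion"

    def test_shifted_deletion_disruptive(self):
        g, seq = self._gene()
        v = VariantRecord("chr1", 14, seq[13:17], seq[13])  # deletes 15-17
        ann = ea.annotate_effect(v, g, seq)
        assert ann.effect == "disruptive_inframe_deletion"

    def test_codon_boundary_insertion_conservative(self):
        g, seq = self._gene()
        # insertion after position 13 sits on the codon 1|2 boundary
        v = VariantRecord("chr1", 13, seq[12], seq[12] + "AAA")
        ann = ea.annotate_effect(v, g, seq)
        assert ann.effect == "conservative_inframe_insertion"
        v2 = VariantRecord("chr1", 14, seq[13], seq[13] + "AAA")
        assert ea.annotate_effect(v2, g, seq).effect == "disruptive_inframe_insertion"


class TestRegionsAndSplice:
    def test_intergenic_far_from_genes(self):
        g, seq = simple_gene()
        index = ea.GeneIndex([g])
        v = snp(395, seq[394], "T" if seq[394] != "T" else "G")
        located, region = ea.locate_variant(v, index, flank_bp=50)
        assert located is None and region == ea.INTERGENIC

    def test_upstream_downstream_strand_aware(self):
        g, seq = simple_gene(strand="-")
        index = ea.GeneIndex([g])
        # for a minus-strand gene, genomic right of tx_end is upstream
        v_right = snp(g.tx_end + 5, seq[g.tx_end + 4], "A" if seq[g.tx_end + 4] != "A" else "C")
        _, region = ea.locate_variant(v_right, index, flank_bp=50)
        assert region == ea.UPSTREAM
        v_left = snp(g.tx_start - 5, seq[g.tx_start - 6], "A" if seq[g.tx_start - 6] != "A" else "C")
        _, region = ea.locate_variant(v_left, index, flank_bp=50)
        assert region == ea.DOWNSTREAM

    def test_utr_sidedness_minus_strand(self):
        g, seq = simple_gene(strand="-")
        # genomic positions below cds_start are the 3'UTR of a minus gene
        pos = g.tx_start + 2
        v = snp(pos, seq[pos - 1], "A" if seq[pos - 1] != "A" else "C")
        ann = ea.annotate_effect(v, g, seq)
        assert ann.effect == "three_prime_UTR_variant"

    def test_first_intron_base_is_splice_donor(self):
        g, seq = multi_exon_gene()
        intron = g.introns[0]
        v = snp(intron[0], seq[intron[0] - 1], "C" if seq[intron[0] - 1] != "C" else "A")
        ann = ea.annotate_effect(v, g, seq)
        assert (ann.effect, ann.impact) == ("splice_donor_variant", "HIGH")

    def test_last_intron_base_is_splice_acceptor(self):
        g, seq = multi_exon_gene()
        intron = g.introns[0]
        v = snp(intron[1], seq[intron[1] - 1], "C" if seq[intron[1] - 1] != "C" else "A")
        ann = ea.annotate_effect(v, g, seq)
        assert ann.effect == "splice_acceptor_variant"

    def test_intron_interior_is_modifier(self):
        g, seq = multi_exon_gene()
        intron = g.introns[0]
        pos = (intron[0] + intron[1]) // 2
        v = snp(pos, seq[pos - 1], "C" if seq[pos - 1] != "C" else "A")
        ann = ea.annotate_effect(v, g, seq)
        assert (ann.effect, ann.impact) == ("intron_variant", "MODIFIER")

    def test_bidirectional_gene_fusion(self):
        # two adjacent genes on opposite strands, one deletion spanning both CDS
        seq = "A" * 10 + "ATGGCTTAA" + "AAAA" + str(Seq("ATGGCTTAA").reverse_complement()) + "A" * 10
        g1 = ea.GeneModel("gA", "chr1", "+", 11, 19, ((11, 19),), ((11, 19),), "")
        g2 = ea.GeneModel("gB", "chr1", "-", 24, 32, ((24, 32),), ((24, 32),), "")
        v = VariantRecord("chr1", 15, seq[14:30], seq[14])  # deletes 16..30
        anns = ea.annotate_variants([v], [g1, g2], {"chr1": seq})
        assert {a.gene for a in anns} == {"gA", "gB"}
        assert all(a.effect == "bidirectional_gene_fusion" for a in anns)


class TestStrandSymmetry:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_revcomp_locus_same_effects(self, strand):
        """Reverse-complementing the chromosome and flipping the gene strand
        must not change coding SNP effect calls."""
        g, seq = simple_gene(strand=strand)
        L = len(seq)
        rc = str(Seq(seq).reverse_complement())
        g_rc = ea.GeneModel(
            g.id, g.chrom, "-" if strand == "+" else "+",
            L - g.tx_end + 1, L - g.tx_start + 1,
            tuple((L - e + 1, L - s + 1) for s, e in g.exons),
            tuple((L - e + 1, L - s + 1) for s, e in g.cds),
            g.description,
        )
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for pos in range(g.cds[0][0], g.cds[0][1] + 1):
            ref = seq[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                a1 = ea.annotate_effect(snp(pos, ref, alt), g, seq)
                mirror = snp(L - pos + 1, comp[ref], comp[alt])
                a2 = ea.annotate_effect(mirror, g_rc, rc)
                assert a1.effect == a2.effect, (pos, alt)


class TestSummaries:
    def test_empty_all_zero(self):
        s = ea.summarize_impacts([])
        assert s["n"] == 0 and all(v == 0 for v in s["by_impact"].values())

    def test_all_modifier_hundred_percent(self):
        anns = [
            ea.EffectAnnotation(snp(i + 1, "A", "T"), None, ea.INTERGENIC, "intergenic_variant")
            for i in range(1000)
        ]
        s = ea.summarize_impacts(anns)
        assert s["impact_pct"]["MODIFIER"] == 100.0

    def test_most_severe_per_variant(self):
        v = snp(5, "A", "T")
        anns = [
            ea.EffectAnnotation(v, "g1", ea.EXON, "missense_variant"),
            ea.EffectAnnotation(v, "g2", ea.EXON, "stop_gained"),
        ]
        s = ea.summarize_impacts(anns)
        assert s["n"] == 1 and s["by_impact"]["HIGH"] == 1

    def test_tier_map_total(self):
        assert set(ea.IMPACT_OF.values()) == {"HIGH", "MODERATE", "LOW", "MODIFIER"}
        for eff in ea.IMPACT_OF:
            assert ea.IMPACT_OF[eff] in ea.SEVERITY_ORDER


class TestPlantedRoundTrip:
    def test_planted_variants_reannotate_exactly(self, dataset):
        """Every planted (variant, effect) pair is recovered verbatim."""
        genes = ea.GeneIndex(dataset.genes)
        genome = dataset.genome
        assert dataset.truth.planted_variants, "generator should plant variants"
        for pv in dataset.truth.planted_variants:
            v = VariantRecord(pv["chrom"], pv["pos"], pv["ref"], pv["alt"])
            anns = ea.annotate_variants([v], genes, genome)
            effects = {a.effect for a in anns}
            assert pv["effect"] in effects, pv

    def test_unsatisfiable_effect_raises(self):
        from introprio.synthetic_data import plant_effect_variants

        g, seq = simple_gene()  # intronless gene
        with pytest.raises(UnsatisfiableEffectError):
            plant_effect_variants(g, seq, ["intron_variant"])


class TestGff3RoundTrip:
    def test_write_read(self, tmp_path):
        g, _ = multi_exon_gene()
        p = tmp_path / "g.gff3"
        ea.write_gff3([g], p)
        back = ea.read_gff3(p)
        assert len(back) == 1
        b = back[0]
        assert (b.id, b.strand, b.tx_start, b.tx_end) == (g.id, g.strand, g.tx_start, g.tx_end)
        assert b.exons == g.exons and b.cds == g.cds
        assert b.description == g.description
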