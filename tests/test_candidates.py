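import pytest

from introprio import candidate_prioritization as cp
from introprio import effect_annotation as ea
from introprio.density_regions import PolymorphicRegion
from introprio.errors import NamespaceError
from introprio.variant_io import VariantRecord


def gene(gid, desc, chrom="chr1", start=1000, end=2000):
    return ea.GeneModel(gid, chrom, "+", start, end, ((start, end),), (), desc)


def qtl(qid, chrom, start, end, trait_class="flower number"):
    return cp.QTLInterval(qid, trait_class, trait_class, chrom, start, end)


def ann(g, effect, pos=1500, chrom="chr1"):
    return ea.EffectAnnotation(VariantRecord(chrom, pos, "A", "T"), g, ea.EXON, effect)


class TestKeywordSelect:
    def test_hsp_description_joins_heat(self):
        heat, rep = cp.keyword_select([gene("a", "Heat shock protein 70 kDa")])
        assert [g.id for g in heat] == ["a"] and rep == []
        assert cp.heat_subcategory("Heat shock protein 70 kDa") == "HSP"

    def test_pollen_receptor_joins_reproduction(self):
        heat, rep = cp.keyword_select([gene("a", "Pollen receptor-like kinase 3")])
        assert heat == [] and [g.id for g in rep] == ["a"]
        assert cp.reproduction_subcategory("Pollen receptor-like kinase 3") == "pollen"

    def test_neutral_joins_neither(self):
        heat, rep = cp.keyword_select([gene("a", "Ubiquitin ligase")])
        assert heat == [] and rep == []

    def test_case_insensitive(self):
        heat, rep = cp.keyword_select([gene("a", "FlowERING LOCUS D")])
        assert [g.id for g in rep] == ["a"]

    def test_dnaj_needs_extended_keywords(self):
        g = gene("a", "Chaperone protein DnaJ")
        assert cp.keyword_select([g])[0] == []
        assert [x.id for x in cp.keyword_select([g], cp.EXTENDED_KEYWORDS)[0]] == ["a"]

    def test_hsf_subcategory(self):
        assert cp.heat_subcategory("Heat stress transcription factor A-5") == "HSF"


class TestColocalize:
    def test_overlap_and_touching(self):
        g = gene("a", "x", start=100, end=200)
        assert cp.colocalize([g], [qtl("q1", "chr1", 150, 500)])["a"]
        assert not cp.colocalize([g], [qtl("q2", "chr1", 201, 500)])["a"]
        assert cp.colocalize([g], [qtl("q3", "chr1", 200, 500)])["a"]

    def test_namespace_mismatch_raises(self):
        g = gene("a", "x", chrom="chr1")
        with pytest.raises(NamespaceError):
            cp.colocalize([g], [qtl("q1", "SL4.0ch01", 1, 10_000)])


class TestPrioritize:
    def setup_method(self):
        self.region = PolymorphicRegion("p1_1", "chr1", 1, 5000, 100, 10, "snp")
        self.g_heat = gene("h1", "Heat shock protein", start=1000, end=2000)
        self.g_rep = gene("r1", "Flowering locus T", chrom="chr2", start=1000, end=2000)

    def test_low_only_excluded(self):
        anns = [ann("h1", "synonymous_variant")]
        out = cp.prioritize([self.g_heat], [], anns, [self.region], [])
        assert out == []

    def test_qtl_route_without_region(self):
        anns = [ann("r1", "stop_gained", chrom="chr2")]
        out = cp.prioritize([], [self.g_rep], anns, [self.region], [qtl("q1", "chr2", 1, 5000)])
        assert len(out) == 1
        c = out[0]
        assert c.region_label is None and c.qtl_ids == ("q1",) and c.high_n == 1

    def test_non_flower_qtl_does_not_select(self):
        anns = [ann("r1", "stop_gained", chrom="chr2")]
        out = cp.prioritize(
            [], [self.g_rep], anns, [], [qtl("q1", "chr2", 1, 5000, trait_class="fruit set")]
        )
        assert out == []
        strict = cp.prioritize(
            [], [self.g_rep], anns, [], [qtl("q1", "chr2", 1, 5000, trait_class="fruit set")],
            flower_trait_classes={"fruit set"},
        )
        assert len(strict) == 1

    def test_unlisted_gene_excluded(self):
        anns = [ann("h1", "stop_gained")]
        out = cp.prioritize([], [], anns, [self.region], [])
        assert out == []

    def test_selection_monotonicity(self):
        anns = [ann("h1", "missense_variant"), ann("r1", "missense_variant", chrom="chr2")]
        base = cp.prioritize([self.g_heat], [self.g_rep], anns, [self.region], [])
        more = cp.prioritize(
            [self.g_heat], [self.g_rep], anns, [self.region], [qtl("q1", "chr2", 1, 5000)]
        )
        assert {c.gene for c in base} <= {c.gene for c in more}
        fewer = cp.prioritize([self.g_heat], [], anns, [self.region], [])
        assert {c.gene for c in fewer} <= {c.gene for c in base}

    def test_every_selected_gene_has_a_route(self):
        anns = [ann("h1", "missense_variant"), ann("r1", "stop_gained", chrom="chr2")]
        out = cp.prioritize(
            [self.g_heat], [self.g_rep], anns, [self.region], [qtl("q1", "chr2", 1, 5000)]
        )
        for c in out:
            assert c.region_label is not None or c.qtl_ids

    def test_synthetic_truth_equality(self, dataset):
        """Selection on simulated data reproduces the generator's intent."""
        truth = dataset.truth
        regions = [
            PolymorphicRegion(f"p{i+1}", s["chrom"], s["start"], s["end"], 0, 0, "snp")
            for i, s in enumerate(truth.segments)
        ]
        genome = dataset.genome
        genes = dataset.genes
        anns = ea.annotate_variants(
            [VariantRecord(*k) for k in _focal_keys(dataset)], ea.GeneIndex(genes), genome
        )
        heat, rep = cp.keyword_select(genes, cp.EXTENDED_KEYWORDS)
        qtls = cp.read_qtl_tsv(dataset.qtl_tsv)
        out = cp.prioritize(heat, rep, anns, regions, qtls)
        assert {c.gene for c in out} == set(truth.intended_candidates)
        assert set(truth.planted_candidates) <= {c.gene for c in out}


def _focal_keys(dataset):
    from introprio.variant_io import read_variants

    return [v.key for v in read_variants(dataset.focal_vcf)]


class TestSummaries:
    def test_empty(self):
        s = cp.summarize_candidates([])
        assert s["total_genes"] == 0 and s["distinct_regions"] == 0

    def test_permutation_invariant(self):
        cands = cp.candidates_from_table(cp.load_candidate_table())
        s1 = cp.summarize_candidates(cands)
        s2 = cp.summarize_candidates(list(reversed(cands)))
        assert s1 == s2


class TestPublishedTableFixture:
    def test_candidate_table_summary(self):
        cands = cp.candidates_from_table(cp.load_candidate_table())
        s = cp.summarize_candidates(cands)
        assert s["total_genes"] == 35
        assert s["distinct_regions"] == 13
        assert s["genes_with_high"] == 7
        assert s["by_list"] == {"heat": 24, "reproduction": 11}
        assert s["by_subcategory"] == {"HSP": 23, "HSF": 1, "flower": 6, "pollen": 5}

    def test_qtl_trait_counts(self):
        df = cp.load_qtl_class_counts()
        assert int(df.qtl_n.sum()) == 86
        assert int(df.loc[df.trait.str.lower() == "flowering time", "qtl_n"].iloc[0]) == 20
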