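"""Allele assembly, frequency tables and dataset summaries."""

import pytest

from allelecat.catalog_builder import (
    assemble_alleles,
    assign_variants_to_genes,
    build_frequency_table,
    genotype_state,
    GenePosition,
    GeneVariantSet,
)
from allelecat.effect_annotation import AnnotatedVariant, EffectCall, classify_severity
from allelecat.io_formats import CategorySpec, ConfigError, SampleMetadata, VariantRecord


def _call(term, gene_id="g1"):
    sev, color = classify_severity(term)
    return EffectCall(gene_id, f"{gene_id}.t1", term, "X1X", sev, color)


def _record(pos, genotypes, ref="A", alts=("G",)):
    return VariantRecord(
        "chr1", pos, ref, tuple(alts), list(genotypes), [False] * len(genotypes)
    )


def _gene_set(records, terms):
    positions = [
        GenePosition(r.chrom, r.pos, r.ref_seq, r, {1: _call(t)})
        for r, t in zip(records, terms)
    ]
    return GeneVariantSet("g1", positions)


class TestGenotypeState:
    def test_homozygous_renders_single_sequence(self):
        rec = _record(10, [(0, 0), (1, 1)])
        assert genotype_state(rec, 0) == "A"
        assert genotype_state(rec, 1) == "G"

    def test_heterozygous_sorted_by_allele_index(self):
        rec = _record(10, [(1, 0)], alts=("G",))
        assert genotype_state(rec, 0) == "A/G"

    def test_multiallelic_states_distinguish_alts(self):
        rec = _record(10, [(1, 1), (2, 2), (1, 2)], alts=("G", "T"))
        assert [genotype_state(rec, i) for i in range(3)] == ["G", "T", "G/T"]

    def test_missing_genotype_is_an_error(self):
        rec = VariantRecord("chr1", 10, "A", ("G",), [None], [True])
        with pytest.raises(ValueError, match="impute"):
            genotype_state(rec, 0)


class TestAssignVariantsToGenes:
    def test_only_modifying_effects_are_collated(self):
        from allelecat.io_formats import GeneModel, Transcript

        gene = GeneModel(
            "g1", "chr1", 1, 100, "+",
            (Transcript("g1.t1", ((1, 100),), ((1, 100, 0),)),),
        )
        missense = _record(10, [(0, 0)])
        synonymous = _record(20, [(0, 0)])
        splice = _record(30, [(0, 0)])
        annotated = [
            AnnotatedVariant(missense, {("g1", 1): _call("missense_variant")}),
            AnnotatedVariant(synonymous, {("g1", 1): _call("synonymous_variant")}),
            AnnotatedVariant(splice, {("g1", 1): _call("splice_donor_variant")}),
        ]
        sets = assign_variants_to_genes(annotated, [gene])
        assert [p.pos for p in sets["g1"].positions] == [10, 30]


class TestAssembleAlleles:
    def test_hand_enumerated_partition(self):
        # accessions a,b,c over two positions: a=(ref,ref), b=(alt,ref), c=(ref,ref)
        r1 = _record(10, [(0, 0), (1, 1), (0, 0)])
        r2 = _record(20, [(0, 0), (0, 0), (0, 0)], ref="C", alts=("T",))
        alleles = assemble_alleles(_gene_set([r1, r2], ["missense_variant"] * 2), "abc")
        assert [(a.state_vector, a.total) for a in alleles] == [
            (("A", "C"), 2),
            (("G", "C"), 1),
        ]
        assert alleles[0].carriers == ("a", "c")

    def test_zero_positions_yields_single_reference_allele(self):
        alleles = assemble_alleles(GeneVariantSet("g1", []), ["a", "b", "c", "d", "e"])
        (allele,) = alleles
        assert allele.state_vector == () and allele.total == 5

    def test_order_is_total_descending(self):
        # 3 alt carriers vs 2 reference carriers: alt allele listed first
        r = _record(10, [(1, 1), (1, 1), (1, 1), (0, 0), (0, 0)])
        alleles = assemble_alleles(_gene_set([r], ["missense_variant"]), "abcde")
        assert [a.total for a in alleles] == [3, 2]
        assert alleles[0].state_vector == ("G",)

    def test_effects_attached_only_to_alternate_states(self):
        r = _record(10, [(1, 1), (0, 0)])
        alleles = assemble_alleles(_gene_set([r], ["missense_variant"]), "ab")
        by_state = {a.state_vector[0]: a for a in alleles}
        assert by_state["G"].effects[0].effect_term == "missense_variant"
        assert by_state["A"].effects[0] is None

    def test_deterministic_tiebreak(self):
        r = _record(10, [(1, 1), (0, 0)])
        first = assemble_alleles(_gene_set([r], ["missense_variant"]), "ab")
        second = assemble_alleles(_gene_set([r], ["missense_variant"]), "ab")
        assert [a.state_vector for a in first] == [a.state_vector for a in second]


SPEC = CategorySpec(
    category_column="Improvement Status",
    values=("G. soja", "Landrace", "Elite"),
    flag_columns={"Cultivar": ("Yes",)},
)


def _metadata(**statuses):
    out = {}
    for acc, (status, cultivar) in statuses.items():
        out[acc] = SampleMetadata(
            acc, {"Improvement Status": status, "Cultivar": cultivar}, {}
        )
    return out


class TestFrequencyTable:
    def test_uncategorized_count_only_in_total(self):
        # 5 G. soja + 2 uncategorized carriers -> (5, 0, 0, Total 7)
        carriers = tuple(f"s{i}" for i in range(5)) + ("u1", "u2")
        r = _record(10, [(1, 1)] * 7)
        gs = _gene_set([r], ["missense_variant"])
        alleles = assemble_alleles(gs, carriers)
        md = _metadata(**{f"s{i}": ("G. soja", "No") for i in range(5)})
        table = build_frequency_table(alleles, md, SPEC)
        (row,) = table.rows
        assert row.counts == {"G. soja": 5, "Landrace": 0, "Elite": 0}
        assert row.total == 7

    def test_empty_spec_gives_total_only(self):
        r = _record(10, [(1, 1), (0, 0)])
        alleles = assemble_alleles(_gene_set([r], ["missense_variant"]), "ab")
        table = build_frequency_table(alleles, {}, CategorySpec())
        assert table.columns == ("Total",)
        assert [row.total for row in table.rows] == [1, 1]

    def test_cultivar_flag_overlaps_elite(self):
        r = _record(10, [(1, 1), (1, 1)])
        alleles = assemble_alleles(_gene_set([r], ["missense_variant"]), ("e1", "e2"))
        md = _metadata(e1=("Elite", "Yes"), e2=("Elite", "No"))
        table = build_frequency_table(alleles, md, SPEC)
        (row,) = table.rows
        assert row.counts["Elite"] == 2 and row.flag_counts["Cultivar"] == 1

    def test_unknown_category_column_is_config_error(self):
        r = _record(10, [(1, 1)])
        alleles = assemble_alleles(_gene_set([r], ["missense_variant"]), ("x",))
        md = {"x": SampleMetadata("x", {"Other": "v"}, {})}
        with pytest.raises(ConfigError):
            build_frequency_table(alleles, md, SPEC)


class TestPanelInvariants:
    def test_partition_conservation(self, panel):
        n = len(panel.accessions)
        for gid, alleles in panel.catalog.alleles.items():
            assert sum(a.total for a in alleles) == n
            carriers = sorted(acc for a in alleles for acc in a.carriers)
            assert carriers == sorted(panel.accessions)

    def test_category_counts_sum_to_category_sizes(self, panel):
        spec = panel.catalog.category_spec
        md = panel.catalog.metadata
        sizes = {
            v: sum(
                1
                for m in md.values()
                if m.categories.get(spec.category_column) == v
            )
            for v in spec.values
        }
        for table in panel.catalog.tables.values():
            for v in spec.values:
                assert sum(r.counts[v] for r in table.rows) == sizes[v]

    def test_at_most_one_reference_allele_per_gene(self, panel):
        for gid, alleles in panel.catalog.alleles.items():
            refs = [
                a
                for a in alleles
                if a.state_vector
                == tuple(p.ref_seq for p in panel.catalog.gene_sets[gid].positions)
            ]
            assert len(refs) <= 1

    def test_rows_ordered_by_total_nonincreasing(self, panel):
        for table in panel.catalog.tables.values():
            totals = [r.total for r in table.rows]
            assert totals == sorted(totals, reverse=True)

    def test_summary_matches_planted_truth(self, panel):
        expected = panel.manifest.summary
        actual = panel.catalog.summary.to_dict()
        for key, value in expected.items():
            assert actual[key] == pytest.approx(value)

    def test_repeat_build_is_byte_identical(self, panel):
        from allelecat.catalog_builder import build_catalog

        again = build_catalog(
            panel.genome, panel.genes, panel.records, panel.accessions,
            panel.metadata, panel.category_spec,
        )
        for gid in panel.catalog.tables:
            assert panel.catalog.tables[gid].to_tsv() == again.tables[gid].to_tsv()
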