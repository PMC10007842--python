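"""Effect classification against hand-derived and brute-force expectations.

The toy gene on chr1 carries CDS ATG ACT GGG TTG TAA (protein MTGL*), so
every expected call below is derivable by hand from the codon table.
"""

import pytest

from allelecat.effect_annotation import (
    EFFECT_TERMS,
    NoCodingTranscript,
    aa_change_notation,
    annotate_variant,
    classify_severity,
    effects_from_ann,
    extract_cds,
    primary_transcript,
    reverse_complement,
    translate,
)
from allelecat.io_formats import GeneModel, GenomeSequence, Transcript, VariantRecord

from conftest import TOY_CHROM
from oracle import oracle_effect


def _variant(chrom, pos, ref, alt):
    return VariantRecord(chrom, pos, ref, (alt,), [(1, 1)], [False])


class TestPrimaryTranscript:
    def test_longest_cds_wins(self):
        t1 = Transcript("t1", ((1, 300),), ((1, 300, 0),))
        t2 = Transcript("t2", ((1, 450),), ((1, 450, 0),))
        gene = GeneModel("g", "c", 1, 450, "+", (t1, t2))
        assert primary_transcript(gene) == "t2"

    def test_tie_breaks_to_smallest_id(self):
        t1 = Transcript("t1", ((1, 300),), ((1, 300, 0),))
        t2 = Transcript("t2", ((1, 300),), ((1, 300, 0),))
        gene = GeneModel("g", "c", 1, 300, "+", (t2, t1))
        assert primary_transcript(gene) == "t1"

    def test_no_cds_signals(self):
        gene = GeneModel("g", "c", 1, 30, "+", (Transcript("t1", ((1, 30),), ()),))
        with pytest.raises(NoCodingTranscript):
            primary_transcript(gene)


class TestExtractCds:
    def test_plus_strand_slice(self, toy_genome, toy_gene):
        assert extract_cds(toy_genome, toy_gene, "gA.t1") == "ATGACTGGGTTGTAA"

    def test_minus_strand_is_reverse_complement(self, toy_genome):
        # independent oracle: reverse-complement of the plus-strand slice
        from Bio.Seq import Seq

        tx = Transcript("gM.t1", ((11, 25),), ((11, 25, 0),))
        gene = GeneModel("gM", "chr1", 11, 25, "-", (tx,))
        expected = str(Seq(TOY_CHROM[10:25]).reverse_complement())
        assert extract_cds(toy_genome, gene, "gM.t1") == expected == "TTACAACCCAGTCAT"

    def test_two_segment_concatenation(self, toy_genome, toy_two_exon_gene):
        assert extract_cds(toy_genome, toy_two_exon_gene, "gB.t1") == "ATGACTGGGTTGTAA"

    def test_out_of_bounds_segment(self, toy_genome):
        tx = Transcript("t", ((11, 500),), ((11, 500, 0),))
        gene = GeneModel("g", "chr1", 11, 500, "+", (tx,))
        with pytest.raises(ValueError):
            extract_cds(toy_genome, gene, "t")


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,protein",
        [
            ("ATGACTGGGTTGTAA", "MTGL*"),  # manual codon-table translation
            ("ATG", "M"),
            ("ATGNNN", "MX"),
            ("ATGTAAACT", "M*"),  # stops at the first stop codon
            ("ATGAC", "M"),  # trailing incomplete codon ignored
        ],
    )
    def test_examples(self, cds, protein):
        assert translate(cds) == protein


class TestAnnotateVariant:
    """Expected values derived with the apply-and-retranslate oracle."""

    @pytest.mark.parametrize(
        "pos,ref,alt,term,aa",
        [
            (14, "A", "G", "missense_variant", "T2A"),  # ACT->GCT
            (21, "T", "A", "stop_gained", "L4*"),  # TTG->TAG
            (14, "AC", "A", "frameshift_variant", "T2fs"),  # 1-base CDS deletion
            (16, "T", "C", "synonymous_variant", ""),  # ACT->ACC, still Thr
            (12, "T", "G", "start_lost", "M1?"),  # ATG->AGG
            (3, "C", "G", "non_coding_or_other", ""),  # upstream of the gene
        ],
    )
    def test_toy_gene_calls(self, toy_genome, toy_gene, pos, ref, alt, term, aa):
        call = annotate_variant(_variant("chr1", pos, ref, alt), 1, toy_gene, toy_genome)
        assert (call.effect_term, call.aa_notation) == (term, aa)
        assert oracle_effect(toy_genome, toy_gene, _variant("chr1", pos, ref, alt), 1) == (
            term,
            aa,
        )

    def test_splice_donor_at_first_intron_base(self, toy_genome, toy_two_exon_gene):
        call = annotate_variant(
            _variant("chr2", 20, "G", "C"), 1, toy_two_exon_gene, toy_genome
        )
        assert call.effect_term == "splice_donor_variant"
        assert call.severity == "null" and call.display_color == "green"

    def test_splice_acceptor_at_last_intron_base(self, toy_genome, toy_two_exon_gene):
        call = annotate_variant(
            _variant("chr2", 27, "G", "T"), 1, toy_two_exon_gene, toy_genome
        )
        assert call.effect_term == "splice_acceptor_variant"

    def test_codon_aligned_deletion_is_conservative(self, toy_genome, toy_gene):
        # delete codon 2 (ACT): REF GACT at pos 13, ALT G
        call = annotate_variant(
            _variant("chr1", 13, "GACT", "G"), 1, toy_gene, toy_genome
        )
        assert call.effect_term == "conservative_inframe_deletion"
        assert call.aa_notation == "T2del"

    def test_unaligned_deletion_is_disruptive(self, toy_genome, toy_gene):
        # delete CTG (offsets 4..6, spanning codons 2 and 3): REF ACTG, ALT A
        call = annotate_variant(
            _variant("chr1", 14, "ACTG", "A"), 1, toy_gene, toy_genome
        )
        assert call.effect_term == "disruptive_inframe_deletion"

    def test_alt_index_out_of_range(self, toy_genome, toy_gene):
        with pytest.raises(ValueError):
            annotate_variant(_variant("chr1", 14, "A", "G"), 2, toy_gene, toy_genome)

    def test_strand_symmetry(self):
        """A gene and its reverse-complemented mirror give identical calls."""
        chrom = TOY_CHROM
        mirror = reverse_complement(chrom)
        n = len(chrom)
        genome = GenomeSequence({"fwd": chrom, "rev": mirror})
        fwd_gene = GeneModel(
            "gF", "fwd", 11, 25, "+",
            (Transcript("gF.t1", ((11, 25),), ((11, 25, 0),)),),
        )
        # interval [11,25] mirrors to [n-25+1, n-11+1]
        rev_gene = GeneModel(
            "gR", "rev", n - 25 + 1, n - 11 + 1, "-",
            (Transcript("gR.t1", ((n - 25 + 1, n - 11 + 1),), ((n - 25 + 1, n - 11 + 1, 0),)),),
        )
        for pos, ref, alt in [(14, "A", "G"), (21, "T", "A"), (16, "T", "C")]:
            fwd_call = annotate_variant(_variant("fwd", pos, ref, alt), 1, fwd_gene, genome)
            mpos = n - pos + 1
            rev_call = annotate_variant(
                _variant("rev", mpos, reverse_complement(ref), reverse_complement(alt)),
                1,
                rev_gene,
                genome,
            )
            assert (fwd_call.effect_term, fwd_call.aa_notation) == (
                rev_call.effect_term,
                rev_call.aa_notation,
            )

    def test_planted_panel_agrees_with_manifest(self, panel):
        """Annotation on the parsed fixture reproduces the plant-time truth."""
        from allelecat.effect_annotation import annotate_panel

        genes = {g.gene_id: g for g in panel.genes}
        annotated = annotate_panel(panel.records, panel.genes, panel.genome)
        by_pos = {(a.record.chrom, a.record.pos): a for a in annotated}
        checked = 0
        for pv in panel.manifest.planted:
            if pv.gene_id is None:
                continue
            av = by_pos[(pv.chrom, pv.pos)]
            ai = av.record.alt_seqs.index(pv.alt) + 1
            eff = av.effects[(pv.gene_id, ai)]
            assert (eff.effect_term, eff.aa_notation) == (pv.effect_term, pv.aa_notation)
            checked += 1
        assert checked >= 10


class TestClassifySeverity:
    def test_total_over_vocabulary(self):
        for term in EFFECT_TERMS:
            severity, color = classify_severity(term)
            assert severity in ("null", "modifying", "non_modifying")
            assert color in ("grey", "red", "orange", "blue", "green", "white")

    @pytest.mark.parametrize(
        "term,severity,color",
        [
            ("missense_variant", "modifying", "blue"),
            ("splice_donor_variant", "null", "green"),
            ("splice_acceptor_variant", "null", "green"),
            ("conservative_inframe_deletion", "modifying", "orange"),
            ("disruptive_inframe_deletion", "modifying", "white"),
            ("frameshift_variant", "null", "red"),
            ("stop_gained", "null", "red"),
            ("synonymous_variant", "non_modifying", "white"),
            ("non_coding_or_other", "non_modifying", "white"),
        ],
    )
    def test_expected_classes(self, term, severity, color):
        assert classify_severity(term) == (severity, color)

    def test_unknown_term_is_an_error(self):
        with pytest.raises(ValueError):
            classify_severity("weird_variant")


class TestAaNotation:
    @pytest.mark.parametrize(
        "term,pos,ref,alt,expected",
        [
            ("missense_variant", 27, "T", "A", "T27A"),
            ("frameshift_variant", 75, "R", "", "R75fs"),
            ("conservative_inframe_deletion", 2, "T", "", "T2del"),
            ("stop_gained", 4, "L", "", "L4*"),
            ("stop_lost", 158, "", "", "*158ext"),
            ("start_lost", 1, "M", "", "M1?"),
            ("splice_donor_variant", 1, "", "", ""),
        ],
    )
    def test_formats(self, term, pos, ref, alt, expected):
        assert aa_change_notation(term, pos, ref, alt) == expected


class TestAnnField:
    def test_ann_entries_map_to_internal_calls(self):
        ann = (
            "G|missense_variant|MODERATE|GeneX|GeneX|transcript|GeneX.t1|"
            "protein_coding|1/1|c.79A>G|p.Thr27Ala|79|79|27||",
        )
        rec = VariantRecord("c", 10, "A", ("G",), [(1, 1)], [False], ann=ann)
        effects = effects_from_ann(rec, {"GeneX"})
        eff = effects[("GeneX", 1)]
        assert eff.effect_term == "missense_variant"
        assert eff.aa_notation == "T27A"
        assert eff.severity == "modifying"

    def test_composite_terms_and_unknown_genes(self):
        ann = (
            "T|stop_gained&splice_region_variant|HIGH|GeneX|GeneX|transcript|t1|"
            "protein_coding|||p.Arg75fs|||||",
            "T|missense_variant|MODERATE|Other|Other|transcript|t2|"
            "protein_coding|||p.Lys82Glu|||||",
        )
        rec = VariantRecord("c", 10, "A", ("T",), [(1, 1)], [False], ann=ann)
        effects = effects_from_ann(rec, {"GeneX"})
        assert set(effects) == {("GeneX", 1)}
        assert effects[("GeneX", 1)].effect_term == "stop_gained"
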