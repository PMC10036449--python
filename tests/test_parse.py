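"""Parser and classifier tests: worked decompositions, the post-hyphen
disambiguation rule, auxiliary grammars, and totality/round-trip
properties."""

import pytest
from hypothesis import given, settings, strategies as st

from wheatnom import (
    Dominance,
    ParseError,
    SuffixKind,
    SymbolClass,
    VariantKind,
    classify,
    parse_any,
    parse_coordinate_marker,
    parse_gene_model,
    parse_mutation_annotation,
    parse_qtl,
    parse_symbol,
    parse_variant_marker,
    render,
)


class TestClassify:
    def test_guideline_examples_classify_as_documented(self, guideline_examples):
        for text, expected in guideline_examples:
            assert classify(text) is SymbolClass(expected), text

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("QYld.psr-7B.1", SymbolClass.QTL),
            ("TraesCS5A02G391700.1", SymbolClass.GENE_MODEL),
            ("CHS21_6A001234567", SymbolClass.COORDINATE_MARKER),
            ("zzz123!!", SymbolClass.UNKNOWN),
            ("", SymbolClass.UNKNOWN),
        ],
    )
    def test_precedence_examples(self, text, expected):
        assert classify(text) is expected

    @settings(max_examples=500, derandomize=True, deadline=None)
    @given(st.text(min_size=0, max_size=40))
    def test_total_on_arbitrary_text(self, text):
        assert classify(text) in SymbolClass

    def test_markdown_italics_stripped(self):
        assert classify("*VRN-A1*") is SymbolClass.LOCUS
        assert render(parse_symbol("*Sr9a*")) == "Sr9a"


class TestParseSymbol:
    def test_suppressor_prefix(self):
        sym = parse_symbol("Su1-Ph1")
        assert (sym.modifier_prefix.code, sym.modifier_prefix.serial) == ("Su", 1)
        assert (sym.basic_symbol, sym.set_number) == ("PH", 1)
        assert sym.dominance is Dominance.DOMINANT

    def test_gene_complex_member(self):
        sym = parse_symbol("GLU-A1-1")
        assert sym.basic_symbol == "GLU"
        assert sym.genome_token.letter == "A"
        assert (sym.set_number, sym.member_number) == (1, 1)

    def test_complex_member_allele(self):
        sym = parse_symbol("Glu-A1-1a")
        assert sym.allele_letters == "a"
        assert sym.dominance is Dominance.DOMINANT
        assert sym.member_number == 1

    def test_temporary_designation(self):
        sym = parse_symbol("SRFr1")
        assert sym.basic_symbol == "SR"
        assert (sym.temporary_stock.abbrev, sym.temporary_stock.serial) == ("Fr", 1)

    def test_recombined_allele(self):
        assert parse_symbol("Lr14ab").allele_letters == "ab"

    def test_haplotype_on_allele(self):
        sym = parse_symbol("Rg1a_h2")
        assert sym.allele_letters == "a"
        assert sym.suffix.kind is SuffixKind.HAPLOTYPE
        assert sym.suffix.index == 2

    def test_post_hyphen_disambiguation(self):
        # uppercase first character: genome + set; all digits: member number
        homoeo = parse_symbol("SEP1-A1")
        paralog = parse_symbol("SEP1-1")
        assert homoeo.genome_token.letter == "A"
        assert homoeo.member_number is None
        assert paralog.genome_token is None
        assert paralog.member_number == 1

    def test_species_prefix_recorded(self):
        sym = parse_symbol("TaAP1-A1")
        assert sym.species_prefix == "Ta"
        assert sym.basic_symbol == "AP1"

    def test_organelle_prefix(self):
        assert parse_symbol("MtATP1").organelle_prefix == "Mt"

    def test_avirulence_prefix(self):
        sym = parse_symbol("AvrLr14a")
        assert sym.avr_prefix is True
        assert (sym.basic_symbol, sym.set_number, sym.allele_letters) == ("LR", 14, "a")

    def test_aberration(self):
        sym = parse_symbol("HP(Tp6D)")
        assert sym.aberration.code == "Tp"
        assert str(sym.aberration.chromosome) == "6D"

    def test_mutant_annotation_attached(self):
        sym = parse_symbol("vrn-A1_m2 (null, W91*)")
        ann = sym.suffix.annotation
        assert ann.kind is VariantKind.AA_NONSENSE
        assert (ann.ref_state, ann.position) == ("W", 91)

    @pytest.mark.parametrize("bad", ["Rg1a_h0", "X1_x3", "vrn-A1_m01"])
    def test_malformed_suffix_raises(self, bad):
        with pytest.raises(ParseError, match="suffix"):
            parse_symbol(bad)

    def test_chromosome_in_symbol_raises(self):
        with pytest.raises(ParseError) as err:
            parse_symbol("VRN-5A")
        assert err.value.rule == "R05"


class TestParseQtl:
    def test_full_form(self):
        q = parse_qtl("QYld.psr-7B.1")
        assert (q.trait, q.lab, str(q.chromosome), q.serial) == ("Yld", "psr", "7B", 1)
        assert q.abbreviated is False

    def test_abbreviated_form(self):
        q = parse_qtl("QYld.psr.2")
        assert q.abbreviated is True
        assert q.serial == 2

    def test_trait_too_long(self):
        with pytest.raises(ParseError) as err:
            parse_qtl("QYield.psr-7B.1")
        assert err.value.rule == "R09"


class TestParseCoordinateMarker:
    def test_worked_example(self):
        m = parse_coordinate_marker("CHS21_6A001234567")
        assert m.assembly_code == "CHS"
        assert m.version == "2.1"
        assert str(m.chromosome) == "6A"
        assert m.position == 1_234_567

    def test_leading_zeros_stripped(self):
        m = parse_coordinate_marker("JAG10_1A000000001")
        assert (m.assembly_code, m.version, m.position) == ("JAG", "1.0", 1)

    def test_wrong_length_rejected(self):
        with pytest.raises(ParseError, match="17"):
            parse_coordinate_marker("CHS21_6A01234567")


class TestParseGeneModel:
    def test_hexaploid_scheme(self):
        g = parse_gene_model("TraesCS5A02G391700")
        assert (g.line_code, str(g.chromosome), g.serial) == ("CS", "5A", 391700)
        assert g.transcript is None

    def test_transcript_suffix(self):
        assert parse_gene_model("TraesCS5A02G391700.1").transcript == 1

    def test_transcript_zero_rejected(self):
        with pytest.raises(ParseError):
            parse_gene_model("TraesCS5A02G391700.0")

    def test_durum_scheme(self):
        g = parse_gene_model("TRITD5Av1G170700")
        assert g.scheme == "durum_svevo"
        assert (str(g.chromosome), g.annotation_version, g.serial) == ("5A", "1", 170700)

    def test_template_mismatch_names_nearest_scheme(self):
        with pytest.raises(ParseError, match="hexaploid_refseq"):
            parse_gene_model("TraesCS5A02G39170")


class TestParseVariantMarker:
    def test_nucleotide_substitution(self):
        m = parse_variant_marker("GW2-B1_C2504T")
        d = m.descriptor
        assert d.kind is VariantKind.NT_SUBSTITUTION
        assert (d.ref_state, d.position, d.alt_state) == ("C", 2504, "T")

    def test_deletion_length(self):
        m = parse_variant_marker("GW2-B1_53_72del")
        assert m.descriptor.kind is VariantKind.NT_DELETION
        assert m.descriptor.length == 20

    def test_platform_prefix(self):
        m = parse_variant_marker("Kasp_Sr13a_S1152F")
        assert m.platform == "Kasp"
        assert m.gene.render() == "Sr13a"
        d = m.descriptor
        assert d.kind is VariantKind.AA_SUBSTITUTION
        assert (d.ref_state, d.position, d.alt_state) == ("S", 1152, "F")

    def test_nonsense(self):
        m = parse_variant_marker("GW2-B1_C2510*")
        assert m.descriptor.kind is VariantKind.AA_NONSENSE
        assert m.descriptor.position == 2510

    def test_three_letter_codes(self):
        m = parse_variant_marker("GW2-B1_Ser1152Phe")
        assert (m.descriptor.ref_state, m.descriptor.alt_state) == ("Ser", "Phe")

    def test_unknown_residue_rejected(self):
        with pytest.raises(ParseError, match="residue"):
            parse_variant_marker("GW2-B1_Xyz12Ser")


class TestParseMutationAnnotation:
    def test_missense(self):
        d = parse_mutation_annotation("missense, V6M")
        assert d.kind is VariantKind.AA_SUBSTITUTION
        assert (d.ref_state, d.position, d.alt_state) == ("V", 6, "M")

    def test_null(self):
        d = parse_mutation_annotation("null, W91*")
        assert d.kind is VariantKind.AA_NONSENSE

    def test_bare_descriptor(self):
        assert parse_mutation_annotation("V6M").kind is VariantKind.AA_SUBSTITUTION

    def test_category_contradiction(self):
        with pytest.raises(ParseError):
            parse_mutation_annotation("null, V6M")
        with pytest.raises(ParseError):
            parse_mutation_annotation("missense, W91*")


class TestRoundTrip:
    def test_guideline_examples_round_trip(self, guideline_examples):
        for text, _ in guideline_examples:
            cls, obj = parse_any(text)
            rendered = obj if isinstance(obj, str) else obj.render("plain")
            assert rendered == text, text
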