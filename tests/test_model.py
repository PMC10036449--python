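"""Unit tests for the symbol data model: rendering, canonicalisation,
protein symbols, genotype and genome formulae, and type invariants."""

import pytest

from wheatnom import (
    ChromosomeToken,
    Dominance,
    GeneSymbol,
    GenomeToken,
    GenotypeFormula,
    InvariantError,
    SuffixKind,
    SuffixTag,
    VariantDescriptor,
    VariantKind,
    build_coordinate_marker,
    build_variant_marker,
    canonicalize,
    genome_formula,
    genotype_string,
    parse_symbol,
    protein_symbol,
    render,
)


class TestRender:
    @pytest.mark.parametrize(
        "symbol,expected",
        [
            (
                GeneSymbol("VRN", genome_token=GenomeToken("A"), set_number=1),
                "VRN-A1",
            ),
            (
                GeneSymbol("SR", set_number=9, allele_letters="a",
                           dominance=Dominance.DOMINANT),
                "Sr9a",
            ),
            (
                GeneSymbol("EPS", genome_token=GenomeToken("A", "m"), set_number=1),
                "EPS-A^m1",
            ),
            (
                GeneSymbol("VRN", genome_token=GenomeToken("A"), set_number=1,
                           dominance=Dominance.RECESSIVE,
                           suffix=SuffixTag(SuffixKind.MUTANT, 2)),
                "vrn-A1_m2",
            ),
        ],
    )
    def test_plain_examples(self, symbol, expected):
        assert render(symbol, "plain") == expected

    def test_styles(self):
        sym = GeneSymbol("EPS", genome_token=GenomeToken("A", "m"), set_number=1)
        assert render(sym, "markdown") == "*EPS-A^m1*"
        assert render(sym, "html") == "<i>EPS-A<sup>m</sup>1</i>"
        with pytest.raises(ValueError):
            render(sym, "latex")

    def test_resistance_override_case(self):
        # resistance alleles keep an uppercase first letter even when
        # they inherit as recessives
        sym = GeneSymbol("SR", set_number=17, dominance=Dominance.RESISTANCE_OVERRIDE)
        assert render(sym) == "Sr17"

    def test_dominance_case_is_recoverable(self):
        for dom, expected in [
            (Dominance.LOCUS, "VRN-A1"),
            (Dominance.DOMINANT, "Vrn-A1"),
            (Dominance.RECESSIVE, "vrn-A1"),
        ]:
            sym = GeneSymbol("VRN", genome_token=GenomeToken("A"), set_number=1,
                             dominance=dom)
            assert render(sym) == expected
            assert parse_symbol(expected).dominance is dom


class TestInvariants:
    def test_basic_symbol_rejects_plus_and_whitespace(self):
        for bad in ("VRN+", "VR N", ""):
            with pytest.raises(InvariantError):
                GeneSymbol(bad)

    def test_basic_symbol_rejects_trailing_chromosome(self):
        with pytest.raises(InvariantError, match="chromosome"):
            GeneSymbol("VRN5A")

    def test_allele_letters_require_dominance(self):
        with pytest.raises(InvariantError):
            GeneSymbol("SR", set_number=9, allele_letters="a")  # locus + letters

    def test_temporary_excludes_genome(self):
        from wheatnom import TemporaryStock

        with pytest.raises(InvariantError):
            GeneSymbol("SR", temporary_stock=TemporaryStock("Fr", 1),
                       genome_token=GenomeToken("A"), set_number=1)

    def test_modifier_case_agreement(self):
        from wheatnom import ModifierPrefix

        with pytest.raises(InvariantError):
            GeneSymbol("PH", set_number=1, modifier_prefix=ModifierPrefix("su", 1),
                       dominance=Dominance.DOMINANT)

    def test_organelle_prefix_closed_set(self):
        with pytest.raises(InvariantError):
            GeneSymbol("ATP", set_number=1, organelle_prefix="Nt")

    def test_suffix_index_positive(self):
        with pytest.raises(InvariantError):
            SuffixTag(SuffixKind.HAPLOTYPE, 0)

    def test_deletion_span_ordered(self):
        with pytest.raises(InvariantError):
            VariantDescriptor(kind=VariantKind.NT_DELETION, position=72, end_position=53)


class TestCanonicalize:
    def test_species_prefix_moves_to_metadata(self):
        sym = canonicalize(parse_symbol("TaAP1-A1"))
        bare = parse_symbol("AP1-A1")
        assert sym.species_prefix is None
        assert sym.metadata["species_prefix"] == "Ta"
        assert render(sym) == render(bare) == "AP1-A1"

    def test_idempotent(self):
        for text in ("TaAP1-A1", "Sr9a", "vrn-A1_m2"):
            once = canonicalize(parse_symbol(text))
            assert canonicalize(once) == once

    def test_dominance_pair_differs_only_in_dominance(self):
        a = canonicalize(parse_symbol("Sr9a"))
        b = canonicalize(parse_symbol("sr9a"))
        assert a.dominance is Dominance.DOMINANT
        assert b.dominance is Dominance.RECESSIVE
        import dataclasses

        fa = {f.name: getattr(a, f.name) for f in dataclasses.fields(a)}
        fb = {f.name: getattr(b, f.name) for f in dataclasses.fields(b)}
        fa.pop("dominance"), fb.pop("dominance")
        assert fa == fb


class TestProteinSymbol:
    @pytest.mark.parametrize(
        "gene,expected",
        [("Sr9a", "SR9a"), ("ADH-A1", "ADH-A1"), ("VRN-A1", "VRN-A1")],
    )
    def test_protein_rendering(self, gene, expected):
        prot = protein_symbol(parse_symbol(gene))
        assert prot.italic is False
        assert render(prot) == expected
        # non-italic symbols are unchanged by the markdown/html styles
        assert render(prot, "markdown") == expected

    def test_no_protein_form_for_suffixed(self):
        with pytest.raises(InvariantError):
            protein_symbol(parse_symbol("vrn-A1_m2"))


class TestGenotype:
    def test_heterozygote_maternal_first(self):
        f = GenotypeFormula(
            maternal=(parse_symbol("Vrn-A1"),), paternal=(parse_symbol("vrn-A1"),)
        )
        assert genotype_string(f) == "Vrn-A1/vrn-A1"

    def test_codominant(self):
        f = GenotypeFormula(
            maternal=(parse_symbol("Sr13a"),), paternal=(parse_symbol("Sr13b"),)
        )
        assert genotype_string(f) == "Sr13a/Sr13b"

    def test_linkage_phases(self):
        A, a = parse_symbol("A"), parse_symbol("a")
        B, b = parse_symbol("B"), parse_symbol("b")
        coupling = GenotypeFormula.from_linkage((A, a), (B, b), "coupling")
        repulsion = GenotypeFormula.from_linkage((A, a), (B, b), "repulsion")
        assert genotype_string(coupling) == "AB/ab"
        assert genotype_string(repulsion) == "Ab/aB"


class TestGenomeFormula:
    @pytest.mark.parametrize(
        "x,ploidy,two_n", [(7, 6, 42), (1, 2, 2), (7, 4, 28)]
    )
    def test_zygotic_number(self, x, ploidy, two_n):
        formula = genome_formula(x, ploidy)
        assert formula.zygotic_number == two_n
        assert formula.render() == f"2n = {ploidy}x = {two_n}"

    def test_bread_wheat_markdown(self):
        assert genome_formula(7, 6).render("markdown") == "2*n* = 6*x* = 42"

    def test_rejects_nonpositive(self):
        with pytest.raises(InvariantError):
            genome_formula(0, 6)
        with pytest.raises(InvariantError):
            genome_formula(7, 1)


class TestBuilders:
    def test_coordinate_marker_is_17_characters(self):
        marker = build_coordinate_marker("CHS", "2.1", "6A", 1_234_567)
        assert marker.render() == "CHS21_6A001234567"
        assert len(marker.render()) == 17

    def test_coordinate_marker_pads_position(self):
        assert build_coordinate_marker("CHS", "2.1", "6A", 1).render() == "CHS21_6A000000001"

    def test_coordinate_marker_overflow(self):
        with pytest.raises(InvariantError):
            build_coordinate_marker("CHS", "2.1", "6A", 1_000_000_000)
        with pytest.raises(InvariantError):
            build_coordinate_marker("CHS", "2.1", "6A", 0)

    def test_variant_marker_forces_three_letter_codes(self):
        # Cys/Ser at residue 10: one-letter C collides with cytosine
        gene = parse_symbol("X")
        desc = VariantDescriptor(
            kind=VariantKind.AA_SUBSTITUTION, position=10, ref_state="C", alt_state="S"
        )
        assert build_variant_marker(gene, desc).render() == "X_Cys10Ser"

    def test_variant_marker_plain_forms(self):
        gene = parse_symbol("GW2-B1")
        sub = VariantDescriptor(
            kind=VariantKind.NT_SUBSTITUTION, position=2504, ref_state="C", alt_state="T"
        )
        deletion = VariantDescriptor(
            kind=VariantKind.NT_DELETION, position=53, end_position=72
        )
        assert build_variant_marker(gene, sub).render() == "GW2-B1_C2504T"
        assert build_variant_marker(gene, deletion).render() == "GW2-B1_53_72del"
        assert deletion.length == 20


class TestChromosomeToken:
    def test_parse_and_render(self):
        tok = ChromosomeToken.from_text("7BS")
        assert (tok.group, tok.genome, tok.arm) == (7, "B", "S")
        assert str(tok) == "7BS"

    def test_group_bounds(self):
        with pytest.raises(InvariantError):
            ChromosomeToken(8, "A")
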