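"""Shared fixture data: the worked naming examples from the published
wheat nomenclature guidelines, with their expected symbol classes, plus
the anti-examples the guidelines explicitly forbid."""

import pytest

# (symbol, expected class) — every worked example string from the
# guidelines.  These must parse, classify as stated, and lint with zero
# error-severity findings.
GUIDELINE_EXAMPLES = [
    # loci named from phenotype; homoeologous sets and sequential series
    ("VRN-A1", "locus"),
    ("VRN-B1", "locus"),
    ("VRN-A2", "locus"),
    ("SR9", "locus"),
    ("SR10", "locus"),
    ("SR11", "locus"),
    ("RHT-1", "gene_complex_member"),  # dash-numbered set, no genome letter
    ("PM1", "locus"),
    ("SR15", "locus"),
    ("LR20", "locus"),
    ("SR26", "locus"),
    # alleles: case of the first letter encodes dominance
    ("Sr9a", "allele"),
    ("sr9", "allele"),
    ("sr9a", "allele"),
    ("Vrn-A1", "allele"),
    ("vrn-A1", "allele"),
    ("Vrn-A1a", "allele"),
    ("vrn-A1a", "allele"),
    ("Vrn-A1b", "allele"),
    ("Rht-B1a", "allele"),
    ("Rht-B1b", "allele"),
    ("rht-B1a", "allele"),
    ("Sr17", "allele"),
    ("Lr14a", "allele"),
    ("Lr14b", "allele"),
    ("Lr14ab", "allele"),      # recombined allele
    ("AvrLr14a", "allele"),    # pathogen avirulence counterpart
    # wild-relative genome superscript
    ("EPS-A^m1", "locus"),
    # genotype formulae, maternal first; linkage coupling/repulsion
    ("Vrn-A1/vrn-A1", "genotype_formula"),
    ("Sr13a/Sr13b", "genotype_formula"),
    ("A/a", "genotype_formula"),
    ("AB/ab", "genotype_formula"),
    ("Ab/aB", "genotype_formula"),
    # temporary designations
    ("SRFr1", "temporary"),
    ("SRFr2", "temporary"),
    ("SRFr3", "temporary"),
    # suppressors
    ("Su1-Ph1", "locus"),
    ("Su2-Ph1", "locus"),
    # transposed location
    ("HP(Tp6D)", "locus"),
    # cloned genes, species prefixes, gene models
    ("AP1-A1", "locus"),
    ("TaAP1-A1", "locus"),
    ("TtAP1-A1", "locus"),
    ("TraesCS5A02G391700", "gene_model"),
    ("TraesCS5A02G391700.1", "gene_model"),
    # homology-based names; paralogues and homoeologues
    ("SEP1-1", "gene_complex_member"),
    ("SEP1-2", "gene_complex_member"),
    ("SEP1-A1", "locus"),
    ("SEP1-B1", "locus"),
    ("SEP1-D1", "locus"),
    ("SEP1-A2", "locus"),
    ("TaSEP1-1", "gene_complex_member"),
    ("FT-A1", "locus"),
    ("FT-B1", "locus"),
    ("FT-D1", "locus"),
    ("OsNAM1", "locus"),
    ("NAM-A1", "locus"),
    ("TaAGL12-A1", "locus"),
    # haplotypes
    ("TaBRI-A1_h1", "haplotype"),
    ("TaBRI-A1_h4", "haplotype"),
    ("Sr9a_h1", "haplotype"),
    ("sr9a_h1", "haplotype"),
    ("Rht-A1a_h3", "haplotype"),
    ("Vrn-A1b_h2", "haplotype"),
    ("Rg1a_h1", "haplotype"),
    ("Rg1a_h2", "haplotype"),
    ("rg1b_h1", "haplotype"),
    ("rg1b_h2", "haplotype"),
    # induced mutants, with and without annotations
    ("vrn-A1_m1", "mutant"),
    ("vrn-A1_m2", "mutant"),
    ("vrn-A1_m1 (missense, V6M)", "mutant"),
    ("vrn-A1_m2 (null, W91*)", "mutant"),
    ("AGL12-A1_m1", "mutant"),
    ("AGL12-A1_m2", "mutant"),
    # gene complexes
    ("GLU-A1-1", "gene_complex_member"),
    ("GLU-B1-1", "gene_complex_member"),
    ("GLU-A1-2", "gene_complex_member"),
    ("GLU-B1-2", "gene_complex_member"),
    ("Glu-A1-1a", "gene_complex_member"),
    # pseudogenes
    ("RG-B1_p1", "pseudogene"),
    # loci encoding proteins
    ("ADH-A1", "locus"),
    ("ADH-B1", "locus"),
    ("ADH-D1", "locus"),
    # QTL, full and abbreviated map forms
    ("QYld.psr-7B.1", "qtl"),
    ("QYld.psr-7B.2", "qtl"),
    ("QYld.psr.1", "qtl"),
    ("QYld.psr.2", "qtl"),
    # DNA markers
    ("GW2-B1_C2504T", "variant_marker"),
    ("GW2-B1_53_72del", "variant_marker"),
    ("Kasp_Sr13a_S1152F", "variant_marker"),
    ("GW2-B1_C2510*", "variant_marker"),
    ("CHS21_6A001234567", "coordinate_marker"),
]

# (symbol, rule id the linter must report as an error)
GUIDELINE_ANTI_EXAMPLES = [
    ("VRN-5A", "R05"),
    ("VRN1-5A", "R05"),
    ("Vrn-A1+", "R01"),
    ("SRFede1", "R08"),
    ("QYield.psr-7B.1", "R09"),
]


@pytest.fixture(scope="session")
def guideline_examples():
    return GUIDELINE_EXAMPLES


@pytest.fixture(scope="session")
def guideline_anti_examples():
    return GUIDELINE_ANTI_EXAMPLES
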