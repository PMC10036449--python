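"""Seeded generator of valid and invalid symbol fixtures.

Valid cases are built as model objects and rendered, so the generated
text is well-formed by construction; the parser and the linter are then
exercised against it (round-trip and soundness properties).  Invalid
cases apply exactly one rule-violating mutation to an otherwise valid
construct and record the planted rule id, which the linter must recover
as its only error finding.

Sampling weights over the valid classes (documented, not configurable):
homoeologous loci 16%, sequential-series loci 8%, alleles 18%, suffixed
designations 14%, gene-complex members 6%, temporary designations 6%,
modifier-prefixed genes 4%, decorated symbols (species/organelle/Avr
prefixes, aberrations, wild-relative genome markers) 8%, QTL 8%,
coordinate markers 5%, gene models 4%, variant markers 6%, genotype
formulae 3%.

Plantable rules: R01-R09, R11, R13, R14, R15, R18 (the context-dependent
warning rules R10/R12 and the info rules R16/R17 have no error-severity
planting).
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass
from typing import List, Optional

from .model import (
    AA1,
    CONFUSABLE_RESIDUES,
    Aberration,
    ChromosomeToken,
    Dominance,
    GeneModelId,
    GeneSymbol,
    GenomeToken,
    GenotypeFormula,
    ModifierPrefix,
    QtlSymbol,
    CoordinateMarkerName,
    SuffixKind,
    SuffixTag,
    TemporaryStock,
    VariantDescriptor,
    VariantKind,
    VariantMarker,
)
from .parse import SymbolClass, _symbol_class_of

_GENOMES = "ABD"
_SAFE_RESIDUES = sorted(AA1 - CONFUSABLE_RESIDUES)
_ABERRATION_CODES = ["Df", "Dp", "Inv", "T", "Tp"]
_SPECIES_CODES = ["Ta", "Tt", "Os", "Hv", "Ae"]


@dataclass(frozen=True)
class FixtureCase:
    """One generated fixture: the text, its intended class and structured
    decomposition, the planted rule id for invalid cases, and the seed
    provenance string that reproduces it."""

    text: str
    symbol_class: SymbolClass
    symbol: object
    planted_rule: Optional[str]
    seed_provenance: str

    @property
    def valid(self) -> bool:
        return self.planted_rule is None


def _letters(rng: random.Random, n: int, alphabet: str = string.ascii_uppercase) -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def _basic(rng: random.Random, nmin: int = 2, nmax: int = 4) -> str:
    while True:
        s = _letters(rng, rng.randint(nmin, nmax))
        # avoid shapes the grammar reserves: modifier codes and the Avr
        # pathogen prefix would be re-tokenised on parse
        if s in ("SU", "EN") or s.startswith("AVR") or s[0] == "Q":
            continue
        return s


def _genome(rng: random.Random) -> str:
    return rng.choice(_GENOMES)


def _chromosome(rng: random.Random, arm_p: float = 0.0) -> ChromosomeToken:
    arm = rng.choice(["S", "L"]) if rng.random() < arm_p else None
    return ChromosomeToken(rng.randint(1, 7), _genome(rng), arm)


# -- valid makers -----------------------------------------------------------


def _mk_locus_homoeo(rng: random.Random) -> GeneSymbol:
    return GeneSymbol(
        basic_symbol=_basic(rng),
        genome_token=GenomeToken(_genome(rng)),
        set_number=rng.randint(1, 9),
    )


def _mk_locus_series(rng: random.Random) -> GeneSymbol:
    return GeneSymbol(basic_symbol=_basic(rng), set_number=rng.randint(1, 30))


def _mk_allele(rng: random.Random) -> GeneSymbol:
    dominance = rng.choice([Dominance.DOMINANT, Dominance.RECESSIVE])
    letters = rng.choice("abcdefg") if rng.random() < 0.85 else rng.choice(["ab", "bc"])
    if rng.random() < 0.5:
        return GeneSymbol(
            basic_symbol=_basic(rng),
            genome_token=GenomeToken(_genome(rng)),
            set_number=rng.randint(1, 9),
            allele_letters=letters,
            dominance=dominance,
        )
    return GeneSymbol(
        basic_symbol=_basic(rng),
        set_number=rng.randint(1, 30),
        allele_letters=letters,
        dominance=dominance,
    )


def _mk_suffixed(rng: random.Random) -> GeneSymbol:
    base = _mk_allele(rng) if rng.random() < 0.6 else _mk_locus_homoeo(rng)
    kind = rng.choice(list(SuffixKind))
    annotation = None
    if kind is SuffixKind.MUTANT and rng.random() < 0.3:
        if rng.random() < 0.5:
            ref, alt = rng.sample(_SAFE_RESIDUES, 2)
            annotation = VariantDescriptor(
                kind=VariantKind.AA_SUBSTITUTION,
                position=rng.randint(1, 900),
                ref_state=ref,
                alt_state=alt,
            )
        else:
            annotation = VariantDescriptor(
                kind=VariantKind.AA_NONSENSE,
                position=rng.randint(1, 900),
                ref_state=rng.choice(_SAFE_RESIDUES),
            )
    base.suffix = SuffixTag(kind, rng.randint(1, 5), annotation)
    return GeneSymbol(**_fields(base))


def _mk_complex_member(rng: random.Random) -> GeneSymbol:
    allele = rng.random() < 0.4
    return GeneSymbol(
        basic_symbol=_basic(rng),
        genome_token=GenomeToken(_genome(rng)),
        set_number=rng.randint(1, 4),
        member_number=rng.randint(1, 3),
        allele_letters=rng.choice("abcd") if allele else None,
        dominance=(
            rng.choice([Dominance.DOMINANT, Dominance.RECESSIVE])
            if allele
            else Dominance.LOCUS
        ),
    )


def _mk_temporary(rng: random.Random) -> GeneSymbol:
    abbrev = rng.choice(string.ascii_uppercase) + _letters(
        rng, rng.randint(1, 2), string.ascii_lowercase
    )
    return GeneSymbol(
        basic_symbol=_basic(rng, 2, 3),
        temporary_stock=TemporaryStock(abbrev, rng.randint(1, 9)),
    )


def _mk_modifier(rng: random.Random) -> GeneSymbol:
    recessive = rng.random() < 0.3
    code = rng.choice(["su", "en", "i"]) if recessive else rng.choice(["Su", "En", "I"])
    return GeneSymbol(
        basic_symbol=_basic(rng, 2, 3),
        set_number=rng.randint(1, 9),
        modifier_prefix=ModifierPrefix(code, rng.randint(1, 3)),
        dominance=Dominance.RECESSIVE if recessive else Dominance.DOMINANT,
    )


def _mk_decorated(rng: random.Random) -> GeneSymbol:
    which = rng.randrange(5)
    if which == 0:  # species prefix
        base = _mk_locus_homoeo(rng)
        base.species_prefix = rng.choice(_SPECIES_CODES)
        return GeneSymbol(**_fields(base))
    if which == 1:  # organelle prefix
        return GeneSymbol(
            basic_symbol=_basic(rng),
            set_number=rng.randint(1, 9),
            organelle_prefix=rng.choice(["Mt", "Pt", "Cp"]),
        )
    if which == 2:  # pathogen avirulence counterpart
        return GeneSymbol(
            basic_symbol=_basic(rng, 2, 3),
            set_number=rng.randint(1, 30),
            allele_letters=rng.choice("abc"),
            dominance=Dominance.DOMINANT,
            avr_prefix=True,
        )
    if which == 3:  # transposed location
        return GeneSymbol(
            basic_symbol=_basic(rng, 2, 3),
            aberration=Aberration(rng.choice(_ABERRATION_CODES), _chromosome(rng)),
        )
    # wild-relative genome superscript marker
    return GeneSymbol(
        basic_symbol=_basic(rng),
        genome_token=GenomeToken(_genome(rng), rng.choice(["m", "u", "sp"])),
        set_number=rng.randint(1, 9),
    )


def _fields(sym: GeneSymbol) -> dict:
    d = dict(sym.__dict__)
    return d


def _mk_qtl(rng: random.Random) -> QtlSymbol:
    trait = rng.choice(string.ascii_uppercase) + _letters(
        rng, rng.randint(1, 3), string.ascii_lowercase
    )
    lab = _letters(rng, rng.randint(2, 4), string.ascii_lowercase)
    if rng.random() < 0.25:
        return QtlSymbol(trait=trait, lab=lab, serial=rng.randint(1, 5))
    return QtlSymbol(
        trait=trait,
        lab=lab,
        chromosome=_chromosome(rng, arm_p=0.2),
        serial=rng.randint(1, 5) if rng.random() < 0.6 else None,
    )


def _mk_coordinate(rng: random.Random) -> CoordinateMarkerName:
    return CoordinateMarkerName(
        assembly_code=_letters(rng, 3),
        version_major=rng.randint(1, 9),
        version_minor=rng.randint(0, 9),
        chromosome=ChromosomeToken(rng.randint(1, 7), _genome(rng)),
        position=rng.randint(1, 999_999_999),
    )


def _mk_gene_model(rng: random.Random) -> GeneModelId:
    if rng.random() < 0.7:
        return GeneModelId(
            scheme="hexaploid_refseq",
            line_code=_letters(rng, 2),
            chromosome=ChromosomeToken(rng.randint(1, 7), _genome(rng)),
            annotation_version="02",
            serial=rng.randint(0, 999_999),
            transcript=rng.randint(1, 3) if rng.random() < 0.4 else None,
        )
    return GeneModelId(
        scheme="durum_svevo",
        chromosome=ChromosomeToken(rng.randint(1, 7), rng.choice("AB")),
        annotation_version="1",
        serial=rng.randint(0, 999_999),
        transcript=rng.randint(1, 3) if rng.random() < 0.4 else None,
    )


def _mk_variant_gene(rng: random.Random) -> GeneSymbol:
    return GeneSymbol(
        basic_symbol=_basic(rng, 2, 3) + (str(rng.randint(2, 9)) if rng.random() < 0.4 else ""),
        genome_token=GenomeToken(_genome(rng)),
        set_number=rng.randint(1, 4),
    )


def _mk_variant(rng: random.Random) -> VariantMarker:
    gene = _mk_variant_gene(rng)
    kind = rng.randrange(4)
    if kind == 0:
        ref, alt = rng.sample("ACGT", 2)
        desc = VariantDescriptor(
            kind=VariantKind.NT_SUBSTITUTION,
            position=rng.randint(1, 9000),
            ref_state=ref,
            alt_state=alt,
        )
    elif kind == 1:
        start = rng.randint(1, 5000)
        desc = VariantDescriptor(
            kind=VariantKind.NT_DELETION,
            position=start,
            end_position=start + rng.randint(0, 60),
        )
    elif kind == 2:
        ref, alt = rng.sample(_SAFE_RESIDUES, 2)
        desc = VariantDescriptor(
            kind=VariantKind.AA_SUBSTITUTION,
            position=rng.randint(1, 2000),
            ref_state=ref,
            alt_state=alt,
        )
    else:
        desc = VariantDescriptor(
            kind=VariantKind.AA_NONSENSE,
            position=rng.randint(1, 2000),
            ref_state=rng.choice(_SAFE_RESIDUES),
        )
    platform = rng.choice(["Kasp", "sunKasp", "Axiom"]) if rng.random() < 0.3 else None
    return VariantMarker(gene=gene, descriptor=desc, platform=platform)


def _mk_genotype(rng: random.Random) -> GenotypeFormula:
    basic = _basic(rng)
    genome = GenomeToken(_genome(rng))
    setn = rng.randint(1, 9)
    dom = GeneSymbol(
        basic_symbol=basic, genome_token=genome, set_number=setn, dominance=Dominance.DOMINANT
    )
    rec = GeneSymbol(
        basic_symbol=basic, genome_token=genome, set_number=setn, dominance=Dominance.RECESSIVE
    )
    return GenotypeFormula(maternal=(dom,), paternal=(rec,))


_VALID_MAKERS = [
    (_mk_locus_homoeo, 16),
    (_mk_locus_series, 8),
    (_mk_allele, 18),
    (_mk_suffixed, 14),
    (_mk_complex_member, 6),
    (_mk_temporary, 6),
    (_mk_modifier, 4),
    (_mk_decorated, 8),
    (_mk_qtl, 8),
    (_mk_coordinate, 5),
    (_mk_gene_model, 4),
    (_mk_variant, 6),
    (_mk_genotype, 3),
]


def _intended_class(obj) -> SymbolClass:
    if isinstance(obj, GeneSymbol):
        return _symbol_class_of(obj)
    if isinstance(obj, QtlSymbol):
        return SymbolClass.QTL
    if isinstance(obj, CoordinateMarkerName):
        return SymbolClass.COORDINATE_MARKER
    if isinstance(obj, GeneModelId):
        return SymbolClass.GENE_MODEL
    if isinstance(obj, VariantMarker):
        return SymbolClass.VARIANT_MARKER
    if isinstance(obj, GenotypeFormula):
        return SymbolClass.GENOTYPE_FORMULA
    raise TypeError(type(obj))


# -- invalid makers (one planted rule each) ----------------------------------


def _bad_r01(rng):  # plus sign
    return _mk_locus_homoeo(rng).render("plain") + "+"


def _bad_r02(rng):  # typographic superscript digit
    return _mk_locus_homoeo(rng).render("plain") + rng.choice("²³⁴")


def _bad_r03(rng):  # mixed case basic symbol
    b = _basic(rng, 3, 4)
    return f"{b[:-1]}{b[-1].lower()}-{_genome(rng)}{rng.randint(1, 9)}"


def _bad_r04(rng):  # allele letters on an all-caps locus name
    return f"{_basic(rng)}{rng.randint(1, 30)}{rng.choice('abc')}"


def _bad_r05(rng):  # chromosome name used as the locus designation
    return f"{_basic(rng)}-{rng.randint(1, 7)}{_genome(rng)}"


def _bad_r06(rng):  # uppercase allele letter
    return f"{_basic(rng).lower()}{rng.randint(1, 30)}{rng.choice('ABC')}"


def _bad_r07(rng):  # malformed suffix
    base = _mk_allele(rng).render("plain")
    tail = rng.choice(["_h0", "_m0", "_p01", "_x3", "_h02"])
    return base + tail


def _bad_r08(rng):  # over-long stock abbreviation
    abbrev = rng.choice(string.ascii_uppercase) + _letters(
        rng, rng.randint(3, 4), string.ascii_lowercase
    )
    return f"{_basic(rng, 2, 3)}{abbrev}{rng.randint(1, 9)}"


def _bad_r09(rng):  # five-letter QTL trait designator
    trait = rng.choice(string.ascii_uppercase) + _letters(rng, 4, string.ascii_lowercase)
    lab = _letters(rng, 3, string.ascii_lowercase)
    return f"Q{trait}.{lab}-{rng.randint(1, 7)}{_genome(rng)}.{rng.randint(1, 3)}"


def _bad_r11(rng):  # coordinate marker with a digit missing
    text = _mk_coordinate(rng).render("plain")
    drop = rng.randrange(9, 17)
    return text[:drop] + text[drop + 1:]


def _bad_r13(rng):  # genome letter outside the configured alphabet
    letter = rng.choice(sorted(set(string.ascii_uppercase) - set(_GENOMES)))
    return f"{_basic(rng)}-{letter}{rng.randint(1, 9)}"


def _bad_r14(rng):  # genotype with an empty side
    return _mk_allele(rng).render("plain") + "/"


def _bad_r15(rng):  # zero member number
    return f"{_basic(rng)}-{_genome(rng)}{rng.randint(1, 4)}-0"


def _bad_r18(rng):  # lowercase organelle prefix
    return f"mt{_basic(rng)}{rng.randint(1, 9)}"


_INVALID_MAKERS = {
    "R01": _bad_r01,
    "R02": _bad_r02,
    "R03": _bad_r03,
    "R04": _bad_r04,
    "R05": _bad_r05,
    "R06": _bad_r06,
    "R07": _bad_r07,
    "R08": _bad_r08,
    "R09": _bad_r09,
    "R11": _bad_r11,
    "R13": _bad_r13,
    "R14": _bad_r14,
    "R15": _bad_r15,
    "R18": _bad_r18,
}

PLANTABLE_RULES = sorted(_INVALID_MAKERS)


def generate_fixtures(n_valid: int, n_invalid: int, seed: int) -> List[FixtureCase]:
    """Generate ``n_valid`` well-formed and ``n_invalid`` single-fault
    symbol fixtures, reproducibly for a given seed."""
    if n_valid < 0 or n_invalid < 0:
        raise ValueError("fixture counts must be non-negative")
    rng = random.Random(seed)
    makers = [m for m, _ in _VALID_MAKERS]
    weights = [w for _, w in _VALID_MAKERS]
    cases: List[FixtureCase] = []
    for i in range(n_valid):
        maker = rng.choices(makers, weights=weights, k=1)[0]
        obj = maker(rng)
        cases.append(FixtureCase(
            text=obj.render("plain"),
            symbol_class=_intended_class(obj),
            symbol=obj,
            planted_rule=None,
            seed_provenance=f"seed={seed} valid#{i}",
        ))
    rules = PLANTABLE_RULES
    for i in range(n_invalid):
        rule = rules[i % len(rules)]
        text = _INVALID_MAKERS[rule](rng)
        cases.append(FixtureCase(
            text=text,
            symbol_class=SymbolClass.UNKNOWN,
            symbol=None,
            planted_rule=rule,
            seed_provenance=f"seed={seed} invalid#{i}",
        ))
    return cases
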