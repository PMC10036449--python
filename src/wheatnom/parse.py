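"""Tokenizer, classifier and parsers for free-text genetic symbols.

The classifier is total and deterministic: every printable string maps to
exactly one :class:`SymbolClass`, with ``unknown`` as the catch-all.
Precedence runs from the most template-like grammars down to generic
symbol shapes:

    gene_model > coordinate_marker > genotype_formula > qtl >
    variant_marker > suffixed > gene_complex_member > allele > locus >
    temporary > unknown

Parsing is strict about letter case because case is semantic (it encodes
dominance).  Markdown italic asterisks are stripped before parsing so
that strings copied from typeset documents parse cleanly.

The one genuinely underdetermined spot in the grammar is the segment
after a hyphen: ``SEP1-A1`` carries a genome letter plus homoeologous set
number, while ``SEP1-1`` carries a paralogue/member number.  The rule
used here is by first-character class: an uppercase letter starts a
genome token, a digit is a member number, and a digit followed by an
uppercase letter is a chromosome token - which is illegal inside a
symbol and reported as such.
"""

from __future__ import annotations

import enum
import re
from typing import Optional, Tuple

from .config import DEFAULT_CONFIG, NomenConfig, ORGANELLE_PREFIXES
from .errors import NomenclatureError, ParseError
from .model import (
    AA1,
    AA3_TO_1,
    Aberration,
    ChromosomeToken,
    Dominance,
    GeneModelId,
    GeneSymbol,
    GenomeToken,
    ModifierPrefix,
    NUCLEOTIDES,
    QtlSymbol,
    CoordinateMarkerName,
    SuffixKind,
    SuffixTag,
    TemporaryStock,
    VariantDescriptor,
    VariantKind,
    VariantMarker,
)


class SymbolClass(str, enum.Enum):
    LOCUS = "locus"
    ALLELE = "allele"
    HAPLOTYPE = "haplotype"
    MUTANT = "mutant"
    PSEUDOGENE = "pseudogene"
    GENE_COMPLEX_MEMBER = "gene_complex_member"
    QTL = "qtl"
    COORDINATE_MARKER = "coordinate_marker"
    VARIANT_MARKER = "variant_marker"
    GENE_MODEL = "gene_model"
    TEMPORARY = "temporary"
    GENOTYPE_FORMULA = "genotype_formula"
    UNKNOWN = "unknown"


def strip_markdown(text: str) -> str:
    """Remove symmetric markdown italic asterisks around a symbol.

    The trailing asterisk of a premature-stop marker (``GW2-B1_C2510*``)
    is meaningful and never at the start, so only a matched leading and
    trailing pair is stripped.
    """
    t = text.strip()
    while len(t) > 2 and t.startswith("*") and t.endswith("*"):
        t = t[1:-1]
    return t


# --------------------------------------------------------------------------
# intent patterns (cheap shape tests used by the classifier)

_GENE_MODEL_INTENT = re.compile(r"^(Traes|TRITD)")
_HEX_MODEL = re.compile(r"^Traes([A-Z]{2})([1-7][A-Z])(\d{2})G(\d{6})(?:\.(\d+))?$")
_DUR_MODEL = re.compile(r"^TRITD([1-7][A-Z])v(\d)G(\d{6})(?:\.(\d+))?$")
_COORD_INTENT = re.compile(r"^[A-Z]{3}\d{2}_(?=\d[A-Z0-9])")
_QTL_INTENT = re.compile(r"^Q[A-Za-z]+\.")
_QTL_FULL = re.compile(r"^Q([A-Za-z]+)\.([a-z]+)-([1-7][A-Z][SL]?)(?:\.([0-9]+))?$")
_QTL_ABBREV = re.compile(r"^Q([A-Za-z]+)\.([a-z]+)\.([0-9]+)$")
_POINT_DESCRIPTOR = re.compile(r"^([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3}|\*)$")
_DEL_TAIL = re.compile(r"^(\d+)del$")

_ABERRATION = re.compile(r"\((Df|Dp|Inv|T|Tp)([1-7])([A-Z])([SL])?\)$")
_ANNOTATION = re.compile(r"\s*\((missense|null),\s*([^()]*)\)$")
_MODIFIER = re.compile(r"^(Su|En|I|su|en|i)([1-9]\d*)-(?=\S)")
_SPECIES = re.compile(r"^([A-Z][a-z])(?=[A-Z])")
_ORGANELLE = re.compile(r"^(Mt|Pt|Cp)(?=[A-Z])")
_TEMPORARY = re.compile(r"^([A-Z]{2,8})([A-Z][a-z]+)([1-9]\d*)$")
_CHROMOSOME_SEG = re.compile(r"^([1-7])([A-Z])([SL])?$")


def _variant_shape(text: str) -> bool:
    if "_" not in text:
        return False
    tokens = text.split("_")
    if len(tokens) >= 3 and _DEL_TAIL.fullmatch(tokens[-1]) and tokens[-2].isdigit():
        return True
    m = _POINT_DESCRIPTOR.fullmatch(tokens[-1])
    # suffix tails like _h2 have no alternate state and never match, but a
    # descriptor needs at least a ref state, a position and an alt state
    return m is not None


# --------------------------------------------------------------------------
# classifier


def classify(text: str, config: NomenConfig = DEFAULT_CONFIG) -> SymbolClass:
    """Map free text to exactly one symbol class; never raises."""
    try:
        t = strip_markdown(str(text))
        if not t:
            return SymbolClass.UNKNOWN
        if _GENE_MODEL_INTENT.match(t):
            return SymbolClass.GENE_MODEL
        if _COORD_INTENT.match(t):
            return SymbolClass.COORDINATE_MARKER
        if "/" in t:
            return SymbolClass.GENOTYPE_FORMULA
        if _QTL_INTENT.match(t):
            return SymbolClass.QTL
        if _variant_shape(t):
            return SymbolClass.VARIANT_MARKER
        sym = parse_symbol(t, config)
    except NomenclatureError:
        return SymbolClass.UNKNOWN
    except (ValueError, TypeError):
        return SymbolClass.UNKNOWN
    return _symbol_class_of(sym)


def _symbol_class_of(sym: GeneSymbol) -> SymbolClass:
    if sym.suffix is not None:
        return {
            SuffixKind.HAPLOTYPE: SymbolClass.HAPLOTYPE,
            SuffixKind.MUTANT: SymbolClass.MUTANT,
            SuffixKind.PSEUDOGENE: SymbolClass.PSEUDOGENE,
        }[sym.suffix.kind]
    if sym.temporary_stock is not None:
        return SymbolClass.TEMPORARY
    if sym.member_number is not None:
        return SymbolClass.GENE_COMPLEX_MEMBER
    if sym.modifier_prefix is not None and sym.allele_letters is None:
        # Su1-Ph1 names the suppressor locus; the case of the affected
        # symbol does not make it an allele designation
        return SymbolClass.LOCUS
    if sym.allele_letters is not None or sym.dominance is not Dominance.LOCUS:
        return SymbolClass.ALLELE
    return SymbolClass.LOCUS


# --------------------------------------------------------------------------
# gene / locus / allele symbols


def parse_symbol(text: str, config: NomenConfig = DEFAULT_CONFIG) -> GeneSymbol:
    """Parse a locus/allele/suffixed/temporary/complex-member symbol."""
    t = strip_markdown(str(text))
    if not t:
        raise ParseError("empty symbol")
    work = t

    aberration = None
    m = _ABERRATION.search(work)
    if m:
        aberration = Aberration(
            m.group(1), ChromosomeToken(int(m.group(2)), m.group(3), m.group(4))
        )
        work = work[: m.start()]

    annotation = None
    m = _ANNOTATION.search(work)
    if m:
        annotation = parse_mutation_annotation(f"{m.group(1)}, {m.group(2)}")
        work = work[: m.start()]

    suffix = None
    if "_" in work:
        head, _, tail = work.rpartition("_")
        sm = re.fullmatch(r"([a-z])([0-9]+)", tail)
        if sm is None or sm.group(1) not in "hmp":
            raise ParseError(
                f"malformed suffix token '_{tail}' (expected _h/_m/_p plus index)",
                token=f"_{tail}",
                rule="R07",
            )
        if sm.group(2).startswith("0"):
            raise ParseError(
                f"suffix index in '_{tail}' must be a positive integer without leading zeros",
                token=f"_{tail}",
                rule="R07",
            )
        suffix = SuffixTag(SuffixKind(sm.group(1)), int(sm.group(2)), annotation)
        annotation = None
        work = head
    if annotation is not None:
        raise ParseError(
            "mutation annotation requires a mutant (_mX) suffix", token=t
        )

    species = None
    m = _SPECIES.match(work)
    if m and m.group(1) not in ORGANELLE_PREFIXES:
        species = m.group(1)
        work = work[2:]
    organelle = None
    m = _ORGANELLE.match(work)
    if m:
        organelle = m.group(1)
        work = work[m.end():]

    avr = False
    if work.startswith("Avr") and len(work) > 3 and work[3].isupper():
        avr = True
        work = work[3:]

    modifier = None
    m = _MODIFIER.match(work)
    if m:
        modifier = ModifierPrefix(m.group(1), int(m.group(2)))
        work = work[m.end():]

    common = dict(
        species_prefix=species,
        organelle_prefix=organelle,
        avr_prefix=avr,
        modifier_prefix=modifier,
        suffix=suffix,
        aberration=aberration,
    )

    m = _TEMPORARY.fullmatch(work)
    if m:
        basic, abbrev, serial = m.group(1), m.group(2), m.group(3)
        if len(abbrev) > 3:
            raise ParseError(
                f"stock abbreviation {abbrev!r} exceeds the 3-letter maximum",
                token=abbrev,
                rule="R08",
            )
        return GeneSymbol(
            basic_symbol=basic,
            temporary_stock=TemporaryStock(abbrev, int(serial)),
            dominance=Dominance.LOCUS,
            **common,
        )

    return _parse_core(work, t, config, common)


def _parse_core(work: str, original: str, config: NomenConfig, common: dict) -> GeneSymbol:
    bound = config.allele_letter_bound
    segs = work.split("-")
    if any(s == "" for s in segs):
        raise ParseError(f"empty hyphen segment in {original!r}", token=original)

    seg0 = segs[0]
    m0 = re.fullmatch(rf"([A-Za-z]+)(\d+)?([a-z]{{1,{bound}}})?", seg0)
    if m0 is None:
        mu = re.fullmatch(r"([A-Za-z]+)(\d+)([A-Z]{1,2})", seg0)
        if mu:
            raise ParseError(
                f"allele letters must be lowercase in {seg0!r}",
                token=mu.group(3),
                rule="R06",
                suggestion=original.replace(seg0, seg0[: mu.start(3)] + mu.group(3).lower()),
            )
        raise ParseError(f"unrecognised token {seg0!r}", token=seg0)
    letters, digits0, allele0 = m0.group(1), m0.group(2), m0.group(3)

    if letters.isupper():
        dominance = Dominance.LOCUS
    elif letters.islower():
        dominance = Dominance.RECESSIVE
    elif letters[0].isupper() and letters[1:].islower():
        dominance = Dominance.DOMINANT
    else:
        raise ParseError(
            f"mixed letter case in {letters!r} encodes no dominance class",
            token=letters,
            rule="R03",
            suggestion=original.replace(letters, letters.upper(), 1),
        )

    if allele0 is not None and len(segs) > 1:
        raise ParseError(
            f"allele letters must follow the final designation, not {seg0!r}",
            token=allele0,
            rule="R06",
        )

    genome: Optional[GenomeToken] = None
    set_number: Optional[int] = None
    member: Optional[int] = None
    allele: Optional[str] = allele0

    for i, seg in enumerate(segs[1:], start=1):
        is_last = i == len(segs) - 1
        mg = re.fullmatch(rf"([A-Z])(?:\^([a-z]{{1,2}}))?([1-9]\d*)([a-z]{{1,{bound}}})?", seg)
        if mg and genome is None and member is None and i == 1:
            genome = GenomeToken(mg.group(1), mg.group(2))
            set_number = int(mg.group(3))
            if mg.group(4):
                if not is_last:
                    raise ParseError(
                        "allele letters must follow the final designation",
                        token=mg.group(4),
                        rule="R06",
                    )
                allele = mg.group(4)
            continue
        mm = re.fullmatch(rf"(\d+)([a-z]{{1,{bound}}})?", seg)
        if mm and member is None:
            if mm.group(1).startswith("0"):
                raise ParseError(
                    f"complex member number {mm.group(1)!r} must be a positive "
                    "Arabic numeral without leading zeros",
                    token=mm.group(1),
                    rule="R15",
                )
            member = int(mm.group(1))
            if mm.group(2):
                if not is_last:
                    raise ParseError(
                        "allele letters must follow the final designation",
                        token=mm.group(2),
                        rule="R06",
                    )
                allele = mm.group(2)
            continue
        if _CHROMOSOME_SEG.fullmatch(seg):
            raise ParseError(
                f"chromosome name {seg!r} must not appear in a gene symbol; use "
                "genome letter + homoeologous set number instead",
                token=seg,
                rule="R05",
            )
        mu = re.fullmatch(r"([A-Z])(\^[a-z]{1,2})?(\d+)([A-Z]{1,2})", seg) or re.fullmatch(
            r"(\d+)([A-Z]{1,2})", seg
        )
        if mu:
            raise ParseError(
                f"allele letters must be lowercase in segment {seg!r}",
                token=seg,
                rule="R06",
                suggestion=original[: len(original) - len(seg)] + seg[:-1] + seg[-1].lower()
                if original.endswith(seg)
                else None,
            )
        raise ParseError(f"unrecognised segment {seg!r}", token=seg)

    if genome is not None and digits0 is not None:
        # digits belong to the basic symbol itself (AGL12-A1, GW2-B1)
        basic = letters + digits0
    else:
        basic = letters
        if digits0 is not None:
            if digits0.startswith("0"):
                raise ParseError(
                    f"set number {digits0!r} has leading zeros", token=digits0
                )
            set_number = int(digits0)

    if allele is not None and dominance is Dominance.LOCUS:
        raise ParseError(
            "an all-uppercase locus name cannot carry allele letters; the first "
            "letter encodes dominance",
            token=allele,
            rule="R04",
        )

    return GeneSymbol(
        basic_symbol=basic,
        genome_token=genome,
        set_number=set_number,
        member_number=member,
        allele_letters=allele,
        dominance=dominance,
        **common,
    )


# --------------------------------------------------------------------------
# QTL symbols


def parse_qtl(text: str) -> QtlSymbol:
    """Parse a full (``QYld.psr-7B.1``) or abbreviated (``QYld.psr.1``)
    QTL symbol."""
    t = strip_markdown(str(text))
    if not t.startswith("Q"):
        raise ParseError(f"{t!r} does not start with the QTL basic symbol Q", token=t)
    m = _QTL_FULL.fullmatch(t)
    if m:
        trait, lab, chrom, serial = m.groups()
        _check_trait(trait)
        return QtlSymbol(
            trait=trait,
            lab=lab,
            chromosome=ChromosomeToken.from_text(chrom),
            serial=int(serial) if serial else None,
        )
    m = _QTL_ABBREV.fullmatch(t)
    if m:
        trait, lab, serial = m.groups()
        _check_trait(trait)
        return QtlSymbol(trait=trait, lab=lab, chromosome=None, serial=int(serial))
    raise ParseError(f"{t!r} matches neither the full nor the abbreviated QTL form", token=t)


def _check_trait(trait: str) -> None:
    if len(trait) > 4:
        raise ParseError(
            f"QTL trait designator {trait!r} exceeds 4 letters",
            token=trait,
            rule="R09",
        )
    if not trait[0].isupper():
        raise ParseError(
            f"QTL trait designator {trait!r} must start with an uppercase letter",
            token=trait,
            rule="R09",
        )


# --------------------------------------------------------------------------
# coordinate markers


def parse_coordinate_marker(text: str) -> CoordinateMarkerName:
    """Parse a 17-character coordinate SNP name by fixed offsets."""
    t = strip_markdown(str(text))
    if len(t) != 17:
        raise ParseError(
            f"coordinate marker must be exactly 17 characters, got {len(t)}",
            token=t,
            rule="R11",
            offset=min(len(t), 17),
        )
    if t[5] != "_":
        raise ParseError(
            "character 6 of a coordinate marker is the understroke",
            token=t[5],
            rule="R11",
            offset=5,
        )
    assembly, version, chrom, pos = t[0:3], t[3:5], t[6:8], t[8:17]
    if not re.fullmatch(r"[A-Z]{3}", assembly):
        raise ParseError(
            f"assembly code {assembly!r} must be 3 uppercase letters",
            token=assembly, rule="R11", offset=0,
        )
    if not version.isdigit():
        raise ParseError(
            f"assembly version {version!r} must be two digits",
            token=version, rule="R11", offset=3,
        )
    if not re.fullmatch(r"[1-7][A-Z]", chrom):
        raise ParseError(
            f"chromosome field {chrom!r} must be group 1-7 plus genome letter",
            token=chrom, rule="R11", offset=6,
        )
    if not pos.isdigit():
        raise ParseError(
            f"position field {pos!r} must be 9 digits (zero padded)",
            token=pos, rule="R11", offset=8,
        )
    position = int(pos)
    if position < 1:
        raise ParseError("position must be >= 1", token=pos, rule="R11", offset=8)
    return CoordinateMarkerName(
        assembly_code=assembly,
        version_major=int(version[0]),
        version_minor=int(version[1]),
        chromosome=ChromosomeToken(int(chrom[0]), chrom[1]),
        position=position,
    )


# --------------------------------------------------------------------------
# gene models


def parse_gene_model(text: str) -> GeneModelId:
    """Parse a hexaploid reference-sequence or durum Svevo gene-model
    identifier, with optional transcript suffix."""
    t = strip_markdown(str(text))
    m = _HEX_MODEL.fullmatch(t)
    if m:
        line, chrom, version, serial, transcript = m.groups()
        if transcript is not None and (transcript.startswith("0") or int(transcript) < 1):
            raise ParseError(
                f"transcript index {transcript!r} must be >= 1", token=transcript
            )
        return GeneModelId(
            scheme="hexaploid_refseq",
            line_code=line,
            chromosome=ChromosomeToken(int(chrom[0]), chrom[1]),
            annotation_version=version,
            serial=int(serial),
            transcript=int(transcript) if transcript else None,
        )
    m = _DUR_MODEL.fullmatch(t)
    if m:
        chrom, version, serial, transcript = m.groups()
        if transcript is not None and (transcript.startswith("0") or int(transcript) < 1):
            raise ParseError(
                f"transcript index {transcript!r} must be >= 1", token=transcript
            )
        return GeneModelId(
            scheme="durum_svevo",
            chromosome=ChromosomeToken(int(chrom[0]), chrom[1]),
            annotation_version=version,
            serial=int(serial),
            transcript=int(transcript) if transcript else None,
        )
    nearest = "hexaploid_refseq" if t.startswith("Traes") else "durum_svevo"
    raise ParseError(
        f"{t!r} does not match the {nearest} gene-model template", token=t
    )


# --------------------------------------------------------------------------
# variant markers and mutation annotations


def parse_variant_marker(
    text: str, config: NomenConfig = DEFAULT_CONFIG
) -> VariantMarker:
    """Parse a gene-based variant marker into its gene core, change
    descriptor and optional platform prefix."""
    t = strip_markdown(str(text))
    tokens = t.split("_")
    if len(tokens) < 2:
        raise ParseError(f"{t!r} is not a variant marker", token=t)

    mdel = _DEL_TAIL.fullmatch(tokens[-1])
    if mdel and len(tokens) >= 3 and tokens[-2].isdigit():
        start, end = int(tokens[-2]), int(mdel.group(1))
        if start < 1:
            raise ParseError("deletion start must be >= 1", token=tokens[-2])
        if end < start:
            raise ParseError(
                f"deletion end {end} precedes start {start}", token=tokens[-1]
            )
        descriptor = VariantDescriptor(
            kind=VariantKind.NT_DELETION, position=start, end_position=end
        )
        gene_tokens = tokens[:-2]
    else:
        descriptor = parse_point_descriptor(tokens[-1])
        gene_tokens = tokens[:-1]

    if len(gene_tokens) == 1:
        platform, gene_text = None, gene_tokens[0]
    elif len(gene_tokens) == 2:
        platform, gene_text = gene_tokens
    else:
        raise ParseError(
            f"too many underscore-separated parts before the descriptor in {t!r}",
            token=t,
        )
    gene = parse_symbol(gene_text, config)
    return VariantMarker(gene=gene, descriptor=descriptor, platform=platform)


def parse_point_descriptor(text: str) -> VariantDescriptor:
    """Parse a point-change descriptor: nucleotide substitution
    (``C2504T``), amino-acid substitution (``S1152F``, ``Ser1152Phe``) or
    nonsense change (``W91*``).

    When both states are single letters drawn from A/C/G/T the change is
    read as a nucleotide substitution; this ambiguity is why the
    guidelines require three-letter codes for Cys/Thr/Gly/Ala residues.
    """
    m = _POINT_DESCRIPTOR.fullmatch(text)
    if m is None:
        raise ParseError(f"{text!r} is not a change descriptor", token=text)
    ref, pos, alt = m.groups()
    position = int(pos)
    if position < 1 or pos.startswith("0"):
        raise ParseError(f"position {pos!r} must be a positive integer", token=pos)
    if len(ref) == 1 and len(alt) == 1 and ref in NUCLEOTIDES and alt in NUCLEOTIDES:
        return VariantDescriptor(
            kind=VariantKind.NT_SUBSTITUTION, position=position, ref_state=ref, alt_state=alt
        )
    _require_residue(ref)
    if alt == "*":
        return VariantDescriptor(
            kind=VariantKind.AA_NONSENSE, position=position, ref_state=ref, alt_state="*"
        )
    _require_residue(alt)
    return VariantDescriptor(
        kind=VariantKind.AA_SUBSTITUTION, position=position, ref_state=ref, alt_state=alt
    )


def _require_residue(state: str) -> None:
    ok = (len(state) == 1 and state in AA1) or state in AA3_TO_1
    if not ok:
        raise ParseError(f"unknown residue code {state!r}", token=state)


def parse_mutation_annotation(text: str) -> VariantDescriptor:
    """Parse a mutant annotation such as ``missense, V6M``, ``null, W91*``
    or a bare ``V6M``; the category is cross-checked against the change."""
    t = str(text).strip()
    m = re.fullmatch(r"(?:(missense|null)\s*,\s*)?(\S+)", t)
    if m is None:
        raise ParseError(f"{t!r} is not a mutation annotation", token=t)
    category, desc_text = m.groups()
    descriptor = _parse_aa_descriptor(desc_text)
    if category == "null" and descriptor.kind is not VariantKind.AA_NONSENSE:
        raise ParseError(
            f"'null' annotations describe premature stops, not {descriptor.render()}",
            token=desc_text,
        )
    if category == "missense" and descriptor.kind is not VariantKind.AA_SUBSTITUTION:
        raise ParseError(
            f"'missense' annotations describe amino-acid substitutions, "
            f"not {descriptor.render()}",
            token=desc_text,
        )
    return descriptor


def _parse_aa_descriptor(text: str) -> VariantDescriptor:
    m = _POINT_DESCRIPTOR.fullmatch(text)
    if m is None:
        raise ParseError(f"{text!r} is not an amino-acid change descriptor", token=text)
    ref, pos, alt = m.groups()
    _require_residue(ref)
    if alt == "*":
        return VariantDescriptor(
            kind=VariantKind.AA_NONSENSE, position=int(pos), ref_state=ref, alt_state="*"
        )
    _require_residue(alt)
    return VariantDescriptor(
        kind=VariantKind.AA_SUBSTITUTION, position=int(pos), ref_state=ref, alt_state=alt
    )


# --------------------------------------------------------------------------
# generic dispatcher


def parse_any(text: str, config: NomenConfig = DEFAULT_CONFIG) -> Tuple[SymbolClass, object]:
    """Classify and parse in one call; raises ParseError for unknown."""
    cls = classify(text, config)
    t = strip_markdown(str(text))
    if cls is SymbolClass.GENE_MODEL:
        return cls, parse_gene_model(t)
    if cls is SymbolClass.COORDINATE_MARKER:
        return cls, parse_coordinate_marker(t)
    if cls is SymbolClass.QTL:
        return cls, parse_qtl(t)
    if cls is SymbolClass.VARIANT_MARKER:
        return cls, parse_variant_marker(t, config)
    if cls is SymbolClass.GENOTYPE_FORMULA:
        return cls, t  # genotype strings are validated, not decomposed further
    if cls is SymbolClass.UNKNOWN:
        raise ParseError(f"{t!r} is not a recognised symbol", token=t)
    return cls, parse_symbol(t, config)
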