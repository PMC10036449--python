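"""Structured data model for Triticeae genetic symbols.

The model covers every symbol family used in wheat genetics: loci and
alleles (``VRN-A1``, ``Sr9a``), haplotype / induced-mutant / pseudogene
suffixes (``_h2``, ``_m1``, ``_p1``), gene-complex members (``GLU-A1-1``),
temporary stock designations (``SRFr1``), QTL symbols (``QYld.psr-7B.1``),
coordinate-based SNP marker names (``CHS21_6A001234567``), gene-model
identifiers (``TraesCS5A02G391700``), genotype formulae and the genome
formula (2n = 6x = 42).

Italics are typography, not data: every type stores an ``italic`` flag and
offers three render styles.  The *plain* style is the canonical comparison
form; *markdown* wraps italic spans in asterisks and *html* uses ``<i>``
(with ``<sup>`` for wild-relative genome markers such as the ``m`` in
``EPS-A^m1``).

Letter case of the basic symbol is likewise derived, not stored: the
symbol is kept uppercase internally and the ``dominance`` field decides
how it renders (locus -> all caps, dominant -> capitalised, recessive ->
lowercase).  This prevents internally inconsistent states such as an
"uppercase recessive" symbol.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Union

from .config import (
    ABERRATION_CODES,
    MODIFIER_CODES,
    ORGANELLE_PREFIXES,
)
from .errors import InvariantError

# --------------------------------------------------------------------------
# residue and nucleotide vocabularies

#: one-letter codes of the 20 standard amino acids
AA1: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: three-letter -> one-letter amino-acid code table
AA3_TO_1: dict[str, str] = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA1_TO_3: dict[str, str] = {v: k for k, v in AA3_TO_1.items()}

NUCLEOTIDES: frozenset[str] = frozenset("ACGT")

#: amino acids whose one-letter code collides with a nucleotide letter
#: (cysteine/cytosine, threonine/thymine, glycine/guanine, alanine/adenine);
#: the guidelines require the three-letter code for these in marker names.
CONFUSABLE_RESIDUES: frozenset[str] = frozenset("ACGT")


class Dominance(str, enum.Enum):
    """Inheritance class encoded by the letter case of a rendered symbol."""

    LOCUS = "locus"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    #: resistance alleles keep an uppercase first letter even when they
    #: inherit as recessives
    RESISTANCE_OVERRIDE = "resistance_override"


class SuffixKind(str, enum.Enum):
    HAPLOTYPE = "h"
    MUTANT = "m"
    PSEUDOGENE = "p"


class VariantKind(str, enum.Enum):
    NT_SUBSTITUTION = "nt_substitution"
    NT_DELETION = "nt_deletion"
    AA_SUBSTITUTION = "aa_substitution"
    AA_NONSENSE = "aa_nonsense"


# --------------------------------------------------------------------------
# small component records


@dataclass(frozen=True)
class ChromosomeToken:
    """A chromosome / linkage-group name: group 1-7, genome letter,
    optional arm (S short / L long), e.g. ``5A`` or ``7BS``."""

    group: int
    genome: str
    arm: Optional[str] = None

    def __post_init__(self) -> None:
        if not 1 <= self.group <= 7:
            raise InvariantError("chromosome_group", f"group {self.group} outside 1-7")
        if not re.fullmatch(r"[A-Z]", self.genome):
            raise InvariantError(
                "chromosome_genome", f"genome {self.genome!r} is not one uppercase letter"
            )
        if self.arm is not None and self.arm not in ("S", "L"):
            raise InvariantError("chromosome_arm", f"arm must be S or L, got {self.arm!r}")

    @classmethod
    def from_text(cls, text: str) -> "ChromosomeToken":
        m = re.fullmatch(r"([1-7])([A-Z])([SL])?", text)
        if m is None:
            raise InvariantError("chromosome_token", f"{text!r} is not a chromosome name")
        return cls(int(m.group(1)), m.group(2), m.group(3))

    def __str__(self) -> str:
        return f"{self.group}{self.genome}{self.arm or ''}"


@dataclass(frozen=True)
class GenomeToken:
    """Sub-genome designation inside a locus symbol, optionally with a
    wild-relative superscript marker (the ``m`` of ``A^m``)."""

    letter: str
    relative_marker: Optional[str] = None

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z]", self.letter):
            raise InvariantError("genome_letter", f"{self.letter!r} is not one uppercase letter")
        if self.relative_marker is not None and not re.fullmatch(
            r"[a-z]{1,2}", self.relative_marker
        ):
            raise InvariantError(
                "relative_marker", f"{self.relative_marker!r} must be 1-2 lowercase letters"
            )

    def render(self, style: str = "plain") -> str:
        if self.relative_marker is None:
            return self.letter
        if style == "html":
            return f"{self.letter}<sup>{self.relative_marker}</sup>"
        return f"{self.letter}^{self.relative_marker}"


@dataclass(frozen=True)
class ModifierPrefix:
    """Inhibitor (I/i), suppressor (Su/su) or enhancer (En/en) prefix with
    its serial number; the remainder of the symbol is the affected gene."""

    code: str
    serial: int

    def __post_init__(self) -> None:
        if self.code not in MODIFIER_CODES:
            raise InvariantError("modifier_code", f"{self.code!r} not one of {sorted(MODIFIER_CODES)}")
        if self.serial < 1:
            raise InvariantError("modifier_serial", "serial must be >= 1")

    @property
    def recessive(self) -> bool:
        return self.code.islower()


@dataclass(frozen=True)
class TemporaryStock:
    """Stock/line abbreviation and serial of a temporary designation,
    e.g. the ``Fr`` + ``1`` of ``SRFr1`` (Federation locus 1)."""

    abbrev: str
    serial: int

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z][a-z]{0,2}", self.abbrev):
            raise InvariantError(
                "stock_abbrev",
                f"{self.abbrev!r} must be a title-case abbreviation of at most 3 letters",
            )
        if self.serial < 1:
            raise InvariantError("stock_serial", "serial must be >= 1")


@dataclass(frozen=True)
class Aberration:
    """Non-standard chromosome location, e.g. the ``Tp6D`` in ``HP(Tp6D)``."""

    code: str
    chromosome: ChromosomeToken

    def __post_init__(self) -> None:
        if self.code not in ABERRATION_CODES:
            raise InvariantError("aberration_code", f"{self.code!r} not one of {sorted(ABERRATION_CODES)}")

    def __str__(self) -> str:
        return f"{self.code}{self.chromosome}"


@dataclass(frozen=True)
class VariantDescriptor:
    """A sequence change used in marker names and mutant annotations.

    Positions are base pairs from the ATG start codon (introns excluded)
    for nucleotide changes, or protein residue indices for amino-acid
    changes.  Amino-acid states may be given in one-letter or three-letter
    form; three-letter form is required when the one-letter code collides
    with a nucleotide letter (Cys, Thr, Gly, Ala).  Premature stops use an
    asterisk as the alternate state.
    """

    kind: VariantKind
    position: int
    end_position: Optional[int] = None
    ref_state: Optional[str] = None
    alt_state: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise InvariantError("variant_position", "position must be >= 1")
        if self.kind is VariantKind.NT_DELETION:
            if self.end_position is None or self.end_position < self.position:
                raise InvariantError(
                    "deletion_span", "deletions need end_position >= position"
                )
            return
        if self.end_position is not None:
            raise InvariantError("variant_span", "end_position is for deletions only")
        if self.kind is VariantKind.NT_SUBSTITUTION:
            for state in (self.ref_state, self.alt_state):
                if state not in NUCLEOTIDES:
                    raise InvariantError("nucleotide_state", f"{state!r} is not one of A/C/G/T")
        elif self.kind is VariantKind.AA_SUBSTITUTION:
            for state in (self.ref_state, self.alt_state):
                _check_residue(state)
        elif self.kind is VariantKind.AA_NONSENSE:
            _check_residue(self.ref_state)
            if self.alt_state not in (None, "*"):
                raise InvariantError("nonsense_alt", "nonsense alternate state is the asterisk")
            object.__setattr__(self, "alt_state", "*")

    @property
    def length(self) -> Optional[int]:
        """Deleted length in nucleotides (deletions only)."""
        if self.kind is VariantKind.NT_DELETION:
            return self.end_position - self.position + 1
        return None

    def render(self) -> str:
        if self.kind is VariantKind.NT_DELETION:
            return f"{self.position}_{self.end_position}del"
        if self.kind is VariantKind.AA_NONSENSE:
            return f"{self.ref_state}{self.position}*"
        return f"{self.ref_state}{self.position}{self.alt_state}"

    @property
    def category(self) -> str:
        """Mutant-annotation category: ``null`` for premature stops,
        ``missense`` for amino-acid substitutions."""
        if self.kind is VariantKind.AA_NONSENSE:
            return "null"
        if self.kind is VariantKind.AA_SUBSTITUTION:
            return "missense"
        raise InvariantError("annotation_category", f"no category for {self.kind.value}")


def _check_residue(state: Optional[str]) -> None:
    if state is None:
        raise InvariantError("residue_state", "amino-acid state missing")
    if len(state) == 1:
        if state not in AA1:
            raise InvariantError("residue_state", f"{state!r} is not a standard amino acid")
    elif state not in AA3_TO_1:
        raise InvariantError("residue_state", f"{state!r} is not a standard amino acid")


def residue_one_letter(state: str) -> str:
    """Normalise an amino-acid state to its one-letter code."""
    if state == "*":
        return "*"
    return AA3_TO_1.get(state, state)


@dataclass(frozen=True)
class SuffixTag:
    """Haplotype / mutant / pseudogene suffix: ``_hX``, ``_mX``, ``_pX``.

    Mutant suffixes may carry an amino-acid annotation which renders in
    parentheses, e.g. ``vrn-A1_m2 (null, W91*)``.
    """

    kind: SuffixKind
    index: int
    annotation: Optional[VariantDescriptor] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise InvariantError("suffix_index", "suffix index must be >= 1")
        if self.annotation is not None:
            if self.kind is not SuffixKind.MUTANT:
                raise InvariantError("suffix_annotation", "only mutant suffixes carry annotations")
            if self.annotation.kind not in (
                VariantKind.AA_SUBSTITUTION,
                VariantKind.AA_NONSENSE,
            ):
                raise InvariantError(
                    "suffix_annotation", "mutant annotations are amino-acid changes"
                )

    def render(self) -> str:
        out = f"_{self.kind.value}{self.index}"
        if self.annotation is not None:
            out += f" ({self.annotation.category}, {self.annotation.render()})"
        return out


# --------------------------------------------------------------------------
# the central gene / locus / allele symbol


@dataclass
class GeneSymbol:
    """Structured decomposition of a locus, allele or suffixed designation.

    ``basic_symbol`` is stored uppercase; its rendered case follows
    ``dominance``.  ``species_prefix`` (Ta, Tt, Os, ...) is informational
    and not part of the formal name; ``canonicalize`` moves it aside.
    """

    basic_symbol: str
    species_prefix: Optional[str] = None
    organelle_prefix: Optional[str] = None
    avr_prefix: bool = False
    modifier_prefix: Optional[ModifierPrefix] = None
    temporary_stock: Optional[TemporaryStock] = None
    genome_token: Optional[GenomeToken] = None
    set_number: Optional[int] = None
    member_number: Optional[int] = None
    allele_letters: Optional[str] = None
    dominance: Dominance = Dominance.LOCUS
    suffix: Optional[SuffixTag] = None
    aberration: Optional[Aberration] = None
    italic: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dominance = Dominance(self.dominance)
        self.basic_symbol = self.basic_symbol.upper()
        if not re.fullmatch(r"[A-Z][A-Z0-9]*", self.basic_symbol):
            raise InvariantError(
                "basic_symbol",
                f"{self.basic_symbol!r} must be letters/digits with no '+' or whitespace",
            )
        if re.search(r"[1-7][A-Z]$", self.basic_symbol):
            raise InvariantError(
                "basic_symbol_chromosome",
                f"{self.basic_symbol!r} ends in a chromosome token; chromosome names "
                "do not belong in the basic symbol",
            )
        if self.temporary_stock is not None and self.genome_token is not None:
            raise InvariantError(
                "temporary_vs_genome", "temporary designations carry no genome token"
            )
        if self.temporary_stock is not None and (
            self.set_number is not None
            or self.member_number is not None
            or self.allele_letters is not None
        ):
            raise InvariantError(
                "temporary_components",
                "temporary designations carry no set/member/allele parts",
            )
        if self.genome_token is not None and self.set_number is None:
            raise InvariantError(
                "genome_requires_set", "a genome token is always followed by a set number"
            )
        for n, name in ((self.set_number, "set_number"), (self.member_number, "member_number")):
            if n is not None and n < 1:
                raise InvariantError(name, f"{name} must be >= 1")
        if self.allele_letters is not None:
            if not re.fullmatch(r"[a-z]+", self.allele_letters):
                raise InvariantError(
                    "allele_letters", f"{self.allele_letters!r} must be lowercase letters"
                )
            if self.dominance is Dominance.LOCUS:
                raise InvariantError(
                    "allele_letters_require_non_locus_dominance",
                    "allele letters imply a dominance class; an all-uppercase locus "
                    "name cannot carry them",
                )
        if self.modifier_prefix is not None:
            if self.modifier_prefix.recessive != (self.dominance is Dominance.RECESSIVE):
                raise InvariantError(
                    "modifier_case",
                    "modifier prefix case must agree with dominance "
                    "(I/Su/En non-recessive; i/su/en recessive)",
                )
        if self.organelle_prefix is not None and self.organelle_prefix not in ORGANELLE_PREFIXES:
            raise InvariantError(
                "organelle_prefix",
                f"{self.organelle_prefix!r} is not one of {sorted(ORGANELLE_PREFIXES)}",
            )
        if self.species_prefix is not None and not re.fullmatch(
            r"[A-Z][a-z]", self.species_prefix
        ):
            raise InvariantError(
                "species_prefix", f"{self.species_prefix!r} must be a two-letter code like Ta"
            )

    # -- rendering ---------------------------------------------------------

    def _cased_basic(self) -> str:
        if not self.italic:
            # protein style: every letter a capital Roman letter
            return self.basic_symbol
        if self.dominance is Dominance.LOCUS:
            return self.basic_symbol
        if self.dominance is Dominance.RECESSIVE:
            return self.basic_symbol.lower()
        # dominant / resistance override: capitalised first letter
        return self.basic_symbol[0] + self.basic_symbol[1:].lower()

    def render(self, style: str = "plain") -> str:
        _check_style(style)
        parts: list[str] = []
        if self.species_prefix:
            parts.append(self.species_prefix)
        if self.organelle_prefix:
            parts.append(self.organelle_prefix)
        if self.avr_prefix:
            parts.append("Avr")
        if self.modifier_prefix:
            parts.append(f"{self.modifier_prefix.code}{self.modifier_prefix.serial}-")
        body = self._cased_basic()
        if self.temporary_stock:
            body += f"{self.temporary_stock.abbrev}{self.temporary_stock.serial}"
        if self.genome_token:
            body += "-" + self.genome_token.render(style)
        if self.set_number is not None:
            body += str(self.set_number)
        if self.member_number is not None:
            body += f"-{self.member_number}"
        if self.allele_letters:
            body += self.allele_letters
        if self.suffix:
            body += self.suffix.render()
        if self.aberration:
            body += f"({self.aberration})"
        text = "".join(parts) + body
        return _italicize(text, style, self.italic)


def _check_style(style: str) -> None:
    if style not in ("plain", "markdown", "html"):
        raise ValueError(f"unknown render style {style!r}")


def _italicize(text: str, style: str, italic: bool) -> str:
    if not italic:
        return text
    if style == "markdown":
        return f"*{text}*"
    if style == "html":
        return f"<i>{text}</i>"
    return text


# --------------------------------------------------------------------------
# auxiliary identifier grammars


@dataclass(frozen=True)
class QtlSymbol:
    """QTL designation: Q + trait (<=4 letters, first uppercase) + period +
    laboratory designator + hyphen + chromosome, optionally + period +
    serial.  The abbreviated map-context form drops the chromosome and
    keeps the serial (``QYld.psr.1``)."""

    trait: str
    lab: str
    chromosome: Optional[ChromosomeToken] = None
    serial: Optional[int] = None

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z][A-Za-z]{0,3}", self.trait):
            raise InvariantError(
                "qtl_trait",
                f"{self.trait!r} must be 1-4 letters with an uppercase first letter",
            )
        if not re.fullmatch(r"[a-z]+", self.lab):
            raise InvariantError("qtl_lab", f"{self.lab!r} must be lowercase letters")
        if self.chromosome is None and self.serial is None:
            raise InvariantError(
                "qtl_form", "abbreviated QTL symbols (no chromosome) require a serial"
            )
        if self.serial is not None and self.serial < 1:
            raise InvariantError("qtl_serial", "serial must be >= 1")

    @property
    def abbreviated(self) -> bool:
        return self.chromosome is None

    def render(self, style: str = "plain") -> str:
        _check_style(style)
        out = f"Q{self.trait}.{self.lab}"
        if self.chromosome is not None:
            out += f"-{self.chromosome}"
        if self.serial is not None:
            out += f".{self.serial}"
        return _italicize(out, style, True)


@dataclass(frozen=True)
class CoordinateMarkerName:
    """17-character coordinate SNP name: 3-letter assembly code, 2-digit
    assembly version, understroke, 2-character chromosome, 9-digit
    zero-padded base-pair position."""

    assembly_code: str
    version_major: int
    version_minor: int
    chromosome: ChromosomeToken
    position: int

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z]{3}", self.assembly_code):
            raise InvariantError(
                "assembly_code", f"{self.assembly_code!r} must be exactly 3 uppercase letters"
            )
        for v, name in ((self.version_major, "version_major"), (self.version_minor, "version_minor")):
            if not 0 <= v <= 9:
                raise InvariantError(name, f"{name} must be a single digit")
        if self.chromosome.arm is not None:
            raise InvariantError(
                "marker_chromosome", "coordinate markers use the 2-character chromosome, no arm"
            )
        if not 1 <= self.position <= 999_999_999:
            raise InvariantError("marker_position", "position must be in 1..999999999")

    @property
    def version(self) -> str:
        return f"{self.version_major}.{self.version_minor}"

    def render(self, style: str = "plain") -> str:
        _check_style(style)
        out = (
            f"{self.assembly_code}{self.version_major}{self.version_minor}"
            f"_{self.chromosome}{self.position:09d}"
        )
        assert len(out) == 17
        return out  # marker names are not italicised


@dataclass(frozen=True)
class GeneModelId:
    """Annotation-derived gene identifier.

    Two schemes: the hexaploid reference-sequence scheme
    (``Traes<line><chromosome><version>G<serial>``, e.g.
    ``TraesCS5A02G391700``) and the durum Svevo scheme
    (``TRITD<chromosome>v<version>G<serial>``).  Transcript isoforms are a
    dot suffix (``.1``).
    """

    scheme: str
    chromosome: ChromosomeToken
    annotation_version: str
    serial: int
    line_code: str = ""
    transcript: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scheme not in ("hexaploid_refseq", "durum_svevo"):
            raise InvariantError("gene_model_scheme", f"unknown scheme {self.scheme!r}")
        if self.scheme == "hexaploid_refseq":
            if not re.fullmatch(r"[A-Z]{2}", self.line_code):
                raise InvariantError(
                    "gene_model_line", f"{self.line_code!r} must be a 2-letter line code"
                )
            if not re.fullmatch(r"\d{2}", self.annotation_version):
                raise InvariantError(
                    "gene_model_version", "hexaploid annotation version is a two-digit token"
                )
        else:
            if not re.fullmatch(r"\d", self.annotation_version):
                raise InvariantError(
                    "gene_model_version", "durum annotation version is a single digit"
                )
        if not 0 <= self.serial <= 999_999:
            raise InvariantError("gene_model_serial", "serial must fit in six digits")
        if self.transcript is not None and self.transcript < 1:
            raise InvariantError("gene_model_transcript", "transcript index must be >= 1")

    def render(self, style: str = "plain") -> str:
        _check_style(style)
        if self.scheme == "hexaploid_refseq":
            out = (
                f"Traes{self.line_code}{self.chromosome}"
                f"{self.annotation_version}G{self.serial:06d}"
            )
        else:
            out = f"TRITD{self.chromosome}v{self.annotation_version}G{self.serial:06d}"
        if self.transcript is not None:
            out += f".{self.transcript}"
        return _italicize(out, style, True)


@dataclass(frozen=True)
class VariantMarker:
    """Gene-based variant marker: gene core + underscore + change
    descriptor, with an optional detection-platform prefix
    (``Kasp_Sr13a_S1152F``)."""

    gene: GeneSymbol
    descriptor: VariantDescriptor
    platform: Optional[str] = None

    def __post_init__(self) -> None:
        if self.platform is not None and not re.fullmatch(r"[A-Za-z][A-Za-z0-9]*", self.platform):
            raise InvariantError("platform", f"{self.platform!r} is not a platform token")

    def render(self, style: str = "plain") -> str:
        _check_style(style)
        out = f"{self.gene.render('plain')}_{self.descriptor.render()}"
        if self.platform:
            out = f"{self.platform}_{out}"
        return out


# --------------------------------------------------------------------------
# genotype and genome formulae


@dataclass(frozen=True)
class GenotypeFormula:
    """Genotype at one linkage group, maternal alleles first, separated by
    a slash.  For linked two-locus genotypes the alleles of each homologue
    are concatenated (``AB/ab`` coupling, ``Ab/aB`` repulsion)."""

    maternal: tuple
    paternal: tuple
    linkage_phase: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.maternal or not self.paternal:
            raise InvariantError("genotype_sides", "both maternal and paternal alleles required")
        if self.linkage_phase is not None and self.linkage_phase not in ("coupling", "repulsion"):
            raise InvariantError("linkage_phase", f"unknown phase {self.linkage_phase!r}")
        if self.linkage_phase is not None and len(self.maternal) != 2:
            raise InvariantError("linkage_phase", "linkage phases describe two-locus genotypes")

    @classmethod
    def from_linkage(
        cls,
        locus1: tuple,
        locus2: tuple,
        phase: str,
    ) -> "GenotypeFormula":
        """Arrange two (dominant, recessive) allele pairs by phase:
        coupling puts both dominants on one homologue, repulsion splits
        them."""
        d1, r1 = locus1
        d2, r2 = locus2
        if phase == "coupling":
            return cls(maternal=(d1, d2), paternal=(r1, r2), linkage_phase=phase)
        if phase == "repulsion":
            return cls(maternal=(d1, r2), paternal=(r1, d2), linkage_phase=phase)
        raise InvariantError("linkage_phase", f"unknown phase {phase!r}")

    def render(self, style: str = "plain") -> str:
        _check_style(style)
        top = "".join(s.render("plain") for s in self.maternal)
        bottom = "".join(s.render("plain") for s in self.paternal)
        return _italicize(f"{top}/{bottom}", style, True)


def genotype_string(formula: GenotypeFormula, style: str = "plain") -> str:
    """Render a genotype formula; maternal alleles come first."""
    return formula.render(style)


@dataclass(frozen=True)
class GenomeFormulaSpec:
    """Cytological genome formula: basic number x, ploidy coefficient, and
    the derived zygotic number 2n = ploidy * x."""

    basic_number: int
    ploidy: int

    def __post_init__(self) -> None:
        if self.basic_number < 1:
            raise InvariantError("basic_number", "basic chromosome number must be >= 1")
        if self.ploidy < 2:
            raise InvariantError("ploidy", "ploidy must be >= 2")

    @property
    def zygotic_number(self) -> int:
        return self.ploidy * self.basic_number

    def render(self, style: str = "plain") -> str:
        _check_style(style)
        if style == "markdown":
            return f"2*n* = {self.ploidy}*x* = {self.zygotic_number}"
        if style == "html":
            return f"2<i>n</i> = {self.ploidy}<i>x</i> = {self.zygotic_number}"
        return f"2n = {self.ploidy}x = {self.zygotic_number}"


def genome_formula(basic_number: int, ploidy: int) -> GenomeFormulaSpec:
    """Build the genome formula, e.g. ``genome_formula(7, 6)`` for bread
    wheat gives 2n = 6x = 42."""
    return GenomeFormulaSpec(basic_number=basic_number, ploidy=ploidy)


# --------------------------------------------------------------------------
# operations on symbols

Renderable = Union[
    GeneSymbol,
    QtlSymbol,
    CoordinateMarkerName,
    GeneModelId,
    VariantMarker,
    GenotypeFormula,
    GenomeFormulaSpec,
]


def render(symbol: Renderable, style: str = "plain") -> str:
    """Render any symbol type in ``plain``, ``markdown`` or ``html`` style.

    Plain style is the canonical comparison form: it drops italics and
    writes wild-relative genome superscripts with a caret (``EPS-A^m1``).
    """
    return symbol.render(style)


def canonicalize(symbol: GeneSymbol) -> GeneSymbol:
    """Return the canonical form of a symbol: the informal species prefix
    is moved into ``metadata['species_prefix']``.  Idempotent."""
    if symbol.species_prefix is None:
        return symbol
    meta = dict(symbol.metadata)
    meta["species_prefix"] = symbol.species_prefix
    return replace(symbol, species_prefix=None, metadata=meta)


def canonical_equal(a: GeneSymbol, b: GeneSymbol) -> bool:
    """Compare two symbols by their canonical plain rendering."""
    return canonicalize(a).render("plain") == canonicalize(b).render("plain")


def protein_symbol(gene: GeneSymbol) -> GeneSymbol:
    """Derive the protein symbol from a gene or allele symbol: non-italic,
    every letter of the basic symbol capital, allele letters kept
    lowercase (``Sr9a`` -> ``SR9a``).  Suffixed designations (haplotypes,
    mutants, pseudogenes) have no protein form."""
    if gene.suffix is not None:
        raise InvariantError(
            "protein_of_suffixed",
            "no protein symbol is defined for haplotype/mutant/pseudogene designations",
        )
    return replace(gene, italic=False, metadata=dict(gene.metadata))


# --------------------------------------------------------------------------
# constructors used by the command-line surface


def build_coordinate_marker(
    assembly_code: str,
    version: str,
    chromosome: str | ChromosomeToken,
    position: int,
) -> CoordinateMarkerName:
    """Assemble a coordinate marker from its fields.

    ``version`` is the dotted assembly version, e.g. ``"2.1"``.
    """
    m = re.fullmatch(r"(\d)\.(\d)", str(version))
    if m is None:
        raise InvariantError("marker_version", f"{version!r} must look like '2.1'")
    if isinstance(chromosome, str):
        chromosome = ChromosomeToken.from_text(chromosome)
    return CoordinateMarkerName(
        assembly_code=assembly_code,
        version_major=int(m.group(1)),
        version_minor=int(m.group(2)),
        chromosome=chromosome,
        position=position,
    )


def build_variant_marker(
    gene: GeneSymbol,
    descriptor: VariantDescriptor,
    platform: Optional[str] = None,
) -> VariantMarker:
    """Assemble a gene-based variant marker, forcing three-letter
    amino-acid codes whenever a one-letter residue could be mistaken for a
    nucleotide (Cys, Thr, Gly, Ala)."""
    if descriptor.kind in (VariantKind.AA_SUBSTITUTION, VariantKind.AA_NONSENSE):
        ref1 = residue_one_letter(descriptor.ref_state)
        alt1 = residue_one_letter(descriptor.alt_state or "*")
        confusable = ref1 in CONFUSABLE_RESIDUES or (
            alt1 != "*" and alt1 in CONFUSABLE_RESIDUES
        )
        if confusable:
            new_ref = AA1_TO_3[ref1]
            new_alt = descriptor.alt_state if alt1 == "*" else AA1_TO_3[alt1]
            descriptor = replace(descriptor, ref_state=new_ref, alt_state=new_alt)
    return VariantMarker(gene=gene, descriptor=descriptor, platform=platform)
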