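"""Rule-based linter for genetic symbols.

Each rule in the catalogue enforces one guideline.  ``validate`` is a
pure function of (text, context, config): it never raises, returning a
deterministic, span-ordered list of findings instead.  Severities follow
a simple policy: grammar violations are errors, style deviations phrased
as "should" are warnings, historical/contextual notes are informational.

Rule catalogue
--------------
R00  symbol cannot be parsed at all (catalogue extension for garbage input)
R01  the plus sign is not used in symbolisation
R02  one line only; no superscripts/subscripts except wild-relative genomes
R03  locus names are written all-uppercase (case encodes dominance)
R04  allele symbol case encodes dominance (upper first letter = dominant)
R05  chromosome names do not appear inside the basic symbol
R06  allele letters are lowercase, after the designation
R07  suffix grammar _h/_m/_p with positive sequential indices
R08  temporary stock abbreviations have at most 3 letters
R09  QTL trait designators have at most 4 letters, first uppercase
R10  resistance alleles take an uppercase first letter even when recessive
R11  coordinate marker names have fixed field widths (17 characters)
R12  three-letter amino-acid codes for residues confusable with bases
R13  genome letter drawn from the configured sub-genome alphabet
R14  genotype formulae are slash-separated, maternal alleles first
R15  gene-complex members numbered by hyphen + Arabic numeral
R16  a homoeologous set number is not a chromosome number
R17  species prefixes are informational, not part of the formal name
R18  organelle prefixes restricted to Mt / Pt / Cp

A01-A04 are registry-audit findings (duplicates, case-collisions, allele
letter gaps, suffix index gaps); they are reported by ``audit_registry``
in :mod:`wheatnom.registry`, never by ``validate``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Tuple

from .config import DEFAULT_CONFIG, NomenConfig
from .errors import NomenclatureError, ParseError
from .model import (
    CONFUSABLE_RESIDUES,
    Dominance,
    GeneSymbol,
    VariantKind,
    build_variant_marker,
    canonicalize,
    residue_one_letter,
)
from .parse import (
    SymbolClass,
    _COORD_INTENT,
    _GENE_MODEL_INTENT,
    _QTL_INTENT,
    _variant_shape,
    classify,
    parse_any,
    parse_coordinate_marker,
    parse_gene_model,
    parse_qtl,
    parse_symbol,
    parse_variant_marker,
    strip_markdown,
)

RULE_CATALOGUE: dict[str, tuple[str, str]] = {
    "R00": ("error", "symbol cannot be parsed"),
    "R01": ("error", "plus sign in symbol"),
    "R02": ("error", "multi-line or superscript/subscript text"),
    "R03": ("error", "letter case encodes no dominance class"),
    "R04": ("error", "allele letters on an all-uppercase locus name"),
    "R05": ("error", "chromosome name inside the basic symbol"),
    "R06": ("error", "allele letters must be lowercase"),
    "R07": ("error", "malformed haplotype/mutant/pseudogene suffix"),
    "R08": ("error", "temporary stock abbreviation exceeds 3 letters"),
    "R09": ("error", "QTL trait designator malformed"),
    "R10": ("warning", "resistance allele written with lowercase first letter"),
    "R11": ("error", "coordinate marker field widths violated"),
    "R12": ("warning", "one-letter amino-acid code confusable with a nucleotide"),
    "R13": ("error", "genome letter outside the configured alphabet"),
    "R14": ("error", "malformed genotype formula"),
    "R15": ("error", "gene-complex member number malformed"),
    "R16": ("info", "set number could be mistaken for a chromosome number"),
    "R17": ("info", "species prefix is not part of the formal name"),
    "R18": ("error", "organelle prefix must be Mt, Pt or Cp"),
    "A01": ("error", "duplicate canonical symbol in registry"),
    "A02": ("info", "case-only collision (dominance pair at one locus)"),
    "A03": ("warning", "allele letter series has gaps"),
    "A04": ("warning", "suffix index series has gaps"),
}

_SUPERSCRIPTS = "⁰¹²³⁴⁵⁶⁷⁸⁹" \
    "₀₁₂₃₄₅₆₇₈₉ⁱⁿ"


@dataclass(frozen=True)
class Finding:
    """One linter hit: rule, severity, character span, message and an
    optional suggested repair."""

    rule_id: str
    severity: str
    span: Tuple[int, int]
    message: str
    suggestion: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "severity": self.severity,
            "span": [self.span[0], self.span[1]],
            "message": self.message,
            "suggestion": self.suggestion,
        }


@dataclass(frozen=True)
class LintContext:
    """Linting context: resistance-gene mode relaxes the case rules per
    R10 (resistance alleles keep uppercase first letters regardless of
    inheritance)."""

    resistance_gene: bool = False
    config: NomenConfig = field(default_factory=lambda: DEFAULT_CONFIG)


def _finding(rule: str, span: Tuple[int, int], message: str,
             suggestion: Optional[str] = None, severity: Optional[str] = None) -> Finding:
    return Finding(
        rule_id=rule,
        severity=severity or RULE_CATALOGUE[rule][0],
        span=span,
        message=message,
        suggestion=suggestion,
    )


def validate(text: str, context: Optional[LintContext] = None) -> List[Finding]:
    """Lint one symbol string; returns findings ordered by span.

    Never raises: unparseable input yields an R00 error finding.
    """
    ctx = context or LintContext()
    raw = str(text)
    t = strip_markdown(raw)
    findings: List[Finding] = []
    if not t:
        return [_finding("R00", (0, len(raw)), "empty symbol")]

    # character-level screens ------------------------------------------------
    for i, ch in enumerate(t):
        if ch == "+":
            findings.append(_finding(
                "R01", (i, i + 1),
                "the plus sign is not used in the symbolisation of hereditary factors",
                suggestion=t.replace("+", ""),
            ))
    cleaned = t.replace("+", "")
    bad_chars = [c for c in cleaned if c in "\n\r\t" or c in _SUPERSCRIPTS]
    if bad_chars:
        stripped = "".join(c for c in cleaned if c not in "\n\r\t" + _SUPERSCRIPTS)
        findings.append(_finding(
            "R02", (0, len(t)),
            "symbols are written on one line without superscripts or subscripts",
            suggestion=stripped or None,
        ))
        cleaned = stripped
    # carets are legal only as the wild-relative genome marker (A^m)
    stray = [
        m.start() for m in re.finditer(r"\^", cleaned)
        if not (m.start() >= 1
                and cleaned[m.start() - 1].isupper()
                and m.start() + 1 < len(cleaned)
                and cleaned[m.start() + 1].islower())
    ]
    if stray:
        fixed = "".join(c for i, c in enumerate(cleaned) if not (c == "^" and i in stray))
        findings.append(_finding(
            "R02", (stray[0], stray[0] + 1),
            "superscripts are reserved for wild-relative genome markers",
            suggestion=fixed or None,
        ))
        cleaned = fixed
    if not cleaned:
        return sorted(findings, key=lambda f: (f.span, f.rule_id))

    # lowercase organelle prefix ----------------------------------------------
    m = re.match(r"(mt|pt|cp)(?=[A-Z])", cleaned)
    if m:
        fixed = m.group(1).capitalize() + cleaned[2:]
        findings.append(_finding(
            "R18", (0, 2),
            f"organelle prefix {m.group(1)!r} must be written {m.group(1).capitalize()!r}",
            suggestion=fixed,
        ))
        cleaned = fixed

    findings.extend(_dispatch(cleaned, ctx))
    return sorted(findings, key=lambda f: (f.span, f.rule_id))


def _dispatch(cleaned: str, ctx: LintContext) -> List[Finding]:
    whole = (0, len(cleaned))
    try:
        if _GENE_MODEL_INTENT.match(cleaned):
            try:
                parse_gene_model(cleaned)
            except ParseError as e:
                return [_finding("R00", whole, str(e))]
            return []
        if _COORD_INTENT.match(cleaned):
            try:
                parse_coordinate_marker(cleaned)
            except ParseError as e:
                start = e.offset if e.offset is not None else 0
                return [_finding("R11", (start, len(cleaned)), str(e))]
            return []
        if "/" in cleaned:
            return _validate_genotype(cleaned, ctx)
        if _QTL_INTENT.match(cleaned):
            try:
                parse_qtl(cleaned)
            except ParseError as e:
                return [_finding(e.rule or "R00", _token_span(cleaned, e.token), str(e))]
            return []
        if _variant_shape(cleaned):
            return _validate_variant(cleaned, ctx)
        return _validate_symbol(cleaned, ctx)
    except NomenclatureError as e:  # defensive: linter never raises
        return [_finding("R00", whole, str(e))]


def _token_span(text: str, token: Optional[str]) -> Tuple[int, int]:
    if token:
        idx = text.find(token)
        if idx >= 0:
            return (idx, idx + len(token))
    return (0, len(text))


def _validate_symbol(cleaned: str, ctx: LintContext) -> List[Finding]:
    try:
        sym = parse_symbol(cleaned, ctx.config)
    except ParseError as e:
        return [_finding(
            e.rule or "R00", _token_span(cleaned, e.token), str(e),
            suggestion=e.suggestion,
        )]
    findings: List[Finding] = []
    if sym.genome_token is not None and sym.genome_token.letter not in ctx.config.genome_alphabet:
        findings.append(_finding(
            "R13", _token_span(cleaned, sym.genome_token.letter),
            f"genome letter {sym.genome_token.letter!r} is outside the configured "
            f"alphabet {{{', '.join(sorted(ctx.config.genome_alphabet))}}}",
        ))
    if sym.species_prefix is not None:
        findings.append(_finding(
            "R17", (0, 2),
            f"species prefix {sym.species_prefix!r} is informational and not part "
            "of the formal gene name",
            suggestion=canonicalize(sym).render("plain"),
        ))
    if ctx.resistance_gene and sym.dominance is Dominance.RECESSIVE:
        fixed = replace(
            sym, dominance=Dominance.RESISTANCE_OVERRIDE, metadata=dict(sym.metadata)
        )
        findings.append(_finding(
            "R10", (0, len(cleaned)),
            "alleles conferring resistance take an uppercase first letter even "
            "when they inherit as recessives",
            suggestion=fixed.render("plain"),
        ))
    if (
        ctx.config.strictness == "strict"
        and sym.genome_token is not None
        and sym.set_number is not None
        and sym.set_number <= 7
    ):
        findings.append(_finding(
            "R16", (0, len(cleaned)),
            f"set number {sym.set_number} indicates order of discovery and must "
            "not be confused with a chromosome number",
        ))
    if sym.allele_letters is not None and len(sym.allele_letters) >= 2 and sym.suffix is not None:
        findings.append(_finding(
            "R07", (0, len(cleaned)),
            "suffix on a recombined (two-letter) allele: the guidelines do not "
            "define this combination; accepted as written",
            severity="info",
        ))
    return findings


def _validate_genotype(cleaned: str, ctx: LintContext) -> List[Finding]:
    findings: List[Finding] = []
    sides = cleaned.split("/")
    if len(sides) != 2 or any(not s for s in sides):
        return [_finding(
            "R14", (0, len(cleaned)),
            "a genotype formula is two allele symbols separated by one slash, "
            "maternal alleles first",
        )]
    offset = 0
    for side in sides:
        span = (offset, offset + len(side))
        try:
            parse_symbol(side, ctx.config)
        except ParseError:
            # classic linkage notation concatenates single-letter alleles
            # of two loci on one homologue (AB/ab, Ab/aB)
            if not re.fullmatch(r"[A-Za-z]{2,4}", side):
                findings.append(_finding(
                    "R14", span,
                    f"genotype side {side!r} is not a well-formed allele symbol",
                ))
        offset += len(side) + 1
    return findings


def _validate_variant(cleaned: str, ctx: LintContext) -> List[Finding]:
    try:
        marker = parse_variant_marker(cleaned, ctx.config)
    except ParseError as e:
        return [_finding(
            e.rule or "R00", _token_span(cleaned, e.token), str(e),
            suggestion=e.suggestion,
        )]
    findings: List[Finding] = []
    d = marker.descriptor
    if d.kind in (VariantKind.AA_SUBSTITUTION, VariantKind.AA_NONSENSE):
        confusable = [
            s for s in (d.ref_state, d.alt_state)
            if s is not None and len(s) == 1 and s in CONFUSABLE_RESIDUES
        ]
        if confusable:
            fixed = build_variant_marker(marker.gene, d, marker.platform).render("plain")
            findings.append(_finding(
                "R12", _token_span(cleaned, d.render()),
                f"residue(s) {', '.join(confusable)} could be mistaken for "
                "nucleotides; use the three-letter amino-acid code",
                suggestion=fixed if fixed != cleaned else None,
            ))
    g = marker.gene
    if g.genome_token is not None and g.genome_token.letter not in ctx.config.genome_alphabet:
        findings.append(_finding(
            "R13", _token_span(cleaned, g.genome_token.letter),
            f"genome letter {g.genome_token.letter!r} is outside the configured alphabet",
        ))
    return findings


def suggest_fix(finding: Finding, original: str) -> Optional[str]:
    """Return the corrected text for a finding, if an unambiguous repair
    exists.  Repairs that would require information not present in the
    string (e.g. the true set number behind a chromosome-named locus, rule
    R05) return None."""
    return finding.suggestion


# --------------------------------------------------------------------------
# report rows


@dataclass(frozen=True)
class LintReportRow:
    """One row of a lint report; ``ok`` is true iff the symbol produced
    zero error-severity findings."""

    input: str
    symbol_class: str
    ok: bool
    findings: Tuple[Finding, ...]
    canonical: str

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "symbol_class": self.symbol_class,
            "ok": self.ok,
            "findings": [f.to_dict() for f in self.findings],
            "canonical": self.canonical,
        }


def canonical_key(text: str, config: NomenConfig = DEFAULT_CONFIG) -> str:
    """Canonical plain rendering used as a registry key; falls back to the
    stripped input when the text does not parse."""
    t = strip_markdown(str(text))
    try:
        cls, obj = parse_any(t, config)
    except NomenclatureError:
        return t
    if isinstance(obj, GeneSymbol):
        return canonicalize(obj).render("plain")
    if isinstance(obj, str):
        return obj
    return obj.render("plain")


def lint_symbol(text: str, context: Optional[LintContext] = None) -> LintReportRow:
    ctx = context or LintContext()
    findings = validate(text, ctx)
    ok = not any(f.severity == "error" for f in findings)
    return LintReportRow(
        input=str(text),
        symbol_class=classify(text, ctx.config).value,
        ok=ok,
        findings=tuple(findings),
        canonical=canonical_key(text, ctx.config) if ok else "",
    )


def lint_symbols(texts: Iterable[str], context: Optional[LintContext] = None) -> List[LintReportRow]:
    """Lint a sequence of symbols, preserving input order."""
    ctx = context or LintContext()
    return [lint_symbol(t, ctx) for t in texts]
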