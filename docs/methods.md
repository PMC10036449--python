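# Methods

This note records how wheatnom models the wheat gene-nomenclature
convention, the choices made where the convention is silent, and what the
test suite does and does not demonstrate.

## The model

A genetic symbol is decomposed into orthogonal parts rather than stored
as a string:

* an optional informal **species prefix** (two-letter code: Ta, Tt, Os,
  …), which is metadata, never part of the formal name;
* an optional **organelle prefix** restricted to Mt/Pt/Cp
  (mitochondrion, plastid, chloroplast);
* an optional **modifier prefix** for inhibitors/suppressors/enhancers
  (I/Su/En, or i/su/en for recessive modifiers) with a serial number, the
  remainder of the symbol being the affected gene (Su1-Ph1);
* an optional **Avr prefix** for the pathogen avirulence counterpart of a
  resistance gene (AvrLr14a);
* the **basic symbol**, stored uppercase (letters and digits, e.g. VRN,
  AGL12, GW2);
* either a **temporary stock** record (title-case abbreviation of at most
  three letters + serial, e.g. Fr1 in SRFr1) or the regular designation:
  an optional **sub-genome token** (one uppercase letter, optionally with
  a wild-relative superscript marker, A^m), a **homoeologous set /
  series number**, an optional dash-separated **member number**
  (gene-complex member or paralogue), and optional lowercase **allele
  letters** (two letters for recombined alleles such as Lr14ab);
* a **dominance class** — locus, dominant, recessive, or the
  resistance-case override;
* an optional **suffix** `_hX` / `_mX` / `_pX` (haplotype, induced
  mutant, pseudogene) with index ≥ 1, mutant suffixes optionally
  annotated with an amino-acid change ("(missense, V6M)",
  "(null, W91*)");
* an optional **aberration** note, e.g. the transposed location in
  HP(Tp6D).

Two normalisations keep the model free of internally inconsistent
states. First, *italics are typography, not data*: a boolean flag plus
three render styles (plain / markdown / html) replace typesetting, and
the plain rendering is the canonical comparison form. Superscript
wild-relative markers use a caret in plain style (EPS-A^m1) and `<sup>`
in HTML. Second, *letter case is derived, not stored*: the basic symbol
is kept uppercase and the dominance field decides the rendered case
(locus → VRN, dominant → Vrn, recessive → vrn, resistance override →
Sr even for recessive inheritance). Dominance is therefore recoverable
from the rendered case alone, except under the resistance override,
which must be requested explicitly.

Protein symbols are the same object with the italic flag cleared; a
non-italic symbol renders every basic-symbol letter uppercase while
keeping allele letters lowercase (gene Sr9a → protein SR9a). Suffixed
designations have no protein form and raise.

## Parsing

Parsing is strict and case-sensitive because case is semantic; the only
input normalisation is stripping symmetric markdown italic asterisks, so
symbols copied from typeset text parse. The classifier is total: any
printable string maps to exactly one of thirteen classes, with `unknown`
as a value rather than an error, using the precedence

gene_model > coordinate_marker > genotype_formula > qtl > variant_marker
> suffixed > gene_complex_member > allele > locus > temporary > unknown.

The template-like grammars (gene models, 17-character coordinate
markers) win over generic symbol shapes because they are the most
specific. Coordinate-marker intent is recognised by the prefix shape
`3 capitals + 2 digits + underscore + digit + letter`; the trailing
digit+letter requirement keeps symbols like `ABC12_h1` (a haplotype of
locus ABC12) out of the marker grammar.

The segment after a hyphen is the one genuinely ambiguous spot: the
convention writes both SEP1-A1 (genome + set) and SEP1-1 (paralogue
number) without stating a rule. wheatnom disambiguates by first-character
class — uppercase letter: genome token; digits: member number; digit
followed by an uppercase letter: a chromosome token, which is illegal
inside a symbol (rule R05). A consequence worth knowing: dash-numbered
set names without a genome letter (ADH-1, RHT-1) parse with a member
number and classify as `gene_complex_member`; the string syntax does not
distinguish them from paralogues, and no information is lost (the
rendering round-trips exactly).

When both states of a point descriptor are single letters drawn from
A/C/G/T, the change is read as a nucleotide substitution. This is
exactly the ambiguity behind the three-letter-code rule (R12): the four
amino acids Cys, Thr, Gly, Ala collide with nucleotide letters, so the
builder always writes them (and their partners) in three-letter form,
and the linter flags one-letter uses as warnings without rejecting them.

## The linter

`validate(text, context)` is a pure function of (text, context, config)
returning findings ordered by character span; it never raises. Severity
policy: grammar violations are errors; deviations the convention phrases
as "should" are warnings (R10 resistance case, R12 confusable residues);
historical or contextual notes are info (R17 species prefixes, R16
set-number/chromosome confusion). A symbol "lints clean" when it has
zero error-severity findings. Suggested fixes are attached only when the
repair is unambiguous — stripping a plus sign, lowercasing an allele
letter, capitalising an organelle prefix — and never when information is
missing from the string (the true set number behind VRN-5A is
unknowable, so R05 offers no fix).

Two rules deserve a note. R16 (a homoeologous set number "should not be
confused with" the chromosome number) is not decidable from a string, so
it is an informational reminder emitted only in strict mode for genome +
set symbols with set ≤ 7. R00 is a catalogue extension: the finding
issued when input matches no grammar at all, keeping the linter total.

Registry auditing reports four conditions under separate ids: A01
duplicate canonical keys (error), A02 case-only collisions — which are
usually a legitimate dominance pair of one locus, hence info — A03
allele-letter gaps and A04 suffix-index gaps (warnings, since historical
catalogues do legitimately skip letters). Next-designation logic assigns
allele letters in sequential alphabetical order with double letters
(aa, ab, …) after z — the convention is silent past z, and the choice is
isolated in one generator function — and suffix indices as max + 1, with
a gap warning when the existing series is non-consecutive. The letter
"a" at a new locus is implicitly reserved for the prototype genotype
(Chinese Spring preferred). The one-crossover-unit ceiling suggested for
designating recombined alleles is exposed as a registry metadata
constant, not computed, since it needs mapping data the registry does
not hold.

Canonicalisation moves the informal species prefix into metadata and is
idempotent. For prefix-free symbols `render(canonicalize(s)) ==
render(s)`; for species-prefixed input the canonical rendering drops the
prefix by design (TaAP1-A1 → AP1-A1), which is the point of the
operation.

## Synthetic fixtures

The fixture generator emulates the symbol population a curation pipeline
would see: all thirteen symbol classes, with sampling weights (documented
in the module docstring) tilted toward the common classes — loci and
alleles roughly half the corpus, suffixed designations 14%, the
identifier grammars (QTL, markers, gene models) about a quarter,
decorated rarities (organelle/species/Avr prefixes, aberrations,
wild-relative markers) the remainder. Valid cases are built as model
objects and rendered, so validity is by construction; invalid cases
apply exactly one rule-violating mutation and record the planted rule.
Fourteen rules are plantable (R01–R09, R11, R13–R15, R18); the
warning/info rules (R10, R12, R16, R17) are exercised by directed unit
tests instead, because a planted fault must surface as an error finding.

What passing these suites shows: the grammar, renderer and linter are
mutually consistent (parse∘render identity on 10⁴ seeded symbols,
exact planted-rule recovery on 10³ faults, canonical idempotence,
determinism), and every worked example printed in the guidelines is
reproduced exactly. What it does not show: behaviour on the long tail of
*historical* wheat names (pre-guideline RFLP/SSR lab codes, legacy
translocation descriptions), which are explicitly out of the modern
convention and of this package; and scientific correctness of curation
decisions (homoeology evidence, priority between species names), which
are human judgements.

## Numerical and interface choices

* Genome alphabet defaults to {A, B, D}; introgression genomes (R, S,
  …) are admitted by configuration (`genome_alphabet=ABDR`), and the
  guidelines' own examples of alien genomes motivate keeping this open.
* Allele letters default to at most 2 (covers recombined alleles);
  configurable.
* Coordinate positions are 1-based assembly coordinates, stored with
  padding stripped; the rendered field is always 9 digits, making every
  coordinate marker exactly 17 characters.
* Suffix indices, set/member numbers, serials: positive integers without
  leading zeros; violations are parse errors, not silent corrections.
* TSV is the primary tabular dialect (UTF-8, header row, tab-separated);
  CSV is accepted by file extension. Machine output goes to stdout,
  summaries to stderr, and the lint exit status is non-zero iff any
  error finding occurred — the exit-status contract a CI gate needs.
* Test problem sizes: the acceptance property suites run 10⁴ valid and
  10³ invalid fixtures, sizes at which every symbol class and plantable
  rule appears hundreds of times while the whole suite stays in the
  seconds range.

## Known limitations

* Whole-token parsing only: the package does not mine symbols out of
  running prose.
* The genotype-formula grammar validates the slash form and each side,
  but cannot verify that the maternal allele truly comes first — parental
  origin is not in the string.
* Case-mangled organelle prefixes are only detectable in lowercase form
  (mtATP1); MTATP1 is indistinguishable from a basic symbol.
* Enzyme (E.C.) nomenclature and publication typesetting are out of
  scope; historical marker symbol families are deliberately unsupported.
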