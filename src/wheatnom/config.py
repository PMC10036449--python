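"""Runtime configuration for parsing and linting.

The guidelines leave a few vocabularies open (which sub-genome letters are
legal, how many allele letters a recombined allele may carry, how pedantic
the linter should be).  Those knobs live here so that every parser and
linter entry point can share one immutable configuration object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

#: Organelle prefixes for extra-chromosomal genes (mitochondrion, plastid,
#: chloroplast).  This set is closed by the guidelines.
ORGANELLE_PREFIXES: frozenset[str] = frozenset({"Mt", "Pt", "Cp"})

#: Chromosomal aberration codes: deficiency, duplication, inversion,
#: translocation, transposition.
ABERRATION_CODES: frozenset[str] = frozenset({"Df", "Dp", "Inv", "T", "Tp"})

#: Inhibitor / suppressor / enhancer prefixes; lowercase forms mark
#: recessive modifiers.
MODIFIER_CODES: frozenset[str] = frozenset({"I", "Su", "En", "i", "su", "en"})


@dataclass(frozen=True)
class NomenConfig:
    """Tunable parameters shared by the parser and the linter.

    Attributes
    ----------
    genome_alphabet:
        Sub-genome letters accepted for the hyphenated locus designation.
        Defaults to the hexaploid bread-wheat sub-genomes A, B and D;
        extend it for introgression genomes (R, S, ...) as needed.
    allele_letter_bound:
        Maximum number of trailing lowercase allele letters.  Two covers
        recombined alleles such as ``ab``.
    strictness:
        ``"normal"`` or ``"strict"``.  Strict mode adds informational
        findings for constructs that are legal but easy to misread (for
        example a homoeologous set number that could be mistaken for a
        chromosome number).
    """

    genome_alphabet: frozenset[str] = field(default_factory=lambda: frozenset("ABD"))
    allele_letter_bound: int = 2
    strictness: str = "normal"

    def __post_init__(self) -> None:
        if self.strictness not in ("normal", "strict"):
            raise ValueError(f"unknown strictness {self.strictness!r}")
        if self.allele_letter_bound < 1:
            raise ValueError("allele_letter_bound must be >= 1")


DEFAULT_CONFIG = NomenConfig()


def load_config(path: str | Path) -> NomenConfig:
    """Read a plain ``key = value`` configuration file.

    Recognised keys: ``genome_alphabet`` (string of letters),
    ``strictness``, ``allele_letter_bound``.  Unknown keys raise
    ``ValueError`` so typos do not pass silently.
    """
    kwargs: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "genome_alphabet":
            kwargs["genome_alphabet"] = frozenset(value.replace(",", ""))
        elif key == "strictness":
            kwargs["strictness"] = value
        elif key == "allele_letter_bound":
            kwargs["allele_letter_bound"] = int(value)
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    return NomenConfig(**kwargs)
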