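"""Catalogue registry: persistence, auditing and next-designation logic.

A registry is a small catalogue of named symbols keyed by canonical plain
rendering.  It supports the two curation queries the guidelines call for:
the next free allele letter at a locus (sequential alphabetical order,
with ``a`` reserved for the prototype genotype, preferentially Chinese
Spring) and the next free haplotype/mutant/pseudogene suffix index
(consecutive ascending numbering).
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Tuple

import pandas as pd

from .config import DEFAULT_CONFIG, NomenConfig
from .errors import NomenclatureError
from .model import Dominance, GeneSymbol, SuffixKind
from .parse import SymbolClass, classify, parse_symbol, strip_markdown
from .rules import Finding, RULE_CATALOGUE, canonical_key

#: distance in crossover units below which two recombining resistance
#: factors may be designated as a single combined allele (e.g. Lr14ab)
RECOMBINED_ALLELE_MAX_CROSSOVER_UNITS: float = 1.0

TSV_COLUMNS = ["symbol", "class", "gene_model_id", "prototype_genotype", "source"]


@dataclass(frozen=True)
class RegistryEntry:
    symbol: str
    symbol_class: str = ""
    gene_model_id: Optional[str] = None
    prototype_genotype: Optional[str] = None
    source: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "symbol": self.symbol,
            "class": self.symbol_class,
            "gene_model_id": self.gene_model_id,
            "prototype_genotype": self.prototype_genotype,
            "source": self.source,
        }


@dataclass
class Registry:
    """Ordered collection of catalogue entries.

    Duplicate canonical keys are retained on load so that
    :func:`audit_registry` can report them; lookups resolve to the first
    entry with a given key.
    """

    entries: List[RegistryEntry] = field(default_factory=list)
    config: NomenConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    def add(self, entry: RegistryEntry | str, **kwargs) -> RegistryEntry:
        if isinstance(entry, str):
            entry = RegistryEntry(
                symbol=entry,
                symbol_class=kwargs.pop("symbol_class", classify(entry, self.config).value),
                **kwargs,
            )
        self.entries.append(entry)
        return entry

    def keys(self) -> List[str]:
        return [canonical_key(e.symbol, self.config) for e in self.entries]

    def __contains__(self, symbol: str) -> bool:
        key = canonical_key(symbol, self.config)
        return key in set(self.keys())

    def __len__(self) -> int:
        return len(self.entries)

    # -- persistence -------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path, config: NomenConfig = DEFAULT_CONFIG) -> "Registry":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in ("symbol",) if c not in df.columns]
        if missing:
            raise ValueError(f"registry table lacks required column(s): {missing}")
        reg = cls(config=config)
        for _, row in df.iterrows():
            reg.add(RegistryEntry(
                symbol=row["symbol"],
                symbol_class=row.get("class", "") or classify(row["symbol"], config).value,
                gene_model_id=row.get("gene_model_id", "") or None,
                prototype_genotype=row.get("prototype_genotype", "") or None,
                source=row.get("source", "") or None,
            ))
        return reg

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [
                {
                    "symbol": e.symbol,
                    "class": e.symbol_class,
                    "gene_model_id": e.gene_model_id or "",
                    "prototype_genotype": e.prototype_genotype or "",
                    "source": e.source or "",
                }
                for e in self.entries
            ],
            columns=TSV_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps([e.to_dict() for e in self.entries], indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


# --------------------------------------------------------------------------
# designation sequences


def allele_letter_sequence() -> Iterator[str]:
    """Yield allele letters in sequential order: a..z, then aa, ab, ..."""
    for letter in string.ascii_lowercase:
        yield letter
    for size in itertools.count(2):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)


def _locus_core(symbol: GeneSymbol) -> str:
    """Case-insensitive key identifying the locus an allele belongs to
    (allele letters, suffixes and species prefixes stripped)."""
    core = replace(
        symbol,
        allele_letters=None,
        suffix=None,
        species_prefix=None,
        dominance=symbol.dominance,
        metadata={},
    )
    return core.render("plain").upper()


def _parse_quiet(text: str, config: NomenConfig) -> Optional[GeneSymbol]:
    try:
        return parse_symbol(text, config)
    except NomenclatureError:
        return None


def next_allele_letter(locus: str, registry: Registry) -> str:
    """First unused allele letter at a locus, in sequential alphabetical
    order (a..z then aa, ab, ...).

    For a locus with no registered alleles this returns ``"a"``, the
    letter reserved for the prototype genotype (Chinese Spring preferred).
    """
    target = _parse_quiet(strip_markdown(locus), registry.config)
    if target is None:
        raise NomenclatureError(f"{locus!r} is not a parseable locus symbol")
    target_core = _locus_core(target)
    used: set[str] = set()
    for entry in registry.entries:
        sym = _parse_quiet(entry.symbol, registry.config)
        if sym is None or sym.allele_letters is None:
            continue
        if _locus_core(sym) == target_core:
            used.add(sym.allele_letters)
    for letter in allele_letter_sequence():
        if letter not in used:
            return letter
    raise AssertionError("unreachable")  # pragma: no cover


def _suffix_base(symbol: GeneSymbol) -> str:
    """Case-sensitive base key for suffix numbering (the locus or allele
    the suffix hangs off; Rg1a and rg1b number independently)."""
    core = replace(symbol, suffix=None, species_prefix=None, metadata={})
    return core.render("plain")


def next_suffix_index(
    base: str, kind: SuffixKind | str, registry: Registry
) -> Tuple[int, List[Finding]]:
    """Next haplotype/mutant/pseudogene index for a base symbol:
    one past the maximum registered index (1 when none exist).

    Returns ``(index, findings)``; a gap in the existing series yields an
    A04 warning finding alongside the index.
    """
    kind = SuffixKind(kind)
    target = _parse_quiet(strip_markdown(base), registry.config)
    if target is None:
        raise NomenclatureError(f"{base!r} is not a parseable symbol")
    target_base = _suffix_base(target)
    indices: List[int] = []
    for entry in registry.entries:
        sym = _parse_quiet(entry.symbol, registry.config)
        if sym is None or sym.suffix is None or sym.suffix.kind is not kind:
            continue
        if _suffix_base(sym) == target_base:
            indices.append(sym.suffix.index)
    if not indices:
        return 1, []
    top = max(indices)
    findings: List[Finding] = []
    missing = sorted(set(range(1, top + 1)) - set(indices))
    if missing:
        findings.append(Finding(
            rule_id="A04",
            severity=RULE_CATALOGUE["A04"][0],
            span=(0, len(base)),
            message=(
                f"suffix series _{kind.value}X at {target_base} skips "
                f"{', '.join(str(i) for i in missing)}; numbering should be "
                "consecutive ascending"
            ),
        ))
    return top + 1, findings


# --------------------------------------------------------------------------
# auditing


def audit_registry(registry: Registry) -> List[Finding]:
    """Audit a registry: duplicate canonical keys, case-only collisions
    (dominance pairs of one locus), allele-letter gaps and suffix-index
    gaps."""
    findings: List[Finding] = []
    keys: dict[str, int] = {}
    by_fold: dict[str, set[str]] = {}
    allele_series: dict[str, set[str]] = {}
    suffix_series: dict[Tuple[str, SuffixKind], set[int]] = {}

    for i, entry in enumerate(registry.entries):
        key = canonical_key(entry.symbol, registry.config)
        cls = classify(entry.symbol, registry.config)
        if cls is SymbolClass.UNKNOWN:
            findings.append(Finding(
                "R00", "error", (0, len(entry.symbol)),
                f"registry row {i}: {entry.symbol!r} does not parse",
            ))
            continue
        if key in keys:
            findings.append(Finding(
                "A01", RULE_CATALOGUE["A01"][0], (0, len(entry.symbol)),
                f"registry rows {keys[key]} and {i} share the canonical symbol {key!r}",
            ))
        else:
            keys[key] = i
        by_fold.setdefault(key.lower(), set()).add(key)

        sym = _parse_quiet(entry.symbol, registry.config)
        if sym is None:
            continue
        if sym.allele_letters is not None:
            allele_series.setdefault(_locus_core(sym), set()).add(sym.allele_letters)
        if sym.suffix is not None:
            suffix_series.setdefault(
                (_suffix_base(sym), sym.suffix.kind), set()
            ).add(sym.suffix.index)

    for fold, variants in sorted(by_fold.items()):
        if len(variants) > 1:
            pair = ", ".join(sorted(variants))
            findings.append(Finding(
                "A02", RULE_CATALOGUE["A02"][0], (0, len(fold)),
                f"{pair} differ only in case: a dominance pair of alleles at one locus",
            ))

    for core, letters in sorted(allele_series.items()):
        expected = list(itertools.islice(allele_letter_sequence(), len(letters)))
        missing = [e for e in expected if e not in letters]
        if missing:
            findings.append(Finding(
                "A03", RULE_CATALOGUE["A03"][0], (0, len(core)),
                f"allele series at {core} skips letter(s) {', '.join(missing)}; "
                "new alleles are assigned in sequential alphabetical order",
            ))

    for (base, kind), indices in sorted(suffix_series.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        top = max(indices)
        missing_idx = sorted(set(range(1, top + 1)) - indices)
        if missing_idx:
            findings.append(Finding(
                "A04", RULE_CATALOGUE["A04"][0], (0, len(base)),
                f"suffix series _{kind.value}X at {base} skips "
                f"{', '.join(str(i) for i in missing_idx)}",
            ))
    return findings
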