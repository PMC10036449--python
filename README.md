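# wheatnom

Wheat and Triticeae genetics names its hereditary factors under a precise
community convention: loci are all-uppercase italic (*VRN-A1*), the case of
the first letter of an allele encodes dominance (*Vrn-A1* dominant,
*vrn-A1* recessive), sequence variants hang off a locus or allele as
`_hX` (haplotype), `_mX` (induced mutant) or `_pX` (pseudogene) suffixes,
gene-complex members are dash-numbered (*GLU-A1-1*), QTL follow
`Q` + trait + `.` + lab + `-` + chromosome (*QYld.psr-7B.1*), and SNP
markers come either as gene-based variant names (`GW2-B1_C2504T`,
`Kasp_Sr13a_S1152F`) or as 17-character coordinate names
(`CHS21_6A001234567`). **wheatnom** turns that convention into an
executable standard: a Python library and command-line tool that parses,
classifies, validates, canonicalises and constructs these symbols, and
audits catalogue registries for curation errors.

It is aimed at wheat gene-catalogue curators, genebank and database
maintainers (e.g. teams cross-referencing GrainGenes/KOMUGI entries), and
any group that wants to lint the gene names in a manuscript or marker
table before submission.

## What it implements

* **Data model** — structured types for gene symbols (prefixes, basic
  symbol, sub-genome token, homoeologous set and member numbers, allele
  letters, dominance class, suffixes, chromosomal aberrations), QTL
  symbols, coordinate marker names, gene-model identifiers
  (`TraesCS5A02G391700`, `TRITD5Av1G170700`), variant descriptors,
  genotype formulae (maternal alleles first, slash-separated) and the
  genome formula (2n = 6x = 42 for bread wheat). Italics are typography,
  not data: every type renders in `plain`, `markdown` or `html` style,
  with plain as the canonical comparison form.
* **Parser/classifier** — a total, deterministic classifier over the 13
  symbol classes, and strict case-sensitive parsers (case is semantic).
* **Linter** — a numbered rule catalogue (R01–R18) covering, among
  others: no plus signs; no chromosome names inside basic symbols
  (*VRN-A1*, never *VRN-5A*); lowercase allele letters; suffix grammar;
  ≤3-letter temporary stock abbreviations; ≤4-letter QTL trait
  designators; fixed coordinate-marker field widths; three-letter
  amino-acid codes for residues confusable with nucleotides; and the
  resistance-gene exception (resistance alleles keep an uppercase first
  letter even when recessive). Findings carry severities, character
  spans and, where the repair is unambiguous, a suggested fix.
* **Registry audit and next-designation** — duplicate and case-collision
  detection, allele-letter series gaps, suffix-index gaps, next free
  allele letter (a…z, then aa, ab, …; "a" reserved for the prototype
  genotype) and next free suffix index.
* **Seeded fixture generator** — reproducible valid and single-fault
  symbol corpora used by the property-based test suite.

## Worked example

```bash
$ printf 'symbol\nVRN-A1\nSr9a\nTaAP1-A1\nVRN-5A\nGW2-B1_53_72del\n' > demo.tsv
$ wheatnom lint demo.tsv
input   symbol_class  ok     findings                                  canonical
VRN-A1  locus         True   []                                        VRN-A1
Sr9a    allele        True   []                                        Sr9a
TaAP1-A1 locus        True   [{"rule_id": "R17", "severity": "info", ...}]  AP1-A1
VRN-5A  unknown       False  [{"rule_id": "R05", "severity": "error", ...}]
GW2-B1_53_72del variant_marker True []                                 GW2-B1_53_72del
4/5 symbols conform
```

The summary line says four of the five names conform. `TaAP1-A1` is
accepted with an informational note: the `Ta` species prefix is not part
of the formal name, so its canonical form is `AP1-A1`. `VRN-5A` fails
rule R05 — chromosome names (5A) must not be used in place of the genome
letter + set number designation (`VRN-A1`) — and because the correct set
number cannot be recovered from the string, no automatic fix is offered.
The process exits non-zero, so the lint can gate a curation pipeline.

Single symbols decompose to JSON:

```bash
$ wheatnom parse Sr9a
{ "input": "Sr9a", "class": "allele",
  "fields": { "basic_symbol": "SR", "set_number": 9,
              "allele_letters": "a", "dominance": "dominant", ... },
  "canonical": "Sr9a", "findings": [] }
```

and the builders construct marker names from fields:

```bash
$ wheatnom build-marker --assembly CHS --version 2.1 --chromosome 6A --position 1234567
CHS21_6A001234567
$ wheatnom build-variant X --change C10S
X_Cys10Ser
```

The second call shows the confusable-residue rule in action: a
cysteine→serine substitution at residue 10 is written with three-letter
codes because one-letter `C` could be read as cytosine.

From Python:

```python
>>> from wheatnom import parse_symbol, protein_symbol, render, genome_formula
>>> sym = parse_symbol("vrn-A1_m2 (null, W91*)")
>>> sym.suffix.annotation.render()
'W91*'
>>> render(protein_symbol(parse_symbol("Sr9a")))
'SR9a'
>>> genome_formula(7, 6).render()
'2n = 6x = 42'
```

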