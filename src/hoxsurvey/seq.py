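"""Nucleotide/protein sequence primitives shared across the package.

The survey works on genomic DNA amplified with degenerate oligonucleotides,
so the nucleotide alphabet is the full 15-letter IUPAC DNA code. A degenerate
sequence denotes the set of all concrete sequences obtained by expanding each
ambiguity symbol; most operations below are defined in terms of that set.

Only the standard genetic code is used (all surveyed loci are nuclear).
Lowercase input is normalised to uppercase; RNA ('U') is rejected rather than
silently converted, because the data modelled here is genomic DNA.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable, IUPACData
from Bio.Seq import Seq

__all__ = [
    "AlphabetError",
    "TranslationError",
    "IUPAC_DNA",
    "GeneticCode",
    "STANDARD_CODE",
    "normalize_nuc",
    "normalize_prot",
    "iupac_compatible",
    "expansion_count",
    "expansions",
    "reverse_complement",
    "translate",
    "read_fasta",
    "write_fasta",
]


class AlphabetError(ValueError):
    """A symbol outside the expected alphabet was encountered."""


class TranslationError(ValueError):
    """Translation could not produce a single interpretable protein."""


#: IUPAC DNA symbol -> frozenset of concrete bases it stands for (15 letters).
IUPAC_DNA: dict[str, frozenset[str]] = {
    sym: frozenset(bases)
    for sym, bases in IUPACData.ambiguous_dna_values.items()
    if sym in "ACGTRYSWKMBDHVN"
}

_BASES = ("A", "C", "G", "T")
_PROT_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")


def normalize_nuc(seq: str) -> str:
    """Return the canonical (uppercase) form of a IUPAC DNA string.

    Raises AlphabetError for empty input, 'U', or any symbol outside the
    15-letter IUPAC DNA alphabet.
    """
    s = str(seq).upper()
    if not s:
        raise AlphabetError("empty nucleotide sequence")
    bad = set(s) - set(IUPAC_DNA)
    if bad:
        raise AlphabetError(f"non-IUPAC DNA symbol(s): {sorted(bad)!r}")
    return s


def normalize_prot(seq: str) -> str:
    s = str(seq).upper()
    if not s:
        raise AlphabetError("empty protein sequence")
    bad = set(s) - _PROT_ALPHABET
    if bad:
        raise AlphabetError(f"non-amino-acid symbol(s): {sorted(bad)!r}")
    return s


def iupac_compatible(symbol: str, base: str) -> bool:
    """True iff concrete ``base`` is in the expansion set of IUPAC ``symbol``."""
    try:
        expansion = IUPAC_DNA[symbol.upper()]
    except KeyError:
        raise AlphabetError(f"unknown IUPAC symbol {symbol!r}") from None
    if base.upper() not in _BASES:
        raise AlphabetError(f"expected a concrete base, got {base!r}")
    return base.upper() in expansion


def expansion_count(seq: str) -> int:
    """Number of concrete sequences a degenerate sequence stands for."""
    n = 1
    for sym in normalize_nuc(seq):
        n *= len(IUPAC_DNA[sym])
    return n


def expansions(seq: str) -> Iterator[str]:
    """Iterate over all concrete expansions of a degenerate sequence."""
    sets = [sorted(IUPAC_DNA[sym]) for sym in normalize_nuc(seq)]
    for combo in itertools.product(*sets):
        yield "".join(combo)


def reverse_complement(seq: str) -> str:
    """Reverse complement honouring IUPAC ambiguity codes (R<->Y, K<->M, ...)."""
    return str(Seq(normalize_nuc(seq)).reverse_complement())


class GeneticCode:
    """The standard genetic code with helpers for degenerate-codon reasoning."""

    def __init__(self) -> None:
        table = CodonTable.unambiguous_dna_by_id[1]
        self.forward: dict[str, str] = dict(table.forward_table)
        for stop in table.stop_codons:
            self.forward[stop] = "*"
        if len(self.forward) != 64:
            raise AssertionError("genetic code table is not total")
        self.codons_for: dict[str, frozenset[str]] = {}
        by_aa: dict[str, set[str]] = {}
        for codon, aa in self.forward.items():
            by_aa.setdefault(aa, set()).add(codon)
        self.codons_for = {aa: frozenset(c) for aa, c in by_aa.items()}
        self.stop_codons = self.codons_for["*"]

    def translate_codon(self, codon: str) -> str:
        """Translate one (possibly degenerate) codon.

        Returns the unique residue if all expansions agree, '*' if all
        expansions are stops, else 'X'.
        """
        if len(codon) != 3:
            raise TranslationError(f"codon of length {len(codon)}")
        if all(c in _BASES for c in codon):
            return self.forward[codon]
        aas = {self.forward[c] for c in expansions(codon)}
        if len(aas) == 1:
            return aas.pop()
        return "X"

    def is_synonymous(self, codon_a: str, codon_b: str) -> bool:
        """Whether two concrete codons encode the same residue (stops included)."""
        return self.forward[codon_a] == self.forward[codon_b]

    def codon_can_encode(self, codon: str, aa: str) -> bool:
        """Whether some expansion of a degenerate codon encodes ``aa``."""
        allowed = self.codons_for.get(aa.upper())
        if allowed is None:
            raise AlphabetError(f"unknown residue {aa!r}")
        if all(c in _BASES for c in codon):
            return codon in allowed
        # positional pre-filter, then exact expansion check (residue codon
        # sets such as Leu/Arg/Ser are not cartesian products of base sets)
        for i in range(3):
            if IUPAC_DNA[codon[i]].isdisjoint({c[i] for c in allowed}):
                return False
        return any(c in allowed for c in expansions(codon))


@lru_cache(maxsize=1)
def _standard_code() -> GeneticCode:
    return GeneticCode()


STANDARD_CODE = _standard_code()


def translate(seq: str, frame_offset: int = 0, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate DNA from ``frame_offset`` (0..2), one residue per complete codon.

    Trailing partial codons are dropped. Degenerate codons whose expansions
    disagree yield 'X'. Raises TranslationError if no complete codon exists or
    if every codon is ambiguous beyond resolution.
    """
    s = normalize_nuc(seq)
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0..2, got {frame_offset}")
    if len(s) - frame_offset < 3:
        raise TranslationError("no complete codon in the requested frame")
    residues = [
        code.translate_codon(s[i : i + 3])
        for i in range(frame_offset, len(s) - 2, 3)
    ]
    prot = "".join(residues)
    if set(prot) == {"X"}:
        raise TranslationError("no codon could be resolved to a residue")
    return prot


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(record id, uppercase sequence), ...]``.

    Record ids are preserved verbatim (the full header word); descriptions
    beyond the first whitespace are available to callers via Biopython if
    needed, but the survey encodes metadata as ``key=value`` tokens inside
    the description, parsed by the modules that define them.
    """
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_fasta_with_descriptions(path) -> list[tuple[str, str, str]]:
    return [
        (rec.id, rec.description, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(header, sequence)`` pairs; the header is emitted verbatim."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
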