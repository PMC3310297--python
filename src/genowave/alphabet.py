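"""Alphabets of symbolic sequences and the standard genetic code.

A sequence over the 4-letter nucleotide alphabet {A, C, G, T} can be
re-read as a sequence of length-``l`` words; for ``l = 3`` the biologically
independent words are the 64 codons, which the genetic code collapses onto
20 amino-acid letters (plus a stop marker).  The *order* of an alphabet is
significant throughout this package: the complex unit-root encoding maps
the ``j``-th symbol to ``exp(2*pi*1j*(j-1)/M)``, so permuting an alphabet
permutes the roots.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "Alphabet",
    "CodonTable",
    "NUCLEOTIDES",
    "AMINO_ACIDS",
    "STOP_SYMBOL",
    "load_codon_table",
]

#: Distinguished token emitted for stop codons under ``stop_policy="symbol"``.
#: It is not a member of :data:`AMINO_ACIDS` and has no unit root.
STOP_SYMBOL = "*"


@dataclass(frozen=True)
class Alphabet:
    """An ordered finite set of tokens.

    Parameters
    ----------
    symbols
        Distinct tokens in a fixed order.  The position of a token (0-based
        here, 1-based ``j`` in the unit-root formula) determines its root.
    word_length
        Length ``l`` of the nucleotide word each token stands for
        (1 for plain nucleotides, 3 for amino acids).
    """

    symbols: tuple[str, ...]
    word_length: int = 1
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ValueError("alphabet must contain at least one symbol")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        if self.word_length < 1:
            raise ValueError("word_length must be >= 1")
        if len(self.symbols) > 4 ** self.word_length:
            raise ValueError(
                f"an alphabet of {self.word_length}-length words holds at most "
                f"{4 ** self.word_length} symbols, got {len(self.symbols)}"
            )
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.symbols)})

    @property
    def cardinality(self) -> int:
        """Number of symbols, ``M``."""
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        """0-based position of *symbol*; raises ``KeyError`` if absent."""
        return self._index[symbol]

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self._index


#: The nucleotide alphabet in the canonical order A, C, G, T.
NUCLEOTIDES = Alphabet(("A", "C", "G", "T"), word_length=1)

#: The 20 amino-acid letters, ordered as they index the 20th roots of unity.
AMINO_ACIDS = Alphabet(
    ("M", "E", "Q", "D", "R", "T", "N", "H", "V", "G",
     "L", "S", "P", "F", "I", "C", "A", "K", "Y", "W"),
    word_length=3,
)


@dataclass(frozen=True)
class CodonTable:
    """The standard genetic code: 64 codons onto 20 letters plus stop.

    Invariants enforced at construction: exactly 61 coding codons, the 3
    stop codons TAA/TAG/TGA, and a letter set equal to :data:`AMINO_ACIDS`.
    """

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.mapping) != 64:
            raise ValueError(f"expected 64 codons, got {len(self.mapping)}")
        stops = {c for c, aa in self.mapping.items() if aa == STOP_SYMBOL}
        if stops != {"TAA", "TAG", "TGA"}:
            raise ValueError(f"stop codons must be TAA, TAG, TGA; got {sorted(stops)}")
        letters = {aa for aa in self.mapping.values() if aa != STOP_SYMBOL}
        if letters != set(AMINO_ACIDS.symbols):
            raise ValueError("coding codons must map onto the 20 amino-acid letters")

    def translate(self, codon: str) -> str:
        """Amino-acid letter (or the stop symbol) for a 3-letter codon."""
        try:
            return self.mapping[codon.upper()]
        except KeyError:
            raise KeyError(f"not a recognized codon: {codon!r}") from None

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == STOP_SYMBOL

    @property
    def coding_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in sorted(self.mapping.items()) if aa != STOP_SYMBOL)


def load_codon_table() -> CodonTable:
    """Load the packaged genetic-code table (tab-separated, one row per letter)."""
    mapping: dict[str, str] = {}
    path = resources.files("genowave.data").joinpath("codon_table.tsv")
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            for codon in row["codons"].split(","):
                mapping[codon.strip().upper()] = row["amino_acid"].strip()
    return CodonTable(mapping)
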