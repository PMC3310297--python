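"""Symbolic sequences: container, FASTA/plain-text I/O, validation, translation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS, NUCLEOTIDES, STOP_SYMBOL, Alphabet, CodonTable, load_codon_table

__all__ = [
    "SymbolSequence",
    "read_fasta",
    "read_plain_text",
    "write_fasta",
    "validate_nucleotides",
    "translate_codons",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SymbolSequence:
    """An ordered finite sequence of tokens, optionally bound to an alphabet.

    Sequences fresh from a file carry ``alphabet=None`` (tokens unchecked);
    :func:`validate_nucleotides` and :func:`translate_codons` return
    sequences bound to :data:`~genowave.alphabet.NUCLEOTIDES` /
    :data:`~genowave.alphabet.AMINO_ACIDS`.  Numeric encodings require a
    bound alphabet.
    """

    symbols: tuple[str, ...]
    identifier: str = ""
    alphabet: Alphabet | None = None
    _codes: np.ndarray | None = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ValueError(f"empty sequence (id={self.identifier!r})")
        if self.alphabet is not None:
            bad = next((i for i, s in enumerate(self.symbols) if s not in self.alphabet), None)
            if bad is not None:
                raise ValueError(
                    f"token {self.symbols[bad]!r} at position {bad + 1} is not in the alphabet"
                )

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __getitem__(self, i):
        return self.symbols[i]

    def __str__(self) -> str:
        return "".join(self.symbols)

    def codes(self) -> np.ndarray:
        """Integer codes (0-based alphabet positions) as an ``int64`` array."""
        if self.alphabet is None:
            raise ValueError("sequence has no alphabet; validate or translate it first")
        if self._codes is None:
            codes = np.fromiter(
                (self.alphabet.index(s) for s in self.symbols), dtype=np.int64, count=len(self)
            )
            object.__setattr__(self, "_codes", codes)
        return self._codes

    def prefix(self, n: int) -> "SymbolSequence":
        if not 1 <= n <= len(self):
            raise ValueError(f"prefix length {n} out of range 1..{len(self)}")
        return SymbolSequence(self.symbols[:n], self.identifier, self.alphabet)

    @classmethod
    def from_string(
        cls, text: str, identifier: str = "", alphabet: Alphabet | None = None
    ) -> "SymbolSequence":
        """Build from a plain string of single-character tokens (uppercased)."""
        return cls(tuple(text.upper()), identifier, alphabet)


def read_fasta(path: str | Path) -> list[SymbolSequence]:
    """Read every record of a FASTA file into uppercased symbol sequences.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for a
    file with no records or a record with an empty sequence.  Tokens are not
    checked against any alphabet here; see :func:`validate_nucleotides`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    sequences = []
    for rec in records:
        if len(rec.seq) == 0:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        sequences.append(SymbolSequence.from_string(str(rec.seq), identifier=rec.id))
    return sequences


def read_plain_text(path: str | Path, identifier: str = "") -> SymbolSequence:
    """Read a single bare sequence from a text file, ignoring all whitespace."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = "".join(path.read_text().split())
    if not text:
        raise ValueError(f"no sequence characters in {path}")
    return SymbolSequence.from_string(text, identifier=identifier or path.stem)


def write_fasta(sequences: Iterable[SymbolSequence], path: str | Path) -> None:
    """Write sequences as FASTA (wrapped lines); round-trips with :func:`read_fasta`."""
    records = [
        SeqRecord(Seq(str(seq)), id=seq.identifier or f"seq{i + 1}", description="")
        for i, seq in enumerate(sequences)
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def validate_nucleotides(
    seq: SymbolSequence, policy: Literal["error", "drop"] = "error"
) -> SymbolSequence:
    """Bind a raw sequence to the A/C/G/T alphabet.

    ``policy="error"`` raises on the first foreign token (naming its 1-based
    position); ``policy="drop"`` removes foreign tokens — ambiguity codes
    such as N — and logs how many were dropped.  Dropping is the right call
    for occasional Ns; encoding them would corrupt the unit-root signal.
    """
    if policy not in ("error", "drop"):
        raise ValueError(f"unknown policy {policy!r}; use 'error' or 'drop'")
    if policy == "error":
        for i, s in enumerate(seq.symbols):
            if s not in NUCLEOTIDES:
                raise ValueError(
                    f"non-nucleotide token {s!r} at position {i + 1} (id={seq.identifier!r})"
                )
        kept = seq.symbols
    else:
        kept = tuple(s for s in seq.symbols if s in NUCLEOTIDES)
        dropped = len(seq.symbols) - len(kept)
        if dropped:
            logger.warning(
                "dropped %d non-nucleotide token(s) from %r", dropped, seq.identifier
            )
        if not kept:
            raise ValueError(f"no nucleotide tokens left in {seq.identifier!r}")
    return SymbolSequence(kept, seq.identifier, NUCLEOTIDES)


def translate_codons(
    seq: SymbolSequence,
    table: CodonTable | None = None,
    stop_policy: Literal["skip", "symbol"] = "skip",
) -> SymbolSequence:
    """Translate a nucleotide sequence, frame 1, into amino-acid letters.

    The reading frame always starts at position 1 and the trailing partial
    codon is discarded; no ORF scanning or strand handling is attempted.
    Stop codons are skipped by default; with ``stop_policy="symbol"`` they
    are emitted as the ``*`` token, in which case the result is *not* bound
    to the 20-letter alphabet (the stop marker has no unit root) and must be
    filtered before root encoding.
    """
    if stop_policy not in ("skip", "symbol"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}; use 'skip' or 'symbol'")
    if len(seq) < 3:
        raise ValueError(f"sequence of length {len(seq)} is shorter than one codon")
    table = table if table is not None else load_codon_table()
    letters = []
    text = str(seq).upper()
    for i in range(0, len(text) - len(text) % 3, 3):
        aa = table.translate(text[i : i + 3])
        if aa == STOP_SYMBOL and stop_policy == "skip":
            continue
        letters.append(aa)
    if not letters:
        raise ValueError(f"translation of {seq.identifier!r} is empty (all stops?)")
    alphabet = None if STOP_SYMBOL in letters else AMINO_ACIDS
    return SymbolSequence(tuple(letters), seq.identifier, alphabet)
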