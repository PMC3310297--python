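"""Control-sequence generators: pseudorandom, pseudoperiodic, random unit roots.

These are the reference inputs every analysis in the package is calibrated
against: an i.i.d. uniform symbol stream, its periodised counterpart (one
random block repeated), and an i.i.d. stream over the 4th roots of unity.
All draw from ``numpy.random.default_rng(seed)`` so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import NUCLEOTIDES, Alphabet
from .representation import ComplexSignal
from .sequence import SymbolSequence

__all__ = [
    "GeneratorSpec",
    "pseudorandom_sequence",
    "pseudoperiodic_sequence",
    "random_unit_complex",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic sequence: length N, period pi, alphabet, seed.

    For periodic output the length is trimmed to the largest multiple of the
    period not exceeding N (the construction concatenates whole blocks).
    ``period=1`` is taken literally: a 1-block repeated, i.e. a constant
    sequence — *not* a pseudorandom one, despite the common shorthand that a
    unit period "is" the random case.  Use :func:`pseudorandom_sequence`
    for i.i.d. output.
    """

    length: int
    period: int = 1
    alphabet: Alphabet = NUCLEOTIDES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be positive, got {self.length}")
        if self.period < 1:
            raise ValueError(f"period must be >= 1, got {self.period}")

    @property
    def trimmed_length(self) -> int:
        """Largest multiple of the period not exceeding the requested length."""
        return (self.length // self.period) * self.period


def pseudorandom_sequence(spec: GeneratorSpec) -> SymbolSequence:
    """i.i.d. uniform draws from the alphabet; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    codes = rng.integers(0, spec.alphabet.cardinality, size=spec.length)
    symbols = tuple(spec.alphabet.symbols[c] for c in codes)
    return SymbolSequence(symbols, f"pseudorandom-N{spec.length}-seed{spec.seed}",
                          spec.alphabet)


def pseudoperiodic_sequence(spec: GeneratorSpec) -> SymbolSequence:
    """A random period-length block concatenated with itself, N = k*pi.

    Satisfies ``x[i] == x[i + period]`` for every valid ``i``; its dot plot
    shows lines parallel to the main diagonal at lag multiples of the period.
    """
    if spec.period > spec.length:
        raise ValueError(f"period {spec.period} exceeds length {spec.length}")
    rng = np.random.default_rng(spec.seed)
    block = rng.integers(0, spec.alphabet.cardinality, size=spec.period)
    n = spec.trimmed_length
    codes = np.tile(block, n // spec.period)
    symbols = tuple(spec.alphabet.symbols[c] for c in codes)
    return SymbolSequence(
        symbols, f"pseudoperiodic-N{n}-pi{spec.period}-seed{spec.seed}", spec.alphabet
    )


def random_unit_complex(n: int, seed: int = 0) -> ComplexSignal:
    """i.i.d. unit-modulus terms ``(-1)**r * 1j**s``, r in {0,1}, s in {0..3}.

    Every term lands on one of the 4th roots of unity {1, i, -1, -i}, each
    with probability 1/4 (the (r, s) product measure is uniform over the
    four cosets).
    """
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    r = rng.integers(0, 2, size=n)
    s = rng.integers(0, 4, size=n)
    terms = (-1.0) ** r * 1j ** s
    return ComplexSignal(np.asarray(terms, dtype=complex), alphabet=None)
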