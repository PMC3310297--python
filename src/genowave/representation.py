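"""Numeric and geometric representations of symbol sequences.

Four views of the same sequence live here:

* the **indicator matrix** ``u[h, k] = 1`` iff the symbols at positions
  ``h`` and ``k`` are equal — its image is the dot plot, a special case of
  a recurrence plot;
* the **complex unit-root signal**: the ``j``-th alphabet symbol maps to
  ``exp(2*pi*1j*(j-1)/M)``, so A, C, G, T land on 1, i, -1, -i;
* the **walk**: the cumulative sum ``z_n`` of the signal, whose real and
  imaginary parts are differences of running nucleotide counts;
* the **rectangular spiral layout** (an Ulam-style arrangement) mapping the
  1-based sequence index onto an integer lattice spiral.

Two sign conventions for the nucleotide roots are supported.  The
constructive one, ``"CT"``, is the default (C -> i, T -> -i), giving
``Im(z_n) = c_n - t_n``.  The alternative ``"TC"`` swaps the C and T roots
so that ``Im(z_n) = t_n - c_n``; the two signals are complex conjugates of
one another, and the published walk formula uses the ``"TC"`` sign.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .alphabet import NUCLEOTIDES, Alphabet
from .sequence import SymbolSequence

__all__ = [
    "IndicatorMatrix",
    "ComplexSignal",
    "WalkSeries",
    "SpiralLayout",
    "GroupFrequencies",
    "NUCLEOTIDE_GROUPS",
    "indicator_matrix",
    "complex_root_map",
    "encode",
    "decode",
    "walk",
    "group_frequencies",
    "spiral_coords",
    "spiral_index",
    "spiral_layout",
]

Convention = Literal["CT", "TC"]

#: Ligand groupings of the nucleotides.
NUCLEOTIDE_GROUPS: dict[str, frozenset[str]] = {
    "purine": frozenset({"A", "G"}),
    "pyrimidine": frozenset({"C", "T"}),
    "amino": frozenset({"A", "C"}),
    "keto": frozenset({"G", "T"}),
    "weak": frozenset({"A", "T"}),    # 2 hydrogen bonds (A-T pairing)
    "strong": frozenset({"G", "C"}),  # 3 hydrogen bonds (G-C pairing)
}


# ---------------------------------------------------------------------------
# indicator matrix


@dataclass(frozen=True)
class IndicatorMatrix:
    """N x N binary symmetric matrix of symbol equality."""

    values: np.ndarray
    sequence_ref: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"indicator matrix must be square, got shape {v.shape}")

    @property
    def order(self) -> int:
        return self.values.shape[0]

    def density(self) -> float:
        """Fraction of ones; equals sum of squared symbol frequencies."""
        return float(self.values.mean())


def indicator_matrix(seq: SymbolSequence) -> IndicatorMatrix:
    """Binary equality matrix of a sequence over any alphabet.

    ``u[h, k] = 1`` iff ``x[h] == x[k]``; symmetric with unit diagonal.
    Works identically for nucleotides and for amino-acid words.
    """
    arr = np.asarray(seq.symbols)
    values = (arr[:, None] == arr[None, :]).astype(np.uint8)
    return IndicatorMatrix(values, seq.identifier)


# ---------------------------------------------------------------------------
# unit-root encoding


def complex_root_map(
    alphabet: Alphabet, convention: Convention = "CT"
) -> dict[str, complex]:
    """Map each symbol to its root of unity ``exp(2*pi*1j*(j-1)/M)``.

    ``j`` is the 1-based position of the symbol in the alphabet.  For the
    nucleotide alphabet, ``convention="TC"`` swaps the C and T images
    (conjugating the whole signal).
    """
    m = alphabet.cardinality
    roots = {s: np.exp(2j * np.pi * j / m) for j, s in enumerate(alphabet.symbols)}
    if convention == "TC":
        if alphabet is not NUCLEOTIDES and set(alphabet.symbols) != {"A", "C", "G", "T"}:
            raise ValueError("the 'TC' convention applies only to the nucleotide alphabet")
        roots["C"], roots["T"] = roots["T"], roots["C"]
    elif convention != "CT":
        raise ValueError(f"unknown convention {convention!r}; use 'CT' or 'TC'")
    return roots


@dataclass(frozen=True)
class ComplexSignal:
    """A sequence of unit-modulus complex numbers ``y_h``.

    ``alphabet`` and ``convention`` identify the root map that produced the
    signal (``None`` for synthetic unit-root noise); they enable
    nearest-root decoding and count bookkeeping in walks.
    """

    terms: np.ndarray
    alphabet: Alphabet | None = None
    convention: Convention = "CT"
    identifier: str = ""

    def __post_init__(self) -> None:
        terms = np.asarray(self.terms, dtype=complex)
        object.__setattr__(self, "terms", terms)
        if terms.ndim != 1 or len(terms) == 0:
            raise ValueError("signal must be a nonempty 1-D array")
        if not np.allclose(np.abs(terms), 1.0, atol=1e-9):
            raise ValueError("every term of a unit-root signal must have modulus 1")

    def __len__(self) -> int:
        return len(self.terms)


def encode(seq: SymbolSequence, convention: Convention = "CT") -> ComplexSignal:
    """Unit-root signal of a sequence: term ``h`` equals the root of ``x_h``."""
    if seq.alphabet is None:
        raise ValueError("sequence has no alphabet; validate or translate it first")
    roots = complex_root_map(seq.alphabet, convention)
    lookup = np.array([roots[s] for s in seq.alphabet.symbols])
    return ComplexSignal(lookup[seq.codes()], seq.alphabet, convention, seq.identifier)


def decode(signal: ComplexSignal) -> SymbolSequence:
    """Nearest-root decoding; exact inverse of :func:`encode`."""
    if signal.alphabet is None:
        raise ValueError("signal carries no alphabet; cannot decode")
    roots = complex_root_map(signal.alphabet, signal.convention)
    symbols = list(signal.alphabet.symbols)
    lookup = np.array([roots[s] for s in symbols])
    nearest = np.argmin(np.abs(signal.terms[:, None] - lookup[None, :]), axis=1)
    return SymbolSequence(
        tuple(symbols[i] for i in nearest), signal.identifier, signal.alphabet
    )


# ---------------------------------------------------------------------------
# walks


@dataclass(frozen=True)
class WalkSeries:
    """Cumulative sum ``z_n`` of a unit-root signal, plus running counts.

    ``counts`` maps each nucleotide to its running total over prefixes
    (``counts["A"][n-1]`` = number of A in the first ``n`` symbols); it is
    ``None`` when the source signal is not nucleotide-encoded.
    """

    terms: np.ndarray
    counts: dict[str, np.ndarray] | None = None
    identifier: str = ""

    def __len__(self) -> int:
        return len(self.terms)

    def magnitudes(self) -> np.ndarray:
        return np.abs(self.terms)


def walk(signal: ComplexSignal) -> WalkSeries:
    """The walk ``z_n = y_1 + ... + y_n``.

    For nucleotide-encoded signals the running counts a, c, g, t are
    recovered by nearest-root decoding and recorded alongside; they satisfy
    ``a_h + c_h + g_h + t_h = h`` and (in the ``"TC"`` convention)
    ``Re(z) = a - g``, ``Im(z) = t - c``.
    """
    z = np.cumsum(signal.terms)
    counts = None
    if signal.alphabet is not None and set(signal.alphabet.symbols) == {"A", "C", "G", "T"}:
        seq = decode(signal)
        arr = np.asarray(seq.symbols)
        counts = {s: np.cumsum(arr == s).astype(np.int64) for s in "ACGT"}
    return WalkSeries(z, counts, signal.identifier)


# ---------------------------------------------------------------------------
# group counts / frequencies


@dataclass(frozen=True)
class GroupFrequencies:
    """Counts and frequencies of nucleotides (and ligand groups) in a prefix."""

    prefix_length: int
    counts: dict[str, int]
    frequencies: dict[str, float]
    group_frequencies: dict[str, float]


def group_frequencies(seq: SymbolSequence, h: int) -> GroupFrequencies:
    """Nucleotide counts/frequencies over the first ``h`` symbols.

    Returns per-symbol counts ``a_h, c_h, g_h, t_h`` (summing to ``h``),
    frequencies ``count/h``, and the derived group frequencies for
    purine/pyrimidine, amino/keto and weak/strong hydrogen-bond pairs.
    """
    if not 1 <= h <= len(seq):
        raise ValueError(f"prefix length {h} out of range 1..{len(seq)}")
    arr = np.asarray(seq.symbols[:h])
    counts = {s: int((arr == s).sum()) for s in "ACGT"}
    if sum(counts.values()) != h:
        raise ValueError("sequence contains non-ACGT tokens; validate it first")
    freqs = {s: c / h for s, c in counts.items()}
    groups = {
        name: sum(freqs[s] for s in members) for name, members in NUCLEOTIDE_GROUPS.items()
    }
    return GroupFrequencies(h, counts, freqs, groups)


# ---------------------------------------------------------------------------
# rectangular spiral

# Counterclockwise rectangular spiral anchored at the origin: first step +x,
# then +y, with arm lengths 1, 1, 2, 2, 3, 3, ...  The first eleven points
# are (0,0), (1,0), (1,1), (0,1), (-1,1), (-1,0), (-1,-1), (0,-1), (1,-1),
# (2,-1), (2,0).
_DIRECTIONS = ((1, 0), (0, 1), (-1, 0), (0, -1))
_spiral_points: list[tuple[int, int]] = [(0, 0)]
_spiral_lookup: dict[tuple[int, int], int] = {(0, 0): 1}


def _spiral_steps():
    for arm, (dx, dy) in zip(
        itertools.chain.from_iterable((k, k) for k in itertools.count(1)),
        itertools.cycle(_DIRECTIONS),
    ):
        for _ in range(arm):
            yield dx, dy


_spiral_gen = _spiral_steps()


def _extend_spiral(upto: int) -> None:
    while len(_spiral_points) < upto:
        dx, dy = next(_spiral_gen)
        x, y = _spiral_points[-1]
        point = (x + dx, y + dy)
        _spiral_points.append(point)
        _spiral_lookup[point] = len(_spiral_points)


def spiral_coords(n: int) -> tuple[int, int]:
    """Lattice point of the 1-based index ``n`` on the rectangular spiral."""
    if n < 1:
        raise ValueError(f"spiral index must be >= 1, got {n}")
    _extend_spiral(n)
    return _spiral_points[n - 1]


def spiral_index(point: tuple[int, int]) -> int:
    """Inverse of :func:`spiral_coords`: the index whose point is ``point``."""
    point = (int(point[0]), int(point[1]))
    if point not in _spiral_lookup:
        ring = max(abs(point[0]), abs(point[1])) + 1
        _extend_spiral((2 * ring + 1) ** 2)
    if point not in _spiral_lookup:
        raise ValueError(f"point {point} is not on the spiral")  # pragma: no cover
    return _spiral_lookup[point]


@dataclass(frozen=True)
class SpiralLayout:
    """Spiral placement of a sequence: index -> point, partitioned by symbol."""

    points: dict[int, tuple[int, int]]
    by_symbol: dict[str, tuple[tuple[int, int], ...]]
    identifier: str = ""

    def __len__(self) -> int:
        return len(self.points)


def spiral_layout(seq: SymbolSequence) -> SpiralLayout:
    """Place the sequence on the spiral; one point set per symbol.

    The per-symbol point sets partition the first N spiral points, which
    supports one-panel-per-nucleotide rendering of the distribution of a
    single nucleotide over the plane.
    """
    n = len(seq)
    _extend_spiral(n)
    points = {i + 1: _spiral_points[i] for i in range(n)}
    by_symbol: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(seq.symbols):
        by_symbol.setdefault(s, []).append(_spiral_points[i])
    return SpiralLayout(
        points, {s: tuple(pts) for s, pts in by_symbol.items()}, seq.identifier
    )
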