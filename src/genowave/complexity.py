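"""Scalar complexity indices of a symbolic sequence.

Four indices, each computed on a prefix window:

* **randomness** ``R = 1 - spread(frequencies)`` — 1 when all symbol
  frequencies coincide, smaller the more skewed the composition;
* **complexity** ``K = ln(n! / prod(counts!)) / n`` — per-symbol log of
  the multinomial coefficient of the composition (nats/symbol); 0 for a
  constant sequence, maximal near equal counts;
* **fractal dimension** ``D`` of the dot plot by box counting: the average
  over minor sizes ``n`` of ``log p(n) / log n``, where ``p(n)`` is the
  mean number of ones in sampled ``n x n`` contiguous minors;
* **normalized Shannon entropy** ``H = -sum(p log p) / log M`` in [0, 1].

For uniform random sequences ``K`` and ``H`` agree up to the factor
``ln M`` (Stirling), which the report's consistency check exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy.special import gammaln

from .representation import IndicatorMatrix, indicator_matrix
from .sequence import SymbolSequence

__all__ = [
    "ComplexityReport",
    "randomness_index",
    "complexity_K",
    "fractal_dimension",
    "shannon_entropy",
    "complexity_report",
]


def _prefix_frequencies(seq: SymbolSequence, n: int) -> np.ndarray:
    if not 1 <= n <= len(seq):
        raise ValueError(f"prefix length {n} out of range 1..{len(seq)}")
    if seq.alphabet is None:
        raise ValueError("sequence has no alphabet; validate or translate it first")
    counts = np.bincount(seq.codes()[:n], minlength=seq.alphabet.cardinality)
    return counts / n


def randomness_index(
    seq: SymbolSequence, n: int | None = None,
    spread: Literal["variance", "std"] = "variance",
) -> float:
    """``R = 1 - spread`` of the per-symbol frequencies over the first n symbols.

    ``spread="variance"`` (default) uses the population variance of the
    frequency vector; ``"std"`` its population standard deviation.  Equal
    frequencies give exactly 1; piling mass on one symbol lowers the index.
    """
    n = len(seq) if n is None else n
    freqs = _prefix_frequencies(seq, n)
    if spread == "variance":
        return float(1.0 - np.var(freqs))
    if spread == "std":
        return float(1.0 - np.std(freqs))
    raise ValueError(f"unknown spread {spread!r}; use 'variance' or 'std'")


def complexity_K(seq: SymbolSequence, n: int | None = None) -> float:
    """Per-symbol log-multinomial coefficient of the composition, in nats.

    ``K = ln(n! / (a! c! g! t!)) / n`` with the counts taken over the first
    ``n`` symbols (any alphabet is accepted; the product runs over all
    symbol counts).  Evaluated exactly via log-gamma.
    """
    n = len(seq) if n is None else n
    if not 1 <= n <= len(seq):
        raise ValueError(f"prefix length {n} out of range 1..{len(seq)}")
    if seq.alphabet is None:
        raise ValueError("sequence has no alphabet; validate or translate it first")
    counts = np.bincount(seq.codes()[:n], minlength=seq.alphabet.cardinality)
    return float((gammaln(n + 1) - gammaln(counts + 1).sum()) / n)


def shannon_entropy(seq: SymbolSequence, n: int | None = None) -> float:
    """Normalized Shannon entropy ``-sum(p ln p) / ln M`` in [0, 1].

    Frequencies are estimated over the first ``n`` symbols; the convention
    ``0 * ln 0 = 0`` applies, and the normalizer is the log of the alphabet
    cardinality, so the uniform composition scores exactly 1.
    """
    n = len(seq) if n is None else n
    freqs = _prefix_frequencies(seq, n)
    m = len(freqs)
    if m < 2:
        return 0.0
    nz = freqs[freqs > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(m))


def fractal_dimension(
    mat: IndicatorMatrix,
    n_range: Iterable[int] = range(2, 11),
    minors_per_size: int | None = 30,
    seed: int = 0,
    normalization: Literal["mean", "paper_half"] = "mean",
) -> float:
    """Box-counting dimension of a dot plot from random contiguous minors.

    For each minor size ``n`` in ``n_range``, ``minors_per_size`` contiguous
    ``n x n`` submatrices are sampled uniformly (``None`` = exhaustive over
    all positions) and ``p(n)`` is the mean count of ones.  The estimate is
    the average of ``log p(n) / log n`` over the sizes; with
    ``normalization="paper_half"`` the sum is divided by ``2 * order``
    instead of the number of sizes.  Sizes with ``p(n) = 0`` are skipped
    with a warning.  A saturated (all-ones) plot scores exactly 2.
    """
    sizes = sorted(set(int(n) for n in n_range))
    if not sizes:
        raise ValueError("n_range must be nonempty")
    if sizes[0] < 2:
        raise ValueError("minor sizes must be >= 2 (log n must not vanish)")
    order = mat.order
    if sizes[-1] > order:
        raise ValueError(f"largest minor size {sizes[-1]} exceeds matrix order {order}")
    if minors_per_size is not None and minors_per_size < 1:
        raise ValueError("minors_per_size must be >= 1 (or None for exhaustive)")
    rng = np.random.default_rng(seed)
    values = mat.values
    terms = []
    for n in sizes:
        if minors_per_size is None:
            offsets = [(i, j) for i in range(order - n + 1) for j in range(order - n + 1)]
        else:
            offsets = zip(
                rng.integers(0, order - n + 1, size=minors_per_size),
                rng.integers(0, order - n + 1, size=minors_per_size),
            )
        counts = [values[i : i + n, j : j + n].sum() for i, j in offsets]
        p = float(np.mean(counts))
        if p <= 0:
            warnings.warn(f"no ones in any sampled {n}x{n} minor; size skipped")
            continue
        terms.append(np.log(p) / np.log(n))
    if not terms:
        raise ValueError("every sampled minor was empty; cannot estimate a dimension")
    if normalization == "mean":
        return float(np.mean(terms))
    if normalization == "paper_half":
        return float(np.sum(terms) / (2 * order))
    raise ValueError(f"unknown normalization {normalization!r}")


@dataclass(frozen=True)
class ComplexityReport:
    """The four indices of one sequence, with the windows that produced them."""

    identifier: str
    randomness: float
    complexity_K: float
    fractal_dimension: float
    entropy: float
    windows: dict[str, int]

    def as_row(self) -> dict[str, float | str | int]:
        """Flat mapping suitable for a one-row-per-sequence table."""
        return {
            "identifier": self.identifier,
            "randomness": self.randomness,
            "complexity_K": self.complexity_K,
            "fractal_dimension": self.fractal_dimension,
            "entropy": self.entropy,
            **{f"window_{k}": v for k, v in self.windows.items()},
        }


def complexity_report(
    seq: SymbolSequence,
    r_window: int = 10_000,
    k_window: int = 100,
    d_window: int = 100,
    h_window: int = 100,
    spread: Literal["variance", "std"] = "variance",
    n_range: Iterable[int] = range(2, 11),
    minors_per_size: int | None = 30,
    seed: int = 0,
) -> ComplexityReport:
    """All four indices of one sequence with their customary windows.

    Defaults: randomness over the first 10000 symbols, K and the dot-plot
    dimension over the first 100, entropy over the first 100.  Windows
    longer than the sequence are clamped to its length.  Deterministic for
    fixed (sequence, settings, seed) — the seed drives only minor sampling.
    """
    windows = {
        "randomness": min(r_window, len(seq)),
        "complexity_K": min(k_window, len(seq)),
        "fractal_dimension": min(d_window, len(seq)),
        "entropy": min(h_window, len(seq)),
    }
    mat = indicator_matrix(seq.prefix(windows["fractal_dimension"]))
    return ComplexityReport(
        identifier=seq.identifier,
        randomness=randomness_index(seq, windows["randomness"], spread=spread),
        complexity_K=complexity_K(seq, windows["complexity_K"]),
        fractal_dimension=fractal_dimension(
            mat, n_range=n_range, minors_per_size=minors_per_size, seed=seed
        ),
        entropy=shannon_entropy(seq, windows["entropy"]),
        windows=windows,
    )
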