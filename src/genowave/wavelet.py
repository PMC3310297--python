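"""Haar matrices, the short (windowed) Haar transform, coefficient clusters.

The discrete Haar matrix of order ``N = 2**M`` is built by the recursive
product: ``W_2`` is the 2-point average/difference pair, and

    W_{2N} = [ W_N  (x)  (1, 1)/sqrt(2) ]
             [ I_N  (x)  (-1, 1)/sqrt(2) ]

(Kronecker products), giving an orthonormal matrix whose first row is the
constant ``N**-0.5`` and whose detail rows take differences "later half
minus earlier half".  The *short* transform chops a signal into
non-overlapping ``p``-length windows (p in {4, 8, 16, 32}) and transforms
the real and imaginary channels of each window independently.

For unit-root-encoded sequences the detail coefficients at ``p = 4`` can
only take values from a small finite set — differences of roots of unity,
scaled by half-integer powers of 2 — so their scatter across windows
collapses onto a discrete grid of points.  That discreteness fades as the
window grows.  :func:`coefficient_clusters` extracts the distinct
(real-channel, imaginary-channel) pairs with multiplicities: the data
behind cluster scatter plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

from .representation import ComplexSignal, WalkSeries

__all__ = [
    "HaarMatrix",
    "ShortWaveletResult",
    "CoefficientClusters",
    "haar_matrix",
    "coefficient_labels",
    "short_haar_transform",
    "coefficient_clusters",
    "inverse_haar",
]

WaveletConvention = Literal["orthonormal", "eq57_average"]

_ALLOWED_WINDOWS = (4, 8, 16, 32)


@dataclass(frozen=True)
class HaarMatrix:
    """Orthonormal discrete Haar transform matrix of order ``N = 2**M``."""

    order: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (self.order, self.order):
            raise ValueError("matrix shape does not match its declared order")


def haar_matrix(order: int) -> HaarMatrix:
    """Build the orthonormal Haar matrix of a power-of-two order.

    Row 0 is the scaling (average) row; row 1 the coarsest detail
    (second half minus first half); subsequent rows are localized
    differences at finer scales, all with unit L2 norm.
    """
    if order < 2 or order & (order - 1):
        raise ValueError(f"order must be a power of two >= 2, got {order}")
    w = np.array([[1.0, 1.0], [-1.0, 1.0]]) / np.sqrt(2.0)
    n = 2
    while n < order:
        w = np.vstack(
            [
                np.kron(w, [1.0, 1.0]) / np.sqrt(2.0),
                np.kron(np.eye(n), [-1.0, 1.0]) / np.sqrt(2.0),
            ]
        )
        n *= 2
    return HaarMatrix(order, w)


def coefficient_labels(p: int) -> list[str]:
    """Names of the ``p`` coefficients: ``alpha``, then ``beta_k^n`` by scale."""
    if p < 2 or p & (p - 1):
        raise ValueError(f"window must be a power of two >= 2, got {p}")
    labels = ["alpha"]
    n = 0
    while 2 ** (n + 1) <= p:
        labels.extend(f"beta_{k}^{n}" for k in range(2 ** n))
        n += 1
    return labels


def _signal_terms(signal: Union[ComplexSignal, WalkSeries, np.ndarray]) -> np.ndarray:
    if isinstance(signal, (ComplexSignal, WalkSeries)):
        return np.asarray(signal.terms, dtype=complex)
    return np.asarray(signal, dtype=complex)


@dataclass(frozen=True)
class ShortWaveletResult:
    """Per-window Haar coefficients of the real and imaginary channels.

    ``coeffs_real`` and ``coeffs_imag`` have shape ``(segments, window)``;
    column ``i`` holds coefficient ``coefficient_labels(window)[i]`` of
    every window.  Under the orthonormal convention each window conserves
    energy; under ``eq57_average`` the first coefficient is the plain
    window mean instead (the detail rows keep the orthonormal scaling).
    """

    window: int
    segments: int
    coeffs_real: np.ndarray
    coeffs_imag: np.ndarray
    convention: WaveletConvention = "orthonormal"
    identifier: str = ""

    @property
    def labels(self) -> list[str]:
        return coefficient_labels(self.window)


def short_haar_transform(
    signal: Union[ComplexSignal, WalkSeries, np.ndarray],
    p: int = 4,
    convention: WaveletConvention = "orthonormal",
) -> ShortWaveletResult:
    """Windowed Haar transform of a complex signal or walk.

    The signal is split into ``floor(N/p)`` non-overlapping, left-aligned
    windows (trailing remainder discarded) and each window's real and
    imaginary parts are multiplied by the order-``p`` Haar matrix.
    """
    if p not in _ALLOWED_WINDOWS:
        raise ValueError(f"window must be one of {_ALLOWED_WINDOWS}, got {p}")
    if convention not in ("orthonormal", "eq57_average"):
        raise ValueError(f"unknown convention {convention!r}")
    terms = _signal_terms(signal)
    n = len(terms)
    if n < p:
        raise ValueError(f"signal of length {n} is shorter than the window {p}")
    segments = n // p
    windows = terms[: segments * p].reshape(segments, p)
    w = haar_matrix(p).values
    if convention == "eq57_average":
        w = w.copy()
        w[0] /= np.sqrt(p)  # scaling row becomes the plain mean
    coeffs_real = windows.real @ w.T
    coeffs_imag = windows.imag @ w.T
    identifier = getattr(signal, "identifier", "")
    return ShortWaveletResult(p, segments, coeffs_real, coeffs_imag, convention, identifier)


def inverse_haar(result: ShortWaveletResult) -> np.ndarray:
    """Reconstruct the windowed portion of the transformed signal.

    Only the orthonormal convention is invertible from the stored
    coefficients alone (the inverse is the transpose).  Returns a complex
    array of length ``segments * window``; a walk's reconstruction is not
    unit-modulus, hence the plain array rather than a ComplexSignal.
    """
    if result.convention != "orthonormal":
        raise ValueError(
            "inverse requires the orthonormal convention; "
            "the eq57_average scaling row is not stored in the coefficients"
        )
    w = haar_matrix(result.window).values
    real = result.coeffs_real @ w
    imag = result.coeffs_imag @ w
    return (real + 1j * imag).reshape(-1)


@dataclass(frozen=True)
class CoefficientClusters:
    """Distinct (real-channel, imag-channel) coefficient pairs per index.

    ``points[label]`` maps each observed pair (rounded to ``decimals``) to
    its multiplicity across windows; multiplicities sum to the number of
    windows for every coefficient index.
    """

    window: int
    segments: int
    points: dict[str, dict[tuple[float, float], int]]

    def support(self, label: str) -> set[tuple[float, float]]:
        """The set of distinct points of one coefficient index."""
        return set(self.points[label])


def coefficient_clusters(
    result: ShortWaveletResult, decimals: int = 10
) -> CoefficientClusters:
    """Cluster the coefficient pairs of a short-transform result.

    For each coefficient index the pairs ``(real_channel, imag_channel)``
    across windows are rounded to ``decimals`` digits and tallied; for
    root-encoded input at ``p = 4`` the detail indices land on a small
    finite set of points.
    """
    if result.segments < 1:
        raise ValueError("result contains no segments")
    points: dict[str, dict[tuple[float, float], int]] = {}
    for i, label in enumerate(result.labels):
        re = np.round(result.coeffs_real[:, i], decimals)
        im = np.round(result.coeffs_imag[:, i], decimals)
        tally: dict[tuple[float, float], int] = {}
        for pair in zip(re, im):
            key = (float(pair[0]) + 0.0, float(pair[1]) + 0.0)  # normalize -0.0
            tally[key] = tally.get(key, 0) + 1
        points[label] = tally
    return CoefficientClusters(result.window, result.segments, points)
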