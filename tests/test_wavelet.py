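"""Haar matrices, the short transform, inversion, and coefficient clusters."""

import itertools

import numpy as np
import pytest
import pywt

from genowave import (
    GeneratorSpec,
    coefficient_clusters,
    coefficient_labels,
    encode,
    haar_matrix,
    inverse_haar,
    pseudorandom_sequence,
    random_unit_complex,
    short_haar_transform,
    walk,
)

from conftest import nt

FOURTH_ROOTS = (1 + 0j, 1j, -1 + 0j, -1j)
INV_SQRT2 = 2 ** -0.5


def haar_rows_from_functions(order: int) -> np.ndarray:
    """Independent oracle: sample the scaling/wavelet step functions.

    Row (n, k) of the discrete transform is the wavelet 2**(n/2) *
    psi(2**n x - k) sampled at x = j/order and scaled by order**-0.5; the
    first row samples the constant scaling function.
    """

    def psi(x):
        if 0 <= x < 0.5:
            return -1.0
        if 0.5 <= x < 1.0:
            return 1.0
        return 0.0

    xs = np.arange(order) / order
    rows = [np.full(order, 1.0)]
    n = 0
    while 2 ** (n + 1) <= order:
        for k in range(2 ** n):
            rows.append(np.array([2 ** (n / 2) * psi(2 ** n * x - k) for x in xs]))
        n += 1
    return np.array(rows) / np.sqrt(order)


def pywt_short_transform(windows: np.ndarray) -> np.ndarray:
    """Independent oracle: full-depth pywt wavedec per window.

    pywt's haar detail filter is the negation of the later-minus-earlier
    convention, so details flip sign.
    """
    p = windows.shape[1]
    out = []
    for row in windows:
        coeffs = pywt.wavedec(row, "haar", level=int(np.log2(p)))
        out.append(np.concatenate([coeffs[0]] + [-c for c in coeffs[1:]]))
    return np.array(out)


class TestHaarMatrix:
    def test_order_two(self):
        expected = np.array([[INV_SQRT2, INV_SQRT2], [-INV_SQRT2, INV_SQRT2]])
        assert np.allclose(haar_matrix(2).values, expected)

    def test_order_four(self):
        expected = np.array(
            [
                [0.5, 0.5, 0.5, 0.5],
                [-0.5, -0.5, 0.5, 0.5],
                [-INV_SQRT2, INV_SQRT2, 0.0, 0.0],
                [0.0, 0.0, -INV_SQRT2, INV_SQRT2],
            ]
        )
        assert np.allclose(haar_matrix(4).values, expected)

    @pytest.mark.parametrize("order", [2, 4, 8, 16, 32])
    def test_orthonormal(self, order):
        w = haar_matrix(order).values
        assert np.max(np.abs(w @ w.T - np.eye(order))) < 1e-12

    @pytest.mark.parametrize("order", [2, 4, 8, 16, 32])
    def test_matches_function_sampling_oracle(self, order):
        assert np.allclose(haar_matrix(order).values, haar_rows_from_functions(order))

    def test_coarse_detail_formula(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=4)
        beta00 = (haar_matrix(4).values @ y)[1]
        assert beta00 == pytest.approx(0.5 * (y[2] - y[0] + y[3] - y[1]))

    @pytest.mark.parametrize("order", [1, 3, 12])
    def test_rejects_non_powers_of_two(self, order):
        with pytest.raises(ValueError):
            haar_matrix(order)


class TestShortTransform:
    def test_root_window_detail(self):
        # real channel (1, 0, -1, 0), imaginary channel (0, 1, 0, -1)
        res = short_haar_transform(encode(nt("ACGT")), p=4)
        assert res.coeffs_real[0, 1] == pytest.approx(-1.0)
        assert res.coeffs_imag[0, 1] == pytest.approx(-1.0)

    @pytest.mark.parametrize("convention", ["orthonormal", "eq57_average"])
    def test_constant_signal_has_zero_details(self, convention):
        res = short_haar_transform(encode(nt("A" * 16)), p=4, convention=convention)
        assert np.allclose(res.coeffs_real[:, 1:], 0.0)
        assert np.allclose(res.coeffs_imag[:, 1:], 0.0)

    def test_segment_count(self):
        sig = random_unit_complex(4000, seed=0)
        assert short_haar_transform(sig, p=4).segments == 1000

    def test_trailing_remainder_discarded(self):
        sig = random_unit_complex(4001, seed=1)
        res = short_haar_transform(sig, p=4)
        assert res.segments == 1000
        assert np.allclose(inverse_haar(res), sig.terms[:4000])

    def test_eq57_alpha_is_window_mean(self):
        sig = random_unit_complex(64, seed=2)
        res = short_haar_transform(sig, p=4, convention="eq57_average")
        means = sig.terms.reshape(-1, 4).mean(axis=1)
        assert np.allclose(res.coeffs_real[:, 0], means.real)
        assert np.allclose(res.coeffs_imag[:, 0], means.imag)

    @pytest.mark.parametrize("p", [4, 8, 16, 32])
    def test_matches_pywt_oracle(self, p):
        sig = random_unit_complex(8 * p, seed=3)
        res = short_haar_transform(sig, p=p)
        windows = sig.terms.reshape(-1, p)
        assert np.allclose(res.coeffs_real, pywt_short_transform(windows.real))
        assert np.allclose(res.coeffs_imag, pywt_short_transform(windows.imag))

    @pytest.mark.parametrize("p", [4, 8, 32])
    def test_energy_conservation(self, p):
        seq = pseudorandom_sequence(GeneratorSpec(640, seed=4))
        res = short_haar_transform(walk(encode(seq)), p=p)
        coeff_energy = (res.coeffs_real**2 + res.coeffs_imag**2).sum(axis=1)
        windows = walk(encode(seq)).terms[: res.segments * p].reshape(-1, p)
        signal_energy = np.abs(windows) ** 2
        assert np.allclose(coeff_energy, signal_energy.sum(axis=1), atol=1e-12)

    @pytest.mark.parametrize("p", [4, 8])
    def test_exact_inversion(self, p):
        sig = random_unit_complex(16 * p, seed=5)
        res = short_haar_transform(sig, p=p)
        assert np.max(np.abs(inverse_haar(res) - sig.terms)) < 1e-10

    def test_inversion_of_walk(self):
        series = walk(encode(pseudorandom_sequence(GeneratorSpec(128, seed=6))))
        res = short_haar_transform(series, p=8)
        assert np.max(np.abs(inverse_haar(res) - series.terms)) < 1e-10

    def test_inverse_requires_orthonormal(self):
        res = short_haar_transform(random_unit_complex(16, seed=7), convention="eq57_average")
        with pytest.raises(ValueError, match="orthonormal"):
            inverse_haar(res)

    def test_too_short_signal(self):
        with pytest.raises(ValueError, match="shorter"):
            short_haar_transform(random_unit_complex(3, seed=8), p=4)

    def test_unsupported_window(self):
        with pytest.raises(ValueError, match="window"):
            short_haar_transform(random_unit_complex(64, seed=9), p=6)


def enumerate_support(p: int) -> dict[str, set[tuple[float, float]]]:
    """Brute-force oracle: coefficient pairs over all 4**p root windows."""
    w = haar_matrix(p).values
    labels = coefficient_labels(p)
    support: dict[str, set[tuple[float, float]]] = {lab: set() for lab in labels}
    for window in itertools.product(FOURTH_ROOTS, repeat=p):
        y = np.array(window)
        re = w @ y.real
        im = w @ y.imag
        for i, lab in enumerate(labels):
            support[lab].add((round(re[i], 10) + 0.0, round(im[i], 10) + 0.0))
    return support


class TestClusters:
    def test_constant_signal_details_collapse_to_origin(self):
        res = short_haar_transform(encode(nt("G" * 32)), p=4)
        clusters = coefficient_clusters(res)
        for label in ("beta_0^0", "beta_0^1", "beta_1^1"):
            assert clusters.support(label) == {(0.0, 0.0)}

    def test_multiplicities_sum_to_segments(self):
        seq = pseudorandom_sequence(GeneratorSpec(4000, seed=10))
        clusters = coefficient_clusters(short_haar_transform(encode(seq), p=4))
        for tally in clusters.points.values():
            assert sum(tally.values()) == 1000

    def test_fine_detail_real_values_are_scaled_root_differences(self):
        seq = pseudorandom_sequence(GeneratorSpec(4000, seed=11))
        clusters = coefficient_clusters(short_haar_transform(encode(seq), p=4))
        allowed = {0.0, INV_SQRT2, -INV_SQRT2, 2 * INV_SQRT2, -2 * INV_SQRT2}
        observed = {round(pt[0], 9) for pt in clusters.support("beta_1^1")}
        assert observed <= {round(v, 9) for v in allowed}

    def test_level_one_detail_cluster_is_small(self):
        seq = pseudorandom_sequence(GeneratorSpec(4000, seed=12))
        clusters = coefficient_clusters(short_haar_transform(encode(seq), p=4))
        assert len(clusters.support("beta_0^1")) <= 25

    def test_observed_support_equals_enumeration(self):
        """Discreteness: long random input realizes exactly the finite sets."""
        seq = pseudorandom_sequence(GeneratorSpec(4 * 4096, seed=13))
        clusters = coefficient_clusters(short_haar_transform(encode(seq), p=4))
        oracle = enumerate_support(4)
        for label in coefficient_labels(4):
            assert clusters.support(label) == oracle[label]

    def test_discreteness_degrades_with_window_length(self):
        """Attainable detail values grow (weakly) with the window."""
        support4 = enumerate_support(4)
        support8 = enumerate_support(8)
        distinct4 = {v for lab in coefficient_labels(4)[1:] for v in support4[lab]}
        distinct8 = {v for lab in coefficient_labels(8)[1:] for v in support8[lab]}
        assert len(distinct8) >= len(distinct4)

    def test_empty_result_rejected(self):
        res = short_haar_transform(random_unit_complex(8, seed=14), p=4)
        object.__setattr__(res, "segments", 0)
        with pytest.raises(ValueError, match="segments"):
            coefficient_clusters(res)
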