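"""Dyadic wavelet decomposition and per-scale alpha-entropy."""

import numpy as np
import pytest
import pywt
from hypothesis import given, strategies as st

import pafentropy as pe
from pafentropy.exceptions import DegenerateLevelError, ParameterError
from pafentropy.wavelet import EnergyDistribution


def random_simplex(rng, n):
    w = rng.exponential(size=n)
    return w / w.sum()


def dist(p, level=1):
    return EnergyDistribution(np.asarray(p, dtype=float), level)


class TestDecompose:
    def test_constant_signal_vanishing_details(self):
        sig = pe.HrvSignal(np.full(256, 0.8), 2.0)
        d = pe.dwt_decompose(sig, pe.WaveletConfig(levels=4))
        for det in d.details:
            assert np.max(np.abs(det)) < 1e-10

    def test_dyadic_halving_lengths(self):
        sig = pe.HrvSignal(np.random.default_rng(0).normal(size=1024), 2.0)
        d = pe.dwt_decompose(sig, pe.WaveletConfig(levels=3))
        assert d.lengths == [512, 256, 128]

    def test_parseval_and_reconstruction(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            # analysis window is the leading 512 samples (dyadic trim)
            x = rng.normal(size=600)
            d = pe.dwt_decompose(pe.HrvSignal(x, 2.0), pe.WaveletConfig())
            energy = np.sum(x[:512] ** 2)
            assert d.coeff_energy() == pytest.approx(energy, rel=1e-8)
            rec = d.reconstruct()
            assert rec.size == 512
            np.testing.assert_allclose(rec, x[:512], atol=1e-8)

    def test_coefficients_match_basis_inner_products(self):
        """Independent oracle: project the signal on explicit basis vectors
        (built by inverting unit coefficient vectors) and compare with the
        cascade's coefficients."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=32)
        cfg = pe.WaveletConfig(levels=2)
        d = pe.dwt_decompose(pe.HrvSignal(x, 2.0), cfg)
        coeffs = [d.approximation] + d.details[::-1]
        template = [np.zeros_like(c) for c in coeffs]
        for ci, c in enumerate(coeffs):
            for k in range(c.size):
                unit = [t.copy() for t in template]
                unit[ci][k] = 1.0
                basis_vec = pywt.waverec(unit, cfg.wavelet_name,
                                         mode=cfg.boundary_mode)
                assert np.dot(x, basis_vec) == pytest.approx(c[k], abs=1e-10)

    def test_too_short_signal(self):
        with pytest.raises(ParameterError):
            pe.dwt_decompose(pe.HrvSignal(np.ones(100), 2.0),
                             pe.WaveletConfig(levels=8))

    def test_unknown_wavelet(self):
        with pytest.raises(ParameterError):
            pe.WaveletConfig(wavelet_name="nosuch99")


class TestBands:
    @pytest.mark.parametrize("j,nyq,expected", [
        (1, 1.0, (0.5, 1.0)),
        (2, 1.0, (0.25, 0.5)),
        (3, 0.5, (0.0625, 0.125)),
    ])
    def test_dyadic_band_edges(self, j, nyq, expected):
        assert pe.band_for_level(j, nyq) == pytest.approx(expected)

    @pytest.mark.parametrize("j,group", [
        (1, "ABOVE_HF"), (2, "HF"), (3, "HF"), (4, "LF"), (5, "LF"),
        (6, "VLF"), (7, "VLF"), (8, "VLF"),
    ])
    def test_hrv_band_groups(self, j, group):
        assert pe.band_group_for_level(j) == group

    def test_range_errors(self):
        with pytest.raises(ParameterError):
            pe.band_for_level(0, 1.0)
        with pytest.raises(ParameterError):
            pe.band_group_for_level(9)


class TestRelativeEnergy:
    def test_squared_normalization(self):
        sig = pe.HrvSignal(np.random.default_rng(0).normal(size=64), 2.0)
        d = pe.dwt_decompose(sig, pe.WaveletConfig(levels=2))
        d.details[0] = np.array([3.0, -4.0])
        p = pe.relative_energy(d, 1)
        np.testing.assert_allclose(p.p, [0.36, 0.64])

    def test_abs_normalization_option(self):
        cfg = pe.WaveletConfig(levels=2, pnorm="abs")
        sig = pe.HrvSignal(np.random.default_rng(0).normal(size=64), 2.0)
        d = pe.dwt_decompose(sig, cfg)
        d.details[0] = np.array([3.0, -1.0])
        np.testing.assert_allclose(pe.relative_energy(d, 1).p, [0.75, 0.25])

    def test_sums_to_one(self):
        sig = pe.HrvSignal(np.random.default_rng(3).normal(size=600), 2.0)
        d = pe.dwt_decompose(sig)
        for j in range(1, 9):
            assert pe.relative_energy(d, j).p.sum() == pytest.approx(
                1.0, abs=1e-12)

    def test_zero_level_degenerate(self):
        sig = pe.HrvSignal(np.full(256, 1.0), 2.0)
        d = pe.dwt_decompose(sig, pe.WaveletConfig(levels=4))
        d.details[0] = np.zeros_like(d.details[0])
        with pytest.raises(DegenerateLevelError):
            pe.relative_energy(d, 1)


class TestEntropies:
    @pytest.mark.parametrize("p,expected", [
        ([1.0, 0.0, 0.0], 0.0),
        ([0.125] * 8, np.log(8)),
        ([0.5, 0.25, 0.25], 1.5 * np.log(2)),
    ])
    def test_shannon_closed_forms(self, p, expected):
        assert pe.shannon_entropy(dist(p)) == pytest.approx(expected)

    @pytest.mark.parametrize("p,alpha,expected", [
        ([1.0, 0.0], 0.5, 0.0),
        ([0.25] * 4, 2.0, 0.75),
    ])
    def test_alpha_closed_forms(self, p, alpha, expected):
        assert pe.alpha_entropy(dist(p), alpha) == pytest.approx(expected)

    def test_shannon_limit(self):
        d = dist([0.5, 0.5])
        for a in (1 - 1e-7, 1 + 1e-7, 1.0):
            assert pe.alpha_entropy(d, a) == pytest.approx(np.log(2),
                                                           abs=1e-6)

    def test_alpha_validation(self):
        with pytest.raises(ParameterError):
            pe.alpha_entropy(dist([0.5, 0.5]), 0.0)

    @given(st.integers(2, 5), st.integers(0, 2 ** 31 - 1),
           st.sampled_from([0.3, 0.7, 1.0, 1.7, 2.5, 4.9]))
    def test_nonnegative_and_uniform_maximal(self, n, seed, alpha):
        rng = np.random.default_rng(seed)
        p = random_simplex(rng, n)
        h = pe.alpha_entropy(dist(p), alpha)
        h_uniform = pe.alpha_entropy(dist(np.full(n, 1.0 / n)), alpha)
        assert h >= 0.0
        assert h <= h_uniform + 1e-12

    @given(st.integers(0, 2 ** 31 - 1))
    def test_continuity_at_one(self, seed):
        rng = np.random.default_rng(seed)
        p = random_simplex(rng, 5)
        h_shannon = pe.shannon_entropy(dist(p))
        for eps in (1e-4, 1e-6):
            assert pe.alpha_entropy(dist(p), 1 + eps) == pytest.approx(
                h_shannon, abs=1e-3)


class TestEntropyVector:
    def test_white_noise_all_positive(self):
        sig = pe.HrvSignal(np.random.default_rng(5).normal(size=600), 2.0)
        ev = pe.entropy_vector(sig, alpha=1.7)
        assert ev.H.size == 8
        assert np.all(ev.H > 0)

    def test_tone_energy_lands_in_matching_band(self):
        """A 0.1 Hz tone concentrates detail energy in the level whose
        dyadic band contains 0.1 Hz."""
        t = np.arange(600) / 2.0
        sig = pe.HrvSignal(np.sin(2 * np.pi * 0.1 * t), 2.0)
        d = pe.dwt_decompose(sig)
        energies = [np.sum(det ** 2) for det in d.details]
        j = int(np.argmax(energies)) + 1
        lo, hi = pe.band_for_level(j, 1.0)
        assert lo <= 0.1 <= hi

    def test_deterministic(self):
        sig = pe.HrvSignal(np.random.default_rng(6).normal(size=600), 2.0)
        a = pe.entropy_vector(sig, alpha=0.3).H
        b = pe.entropy_vector(sig, alpha=0.3).H
        np.testing.assert_array_equal(a, b)

    def test_permutation_within_level_invariant(self):
        sig = pe.HrvSignal(np.random.default_rng(7).normal(size=600), 2.0)
        d = pe.dwt_decompose(sig)
        rng = np.random.default_rng(0)
        for j in (1, 4, 8):
            p = pe.relative_energy(d, j)
            h = pe.alpha_entropy(p, 1.7)
            shuffled = EnergyDistribution(rng.permutation(p.p), j)
            assert pe.alpha_entropy(shuffled, 1.7) == pytest.approx(h)
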