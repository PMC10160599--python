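"""Wavelet machinery: filter identities, oracle agreement, perfect
reconstruction, energy conservation, MODWT shift equivariance, denoising."""

import numpy as np
import pytest
import pywt

from wavebeat.wavelets import (HAAR, SYM8, WaveletDenoiser, WaveletFilterBank,
                               denoise, dwt_multilevel, get_bank,
                               idwt_multilevel, imodwt, modwt, mra_reconstruct,
                               universal_threshold)

SQRT2 = np.sqrt(2.0)


# --- independent oracle: circular convolution + decimation at offset L/2 ---

def oracle_dwt_level(x, bank):
    n, L = len(x), len(bank.h)

    def branch(f):
        return np.array([
            sum(f[m] * x[(2 * k + L // 2 - m) % n] for m in range(L))
            for k in range(n // 2)
        ])

    return branch(bank.h), branch(bank.g)


def oracle_dwt_multilevel(x, bank, J):
    approx, details = np.asarray(x, dtype=float), []
    for _ in range(J):
        approx, d = oracle_dwt_level(approx, bank)
        details.append(d)
    return approx, details


class TestFilterBanks:
    @pytest.mark.parametrize("bank", [SYM8, HAAR], ids=["sym8", "haar"])
    def test_quadrature_identities(self, bank):
        assert abs(bank.h.sum() - SQRT2) < 1e-12
        assert abs((bank.h ** 2).sum() - 1.0) < 1e-12
        L = len(bank.h)
        signs = (-1.0) ** np.arange(L)
        np.testing.assert_allclose(bank.g, signs * bank.h[::-1], atol=0)

    def test_sym8_shape(self):
        assert len(SYM8.h) == 16
        assert SYM8.n_vanishing_moments == 8

    def test_sym8_matches_reference_library(self):
        # cross-check of the embedded constants against PyWavelets' sym8
        np.testing.assert_allclose(SYM8.h, pywt.Wavelet("sym8").dec_lo, atol=1e-15)

    def test_invalid_bank_rejected(self):
        with pytest.raises(ValueError):
            WaveletFilterBank("bad", np.ones(4), 1)
        with pytest.raises(ValueError):
            get_bank("nonexistent")

    @pytest.mark.parametrize("bank", [SYM8, HAAR], ids=["sym8", "haar"])
    def test_vanishing_moments_annihilate_polynomials(self, bank):
        # interior high-pass outputs vanish for degrees < n_vanishing_moments
        t = np.linspace(-1, 1, 200)
        for degree in range(bank.n_vanishing_moments):
            out = np.convolve(t ** degree, bank.g, mode="valid")
            assert np.max(np.abs(out)) < 1e-8


class TestDecimatedDWT:
    def test_haar_worked_example(self):
        d = dwt_multilevel([1.0, 1.0, 2.0, 2.0], "haar", 1, "periodic")
        np.testing.assert_allclose(d.approx, [SQRT2, 2 * SQRT2], atol=1e-12)
        np.testing.assert_allclose(d.details[0], [0.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("bank_name,n_min", [("haar", 2), ("sym8", 16)])
    def test_agrees_with_convolution_decimation_oracle(self, bank_name, n_min):
        bank = get_bank(bank_name)
        for n in range(n_min, 65, 2):
            x = np.random.default_rng(n).normal(size=n)
            a, d = oracle_dwt_level(x, bank)
            dec = dwt_multilevel(x, bank_name, 1, "periodic")
            np.testing.assert_allclose(dec.approx, a, atol=1e-10)
            np.testing.assert_allclose(dec.details[0], d, atol=1e-10)

    @pytest.mark.parametrize("bank_name", ["haar", "sym8"])
    def test_multilevel_agrees_with_recursive_oracle(self, bank_name):
        x = np.random.default_rng(7).normal(size=64)
        a, details = oracle_dwt_multilevel(x, get_bank(bank_name), 2)
        dec = dwt_multilevel(x, bank_name, 2, "periodic")
        np.testing.assert_allclose(dec.approx, a, atol=1e-10)
        for got, want in zip(dec.details, details):
            np.testing.assert_allclose(got, want, atol=1e-10)

    @pytest.mark.parametrize("bank_name", ["haar", "sym8"])
    def test_constant_signal_has_zero_details(self, bank_name):
        d = dwt_multilevel(np.full(256, 3.7), bank_name, 3)
        for w in d.details:
            assert np.max(np.abs(w)) < 1e-10

    def test_energy_conservation_periodic(self, rng):
        x = rng.normal(size=1024)
        d = dwt_multilevel(x, "sym8", 4, "periodic")
        total = (d.approx ** 2).sum() + sum((w ** 2).sum() for w in d.details)
        assert abs(total - (x ** 2).sum()) < 1e-8

    @pytest.mark.parametrize("boundary", ["periodic", "symmetric"])
    def test_perfect_reconstruction(self, rng, boundary):
        x = rng.normal(size=4096)
        d = dwt_multilevel(x, "sym8", 4, boundary)
        assert np.max(np.abs(idwt_multilevel(d) - x)) < 1e-8

    def test_zero_coefficients_give_zero_signal(self):
        d = dwt_multilevel(np.zeros(128), "sym8", 3)
        assert np.max(np.abs(idwt_multilevel(d))) == 0.0

    def test_structure_errors(self, rng):
        with pytest.raises(ValueError):
            dwt_multilevel(np.ones(8), "haar", 5)  # 2^5 > 8
        d = dwt_multilevel(rng.normal(size=64), "haar", 2)
        d.details = d.details[:1]
        with pytest.raises(ValueError):
            idwt_multilevel(d)


class TestMODWT:
    def test_energy_identity(self, rng):
        x = rng.normal(size=777)
        m = modwt(x, "sym8", 5)
        total = (m.approx ** 2).sum() + sum((w ** 2).sum() for w in m.details)
        assert abs(total - (x ** 2).sum()) < 1e-8

    def test_all_sequences_keep_input_length(self, rng):
        x = rng.normal(size=300)
        m = modwt(x, "sym8", 4)
        assert len(m.approx) == 300
        assert all(len(w) == 300 for w in m.details)

    def test_shift_equivariance_is_exact(self, rng):
        x = rng.normal(size=512)
        m = modwt(x, "sym8", 5)
        ms = modwt(np.roll(x, 17), "sym8", 5)
        assert np.array_equal(np.roll(m.approx, 17), ms.approx)
        for w, ws in zip(m.details, ms.details):
            assert np.array_equal(np.roll(w, 17), ws)

    def test_constant_signal_details_vanish(self):
        m = modwt(np.full(256, -2.5), "sym8", 4)
        for w in m.details:
            assert np.max(np.abs(w)) < 1e-10

    def test_perfect_reconstruction(self, rng):
        x = rng.normal(size=1000)
        m = modwt(x, "sym8", 7)
        assert np.max(np.abs(imodwt(m) - x)) < 1e-8

    def test_depth_validation(self):
        with pytest.raises(ValueError):
            modwt(np.ones(100), "sym8", 7)  # 2^7 > 100


class TestMRA:
    @pytest.mark.parametrize("scheme", ["decimated", "modwt"])
    def test_keep_everything_recovers_signal(self, rng, scheme):
        x = rng.normal(size=512)
        d = (dwt_multilevel(x, "sym8", 4) if scheme == "decimated"
             else modwt(x, "sym8", 4))
        keep = set(range(1, 5)) | {"approx"}
        assert np.max(np.abs(mra_reconstruct(d, keep) - x)) < 1e-8

    def test_approx_only_on_constant_signal(self):
        x = np.full(256, 1.25)
        m = modwt(x, "sym8", 4)
        np.testing.assert_allclose(mra_reconstruct(m, {"approx"}), x, atol=1e-8)

    @pytest.mark.parametrize("scheme", ["decimated", "modwt"])
    def test_singleton_reconstructions_are_additive(self, rng, scheme):
        x = rng.normal(size=512)
        d = (dwt_multilevel(x, "sym8", 4) if scheme == "decimated"
             else modwt(x, "sym8", 4))
        parts = sum(mra_reconstruct(d, {j}) for j in range(1, 5))
        parts = parts + mra_reconstruct(d, {"approx"})
        full = idwt_multilevel(d) if scheme == "decimated" else imodwt(d)
        assert np.max(np.abs(parts - full)) < 1e-8

    def test_empty_or_invalid_keep_set_rejected(self, rng):
        d = modwt(rng.normal(size=64), "haar", 3)
        with pytest.raises(ValueError):
            mra_reconstruct(d, set())
        with pytest.raises(ValueError):
            mra_reconstruct(d, {9})


class TestDenoise:
    def test_zero_signal_maps_to_zero(self):
        out = denoise(np.zeros(1000))
        assert np.max(np.abs(out)) == 0.0

    def test_snr_gain_on_noisy_sine(self, rng):
        t = np.arange(5000) / 500.0
        clean = np.sin(2 * np.pi * 1.7 * t)
        noise = rng.normal(size=clean.size)
        noise *= np.sqrt(np.mean(clean ** 2) / np.mean(noise ** 2) / 10 ** 0.5)
        noisy = clean + noise           # SNR 5 dB by construction

        def snr(s):
            return 10 * np.log10(np.mean(clean ** 2) / np.mean((s - clean) ** 2))

        assert abs(snr(noisy) - 5.0) < 0.1
        assert snr(denoise(noisy)) - snr(noisy) >= 5.0

    def test_noiseless_smooth_signal_barely_changes(self):
        t = np.arange(4000) / 500.0
        x = np.sin(2 * np.pi * 1.7 * t)
        rel = np.linalg.norm(denoise(x) - x) / np.linalg.norm(x)
        assert rel < 0.05

    def test_universal_threshold_scales_with_noise(self, rng):
        d1 = rng.normal(0, 2.0, size=500)
        thr = universal_threshold(d1, 1000)
        sigma_hat = np.median(np.abs(d1)) / 0.6745
        assert thr == pytest.approx(sigma_hat * np.sqrt(2 * np.log(1000)))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            denoise(np.ones(10), J=4)

    def test_denoiser_transformer_api(self, rng):
        X = rng.normal(size=(3, 1000))
        den = WaveletDenoiser()
        out = den.fit_transform(X)
        assert out.shape == X.shape
        assert den.get_params()["wavelet"] == "sym8"
        den.set_params(level=3)
        assert den.level == 3
        with pytest.raises(ValueError):
            den.set_params(bogus=1)
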