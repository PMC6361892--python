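"""Hann/FFT, power spectra, and the dbWPLI estimator."""

import numpy as np
import pytest

from alphaconn import (
    ConnectivityMatrix,
    EdgeMask,
    EpochSet,
    dbwpli,
    global_dbwpli,
    masked_mean,
    power_spectrum,
    taper_fft,
)
from alphaconn.spectral import SpectralTensor, dbwpli_pairwise_oracle

from conftest import white_noise_epochs


def tensor_from_im(imx, n_bins=1):
    """SpectralTensor for 2 channels whose Im cross-spectrum at bin 0 is imx."""
    imx = np.asarray(imx, dtype=float)
    coef = np.zeros((len(imx), 2, max(n_bins, 2)), dtype=complex)
    coef[:, 0, 0] = 1j * imx
    coef[:, 1, 0] = 1.0
    freqs = np.arange(coef.shape[2], dtype=float)
    return SpectralTensor(coef, freqs, fs=2.0 * (coef.shape[2] - 1), channel_labels=["a", "b"])


class TestTaperFFT:
    def test_zero_epochs_give_zero_coefficients(self):
        eps = EpochSet(
            epochs=np.zeros((3, 2, 500)), fs=500.0, epoch_length=1.0, overlap=0.5,
            channel_labels=["a", "b"],
        )
        assert np.all(taper_fft(eps).coefficients == 0)

    def test_one_second_epochs_give_integer_hz_bins(self):
        spec = taper_fft(white_noise_epochs(2, 2, n_samples=500, fs=500.0))
        assert spec.resolution == pytest.approx(1.0)
        assert spec.freqs[7] == pytest.approx(7.0)

    def test_pure_sine_concentrates_in_main_lobe(self):
        """An 8 Hz sine puts its power in the 7-9 Hz Hann main lobe, peaked at 8."""
        t = np.arange(500) / 500.0
        sig = np.sin(2 * np.pi * 8.0 * t)
        eps = EpochSet(
            epochs=np.tile(sig, (3, 1, 1)), fs=500.0, epoch_length=1.0,
            overlap=0.5, channel_labels=["a"],
        )
        power = power_spectrum(taper_fft(eps))[0]
        non_dc = power[1:]
        assert np.argmax(power) == 8
        assert power[7:10].sum() / non_dc.sum() > 0.9

    def test_ragged_epochs_rejected(self):
        eps = white_noise_epochs(2, 2)
        eps.epochs = eps.epochs[:, :, 0]  # not epoch x channel x sample
        with pytest.raises(ValueError, match="3-D"):
            taper_fft(eps)


class TestPowerSpectrum:
    def test_amplitude_scaling_and_single_epoch(self):
        eps = white_noise_epochs(1, 2)
        p1 = power_spectrum(taper_fft(eps))
        eps2 = EpochSet(
            epochs=2.0 * eps.epochs, fs=eps.fs, epoch_length=eps.epoch_length,
            overlap=eps.overlap, channel_labels=eps.channel_labels,
        )
        p2 = power_spectrum(taper_fft(eps2))
        np.testing.assert_allclose(p2, 4.0 * p1, rtol=1e-10)


class TestDbwpli:
    @pytest.mark.parametrize(
        "imx, expected",
        [([1.0, 1.0], 1.0), ([1.0, -1.0], -1.0)],
    )
    def test_two_epoch_closed_forms(self, imx, expected):
        m = dbwpli(tensor_from_im(imx), (0.0, 0.0))
        assert m.values[0, 1] == pytest.approx(expected)

    def test_zero_denominator_is_undefined(self):
        m = dbwpli(tensor_from_im([1.0, 0.0]), (0.0, 0.0))
        assert np.isnan(m.values[0, 1])

    def test_fewer_than_two_epochs_rejected(self):
        with pytest.raises(ValueError, match="two epochs"):
            dbwpli(tensor_from_im([1.0]), (0.0, 0.0))

    def test_band_outside_available_bins_rejected(self):
        spec = taper_fft(white_noise_epochs(4, 2))
        with pytest.raises(ValueError, match="no frequency bins"):
            dbwpli(spec, (400.0, 500.0))

    def test_streaming_equals_pairwise_oracle(self, rng):
        """The streaming identity reproduces the O(n^2) pairwise-product form."""
        for _ in range(25):
            n_ep = rng.integers(2, 12)
            imx = rng.standard_normal(n_ep)
            m = dbwpli(tensor_from_im(imx), (0.0, 0.0))
            oracle = dbwpli_pairwise_oracle(imx)
            if np.isnan(oracle):
                assert np.isnan(m.values[0, 1])
            else:
                assert m.values[0, 1] == pytest.approx(oracle, abs=1e-10)

    def test_symmetric_and_bounded(self, rng):
        eps = white_noise_epochs(50, 6, seed=3)
        m = dbwpli(taper_fft(eps), (5.0, 10.0))
        np.testing.assert_array_equal(m.values, m.values.T)
        finite = m.values[np.isfinite(m.values)]
        assert np.all(finite <= 1.0 + 1e-12)
        assert np.all(np.isnan(np.diag(m.values)))

    def test_consistency_grows_with_epoch_count_on_planted_coupling(self, coupled_recording):
        """More epochs push the planted-pair estimate toward 1 in expectation."""
        from alphaconn import epoch_segments, valid_segments

        rec = coupled_recording
        small = epoch_segments(rec, [(0.0, 10.0)])
        large = epoch_segments(rec, valid_segments(rec))
        v_small = dbwpli(taper_fft(small), (7, 8)).values[0, 1]
        v_large = dbwpli(taper_fft(large), (7, 8)).values[0, 1]
        assert v_large > 0.9
        assert v_large >= v_small - 0.05

    def test_zero_lag_mixing_gives_undefined_not_spurious(self):
        """A single source mixed instantaneously into both channels has an
        exactly real cross-spectrum, so the estimator is undefined rather
        than spuriously large."""
        g = np.random.default_rng(4)
        src = g.standard_normal((40, 1, 500))
        eps = EpochSet(
            epochs=np.concatenate([1.0 * src, 0.6 * src], axis=1),
            fs=500.0, epoch_length=1.0, overlap=0.5, channel_labels=["a", "b"],
        )
        m = dbwpli(taper_fft(eps), (7, 8))
        assert np.isnan(m.values[0, 1])


class TestSummaries:
    def build(self, values):
        v = np.asarray(values, dtype=float)
        return ConnectivityMatrix(values=v, band=(7, 8), n_epochs=10,
                                  channel_labels=[f"c{i}" for i in range(v.shape[0])])

    def test_global_mean_of_lower_triangle(self):
        v = np.full((3, 3), np.nan)
        v[1, 0] = v[0, 1] = 0.1
        v[2, 0] = v[0, 2] = 0.2
        v[2, 1] = v[1, 2] = 0.3
        assert global_dbwpli(self.build(v)) == pytest.approx(0.2)

    def test_global_constant_matrix(self):
        v = np.full((4, 4), 0.7)
        np.fill_diagonal(v, np.nan)
        assert global_dbwpli(self.build(v)) == pytest.approx(0.7)

    def test_global_is_missing_aware(self):
        v = np.full((3, 3), np.nan)
        v[1, 0] = 0.1
        v[2, 1] = 0.3
        assert global_dbwpli(self.build(v)) == pytest.approx(0.2)

    def test_global_all_undefined_is_nan(self):
        v = np.full((3, 3), np.nan)
        assert np.isnan(global_dbwpli(self.build(v)))

    def test_masked_mean_and_equivalence_with_global(self):
        g = np.random.default_rng(1)
        v = g.random((5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, np.nan)
        m = self.build(v)
        two_edges = EdgeMask.from_edges([(0, 1), (2, 3)], 5)
        expected = (v[1, 0] + v[3, 2]) / 2
        assert masked_mean(m, two_edges) == pytest.approx(expected)
        full = EdgeMask(np.ones((5, 5), dtype=bool))
        assert masked_mean(m, full) == pytest.approx(global_dbwpli(m))

    def test_empty_mask_rejected(self):
        m = self.build(np.full((3, 3), 0.5))
        with pytest.raises(ValueError, match="no connections"):
            masked_mean(m, EdgeMask(np.zeros((3, 3), dtype=bool)))
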