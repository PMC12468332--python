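import numpy as np
import pytest

from mwbreast.forward import complex_wavenumber
from mwbreast.preprocess import (Mode, classify_imfs, emd_decompose,
                                 integrated_psd, loss_compensate,
                                 pca_coupling_removal, psd_filter,
                                 select_mode, to_time_domain,
                                 transition_velocity_mm_ns)


@pytest.fixture()
def band():
    return np.linspace(0.8e9, 4.1e9, 34)


class TestTimeDomain:
    def test_flat_spectrum_impulse_at_zero(self, band):
        tc = to_time_domain(np.ones(len(band)), band)
        assert np.argmax(np.abs(tc.signal)) == 0

    def test_delayed_spectrum_peaks_at_delay(self, band):
        tau = 2e-9
        tc = to_time_domain(np.exp(-2j * np.pi * band * tau), band)
        k = np.argmax(np.abs(tc.signal))
        assert abs(tc.times[k] - tau) <= tc.dt

    def test_round_trip_identity(self, band, rng):
        spec = rng.standard_normal(len(band)) + 1j * rng.standard_normal(len(band))
        tc = to_time_domain(spec, band)
        back = tc.to_spectrum()
        assert np.max(np.abs(back - spec)) / np.max(np.abs(spec)) < 1e-10

    def test_too_few_points_rejected(self):
        with pytest.raises(Exception):
            to_time_domain(np.ones(3), np.linspace(1e9, 2e9, 3))


class TestPCACouplingRemoval:
    def test_pure_common_mode_removed(self, rng):
        c = rng.standard_normal(128) + 1j * rng.standard_normal(128)
        X = np.tile(c, (12, 1))
        Xc = pca_coupling_removal(X)
        assert np.max(np.abs(Xc)) < 1e-10 * np.max(np.abs(X))

    def test_strong_coupling_suppressed_echoes_kept(self, rng):
        """Coupling 30 dB above distinct echoes: >=20 dB suppression with
        >=90% of the echo energy surviving."""
        n_ch, n_t = 12, 256
        t = np.arange(n_t)
        coupling = np.exp(2j * np.pi * 0.02 * t)
        echoes = np.zeros((n_ch, n_t), complex)
        for ch in range(n_ch):
            delay = 30 + 18 * ch  # distinct, well-separated per channel
            echoes[ch] = np.exp(-0.5 * ((t - delay) / 4.0) ** 2) * np.exp(
                2j * np.pi * (0.11 + 0.004 * ch) * t)
        amp = 10 ** (30 / 20) * np.sqrt(np.mean(np.abs(echoes) ** 2))
        X = amp * coupling[None, :] + echoes
        Xc = pca_coupling_removal(X)
        resid = Xc - echoes
        e_coup = np.sum(np.abs(amp * coupling) ** 2) * n_ch
        e_resid = np.sum(np.abs(resid) ** 2)
        suppression_db = 10 * np.log10(e_coup / e_resid)
        retention = (np.abs(np.vdot(echoes.ravel(), Xc.ravel()))
                     / np.sum(np.abs(echoes) ** 2))
        assert suppression_db >= 20
        assert retention >= 0.9

    def test_idempotent_within_tolerance(self, rng):
        """Re-applying the removal takes out < 1% additional energy
        (relative to the coupling-dominated input)."""
        X = (rng.standard_normal((10, 64)) + 1j * rng.standard_normal((10, 64)))
        X += 30 * np.ones((10, 1)) * (rng.standard_normal(64)
                                      + 1j * rng.standard_normal(64))[None, :]
        once = pca_coupling_removal(X)
        twice = pca_coupling_removal(once)
        extra = np.sum(np.abs(once - twice) ** 2) / np.sum(np.abs(X) ** 2)
        assert extra < 0.01

    def test_too_many_components_rejected(self):
        with pytest.raises(Exception):
            pca_coupling_removal(np.ones((4, 16)), n_components=4)


class TestEMD:
    def test_constant_signal_no_imfs(self):
        out = emd_decompose(np.ones(64))
        assert out.imfs == []
        assert np.array_equal(out.residual, np.ones(64))

    def test_pure_tone_first_imf(self):
        t = np.linspace(0, 1, 512)
        x = np.sin(2 * np.pi * 25 * t)
        out = emd_decompose(x)
        r = np.corrcoef(out.imfs[0], x)[0, 1]
        assert r > 0.99

    def test_two_tones_recovered(self):
        # 50 MHz + 400 MHz at 2 GHz sampling
        fs = 2e9
        t = np.arange(1024) / fs
        x = np.sin(2 * np.pi * 400e6 * t) + 2.0 * np.sin(2 * np.pi * 50e6 * t)
        out = emd_decompose(x)
        freqs = np.fft.rfftfreq(len(t), 1 / fs)
        peaks = []
        for imf in out.imfs[:4]:
            if np.sum(imf ** 2) < 1e-3 * np.sum(x ** 2):
                continue
            peaks.append(freqs[np.argmax(np.abs(np.fft.rfft(imf)))])
        df = freqs[1] - freqs[0]
        assert any(abs(p - 400e6) <= df for p in peaks)
        assert any(abs(p - 50e6) <= df for p in peaks)

    def test_completeness_on_random_signals(self, rng):
        for _ in range(10):
            x = rng.standard_normal(200)
            out = emd_decompose(x)
            err = np.max(np.abs(out.reconstruct() - x)) / np.max(np.abs(x))
            assert err < 1e-10

    def test_short_signal_rejected(self):
        with pytest.raises(Exception):
            emd_decompose(np.ones(8))


class TestClassifyIMFs:
    def _impulse_imf(self, n, k):
        x = np.zeros(n)
        x[k] = 1.0
        x[k + 1] = -0.5
        return x

    def test_near_far_and_kept(self, media):
        v = transition_velocity_mm_ns(media)
        dt = 0.05e-9
        n = 1024

        def k_for(dist_mm):
            return int(round(2 * dist_mm / v / (dt * 1e9)))

        imfs = [self._impulse_imf(n, k_for(2.0)),
                self._impulse_imf(n, k_for(80.0)),
                self._impulse_imf(n, k_for(720.0))]
        from mwbreast.preprocess import IMFSet
        out = classify_imfs(IMFSet(imfs=imfs, residual=np.zeros(n)), dt, v,
                            ring_diameter=240.0, max_chord=110.0)
        reasons = [a["reason"] for a in out.annotations]
        assert reasons == ["coupling", "kept", "multipath"]


class TestLossCompensation:
    def test_zero_distance_identity(self, band, media, rng):
        spec = rng.standard_normal(len(band)) + 0j
        out = loss_compensate(spec, band, 0.0, 0.0, 0.5, media)
        assert np.array_equal(out, spec)

    def test_mixture_endpoints(self, band, media):
        ones = np.ones(len(band))
        lo = loss_compensate(ones, band, 0.0, 30.0, 0.0, media)
        hi = loss_compensate(ones, band, 0.0, 30.0, 1.0, media)
        a_ad = complex_wavenumber(band, media.adipose).real
        a_fg = complex_wavenumber(band, media.fibroglandular).real
        assert np.allclose(lo, np.exp(a_ad * 0.03))
        assert np.allclose(hi, np.exp(a_fg * 0.03))

    def test_multiplier_monotonicity(self, band, media):
        ones = np.ones(len(band))
        base = loss_compensate(ones, band, 20.0, 30.0, 0.4, media)
        assert np.all(base >= 1.0)
        assert np.all(np.diff(base) > 0)  # increasing in frequency
        assert np.all(loss_compensate(ones, band, 30.0, 30.0, 0.4, media) >= base)
        assert np.all(loss_compensate(ones, band, 20.0, 40.0, 0.4, media) >= base)
        assert np.all(loss_compensate(ones, band, 20.0, 30.0, 0.6, media) >= base)

    def test_two_depth_echo_ratio_restored(self, band, media):
        """Equal-total-path echoes at 20 vs 50 mm in-breast depth: the
        pre-compensation amplitude ratio follows exp(-2 alpha d), and
        compensation restores parity."""
        a_t = complex_wavenumber(band, media.transition)
        a_in = complex_wavenumber(band, media.interior(0.5)).real
        a_inc = complex_wavenumber(band, media.interior(0.5))
        # two-way: (d_out, d_in) = (160, 40) vs (100, 100) mm
        e_shallow = np.exp(-(a_t * 0.160 + a_inc * 0.040))
        e_deep = np.exp(-(a_t * 0.100 + a_inc * 0.100))
        peak = lambda s: np.abs(to_time_domain(s, band).signal).max()
        pre_ratio = peak(e_deep) / peak(e_shallow)
        # per-frequency the closed form exp(-(a_in - a_t) * 2*30mm) is exact
        r_f = np.exp(-(a_in - a_t.real) * 0.060)
        assert np.allclose(np.abs(e_deep) / np.abs(e_shallow), r_f, rtol=1e-12)
        # broadband peak ratio follows the amplitude-weighted closed form
        predicted = np.sum(np.abs(e_shallow) * r_f) / np.sum(np.abs(e_shallow))
        assert pre_ratio == pytest.approx(predicted, rel=0.05)
        c_shallow = loss_compensate(e_shallow, band, 160.0, 40.0, 0.5, media)
        c_deep = loss_compensate(e_deep, band, 100.0, 100.0, 0.5, media)
        post_ratio = peak(c_deep) / peak(c_shallow)
        assert 0.9 <= post_ratio <= 1.1

    def test_negative_distance_rejected(self, band, media):
        with pytest.raises(Exception):
            loss_compensate(np.ones(len(band)), band, -1.0, 0.0, 0.5, media)


class TestPSDFilter:
    @pytest.mark.parametrize("psd,mode,kept", [
        (4.9, Mode.DEFAULT, True),
        (7.0, Mode.CUSTOM1, True),
        (7.0, Mode.DEFAULT, False),
        (7.0, Mode.CUSTOM2, False),
    ])
    def test_threshold_rules(self, psd, mode, kept):
        assert psd_filter(psd, mode) is kept

    def test_integrated_psd_normalization(self, rng):
        x = rng.standard_normal(100)
        assert integrated_psd(x, 0.5, 2.0) == pytest.approx(
            np.sum(x ** 2) * 0.5 / 2.0)


class TestModeSelection:
    def test_small_breast_custom1(self):
        mode, _ = select_mode(breast_volume_ml=200.0)
        assert mode is Mode.CUSTOM1
        assert mode.n_pca == 12
        assert not mode.psd_filter_enabled

    def test_large_breast_with_fold_custom2(self):
        mode, rule = select_mode(breast_volume_ml=1500.0, fold_present=True)
        assert mode is Mode.CUSTOM2
        assert mode.n_pca == 10

    def test_medium_breast_default(self):
        mode, _ = select_mode(breast_volume_ml=750.0)
        assert mode is Mode.DEFAULT
        assert mode.n_pca == 12
        assert mode.psd_filter_enabled
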