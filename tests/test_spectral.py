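"""Spectral estimators: analytic limits, guards, Monte-Carlo behavior."""

import math

import numpy as np
import pytest

from fcsweep import (
    ConnectivityMatrix,
    CrossSpectra,
    OscillatorSpec,
    band_connectivity,
    ciplv,
    coherence,
    compute_cross_spectra,
    generate_recording,
    imcoh,
    ppc,
    wpli,
)
from fcsweep.spectral import load_connectivity, save_connectivity
from fcsweep.synthcohort import Recording


def carrier_bin(cs, f0=10.0):
    return int(np.argmin(np.abs(cs.freqs - f0)))


def phase_cross_spectra(delta_phis):
    """Fabricate unit-amplitude cross-spectra from per-epoch phase diffs."""
    z = np.exp(1j * np.asarray(delta_phis))
    n = len(z)
    sxy = np.ones((n, 2, 2, 1), dtype=complex)
    sxy[:, 0, 1, 0] = z
    sxy[:, 1, 0, 0] = np.conj(z)
    return CrossSpectra(sxy=sxy, freqs=np.array([10.0]), sfreq=256.0,
                        node_labels=["ch00", "ch01"])


class TestCrossSpectra:
    def test_autospectrum_peaks_at_carrier(self, sine_pair):
        cs = compute_cross_spectra(sine_pair(0.3), (5.0, 20.0), 1024)
        auto = cs.auto()
        assert cs.freqs[np.argmax(auto[0])] == 10.0

    def test_identical_channels_cross_equals_auto(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2048)
        rec = Recording("s", "", np.vstack([x, x]), 256.0, 512)
        cs = compute_cross_spectra(rec, (8.0, 13.0), 512)
        np.testing.assert_allclose(
            cs.sxy[:, 0, 1, :], cs.sxy[:, 0, 0, :], rtol=1e-12
        )

    def test_white_noise_power_matches_periodogram_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4096)
        rec = Recording("s", "", np.vstack([x, x]), 256.0, 512)
        cs = compute_cross_spectra(rec, (8.0, 13.0), 512)
        # independent plain-FFT periodogram, same window and epoching
        from scipy.signal.windows import hann

        win = hann(512, sym=False)
        freqs = np.fft.rfftfreq(512, 1 / 256.0)
        keep = (freqs >= 8.0) & (freqs <= 13.0)
        powers = [
            np.abs(np.fft.rfft(win * x[k * 512:(k + 1) * 512])[keep]) ** 2
            for k in range(8)
        ]
        oracle = np.mean(powers, axis=0)
        np.testing.assert_allclose(cs.auto()[0], oracle, rtol=1e-10)

    def test_too_few_epochs_rejected(self):
        rec = Recording("s", "", np.zeros((2, 600)), 256.0, 512)
        with pytest.raises(ValueError, match="epoch"):
            compute_cross_spectra(rec, (8.0, 13.0), 512)


class TestAnalyticLimits:
    @pytest.mark.parametrize("lag", [math.pi / 4, math.pi / 2, 2.0])
    def test_constant_lag_noiseless_pair(self, sine_pair, lag):
        cs = compute_cross_spectra(sine_pair(lag), (8.0, 13.0), 1024)
        c = carrier_bin(cs)
        assert wpli(cs)[0, 1, c] == pytest.approx(1.0, abs=1e-6)
        assert coherence(cs)[0, 1, c] == pytest.approx(1.0, abs=1e-6)
        assert abs(ciplv(cs)[0, 1, c]) == pytest.approx(1.0, abs=1e-6)
        assert ppc(cs)[0, 1, c] == pytest.approx(1.0, abs=1e-6)
        assert abs(imcoh(cs)[0, 1, c]) == pytest.approx(abs(math.sin(lag)), abs=1e-6)

    def test_zero_lag_suppressed_by_lag_sensitive_measures(self, sine_pair):
        cs = compute_cross_spectra(sine_pair(0.0), (8.0, 13.0), 1024)
        c = carrier_bin(cs)
        assert wpli(cs)[0, 1, c] == 0.0  # zero-denominator convention
        assert imcoh(cs)[0, 1, c] == pytest.approx(0.0, abs=1e-9)
        assert ciplv(cs)[0, 1, c] == 0.0  # |Re PLV| = 1 guard
        assert coherence(cs)[0, 1, c] == pytest.approx(1.0, abs=1e-6)

    def test_ciplv_constant_lag_is_one_for_any_nonzero_lag(self):
        cs = phase_cross_spectra([math.pi / 6] * 20)
        assert ciplv(cs)[0, 1, 0] == pytest.approx(1.0, abs=1e-12)

    def test_ppc_two_opposite_epochs(self):
        cs = phase_cross_spectra([0.0, math.pi])
        assert ppc(cs)[0, 1, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_coherence_amplitude_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2048)
        rec = Recording("s", "", np.vstack([x, 3 * x]), 256.0, 512)
        cs = compute_cross_spectra(rec, (8.0, 13.0), 512)
        np.testing.assert_allclose(coherence(cs)[0, 1], 1.0, atol=1e-12)


class TestIndependenceBehavior:
    def test_wpli_small_for_independent_noise(self):
        # Monte-Carlo over 20 replicate runs of 200 epochs: the per-bin null
        # level of wPLI stays below 0.15
        rng = np.random.default_rng(3)
        per_bin = []
        for _ in range(20):
            rec = Recording("s", "", rng.normal(size=(2, 200 * 256)), 256.0, 256)
            cs = compute_cross_spectra(rec, (8.0, 13.0), 256)
            per_bin.append(wpli(cs)[0, 1])
        assert np.mean(per_bin, axis=0).max() < 0.15

    def test_coherence_bias_level_at_100_epochs(self):
        rng = np.random.default_rng(4)
        rec = Recording("s", "", rng.normal(size=(2, 100 * 256)), 256.0, 256)
        cs = compute_cross_spectra(rec, (8.0, 13.0), 256)
        assert coherence(cs)[0, 1].mean() < 0.2

    def test_ppc_unbiased_under_independence(self):
        # 500 replicates of 100 uniform phase differences: PPC mean ~ 0,
        # in contrast with the O(1/n) bias of squared PLV
        rng = np.random.default_rng(5)
        vals = [
            ppc(phase_cross_spectra(rng.uniform(0, 2 * np.pi, 100)))[0, 1, 0]
            for _ in range(500)
        ]
        vals = np.array(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 1e-3

    def test_volume_conduction_ordering(self):
        # y = x + independent noise: zero-lag mixture. wPLI/ImCoh/ciPLV are
        # suppressed while coherence stays high.
        spec = OscillatorSpec(2, duration=500.0, noise_sd=0.0, seed=6)
        base = generate_recording(spec)
        rng = np.random.default_rng(7)
        y = base.data[0] + rng.normal(0, 1, base.data.shape[1])
        rec = Recording("s", "", np.vstack([base.data[0], y]), 256.0, 256)
        cs = compute_cross_spectra(rec, (8.0, 13.0), 256)
        coh = coherence(cs)[0, 1].mean()
        for f in (wpli, imcoh, ciplv):
            assert abs(f(cs)[0, 1]).mean() < 0.2 < coh


class TestBandConnectivity:
    def test_strong_pair_is_argmax_for_all_measures(self):
        spec = OscillatorSpec(
            n_channels=5, duration=60.0, noise_sd=0.0,
            coupled_pairs=((1, 3, math.pi / 2, 1.0),), seed=8,
        )
        rec = generate_recording(spec, epoch_length=512)
        for measure in ("wpli", "imcoh", "coherence", "ciplv", "ppc"):
            m = band_connectivity(rec, measure)
            iu = np.triu_indices(5, 1)
            top = np.argmax(m.weights[iu])
            assert (iu[0][top], iu[1][top]) == (1, 3), measure

    def test_symmetry_is_exact(self):
        spec = OscillatorSpec(n_channels=4, duration=10.0, seed=9)
        rec = generate_recording(spec, epoch_length=512)
        for measure in ("wpli", "imcoh", "ppc"):
            w = band_connectivity(rec, measure).weights
            assert np.array_equal(w, w.T)
            assert np.all(np.diag(w) == 0)

    def test_rectification_modes(self):
        spec = OscillatorSpec(
            n_channels=2, duration=30.0, noise_sd=0.1,
            coupled_pairs=((0, 1, math.pi / 2, 1.0),), seed=10,
        )
        # follower leads by pi/2, so Im(S_xy) = sin(-pi/2) < 0 at the carrier
        rec = generate_recording(spec, epoch_length=512)
        raw = band_connectivity(rec, "imcoh", rectify="raw").weights[0, 1]
        rect = band_connectivity(rec, "imcoh", rectify="default").weights[0, 1]
        assert raw < 0 and rect == pytest.approx(abs(raw))

    def test_zero_power_channel_named_in_error(self):
        data = np.vstack([np.zeros(2048), np.random.default_rng(0).normal(size=2048)])
        rec = Recording("s", "", data, 256.0, 512)
        with pytest.raises(ValueError, match="ch00"):
            band_connectivity(rec, "imcoh")

    def test_unknown_measure_rejected(self, sine_pair):
        with pytest.raises(ValueError, match="unknown measure"):
            band_connectivity(sine_pair(0.5), "granger")


def test_connectivity_matrix_roundtrip(tmp_path):
    rng = np.random.default_rng(11)
    a = rng.random((6, 6))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    m = ConnectivityMatrix("S01", "wpli", (8.0, 13.0),
                           [f"n{i}" for i in range(6)], a)
    path = save_connectivity(m, tmp_path)
    back = load_connectivity(path)
    np.testing.assert_allclose(back.weights, m.weights, rtol=1e-10)
    assert back.subject_id == "S01" and back.measure == "wpli"
    assert back.node_labels == m.node_labels
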