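import numpy as np
import pytest
import scipy.signal
from hypothesis import given, settings
from hypothesis import strategies as st

from stochvoc.signals import Waveform, make_noise, make_tone
from stochvoc.vocoder import (
    BandSpec,
    SpikeTrain,
    VocoderConfig,
    aggregate_or,
    band_filter,
    control_config,
    design_filterbank,
    reconstruct_band,
    spike_probability,
    stochastic_spike_train,
    vocode,
    vocode_channels,
)

from conftest import constant_wave


class TestFilterbankDesign:
    def test_edges_closed_form(self):
        bank = design_filterbank(10, 100.0, 10000.0, 4, 22050.0)
        expected = 100.0 * (10000.0 / 100.0) ** (np.arange(11) / 10.0)
        np.testing.assert_allclose(bank.edges, expected, rtol=1e-12)
        # adjacent edge ratio is 10**(1/5)
        np.testing.assert_allclose(bank.edges[1:] / bank.edges[:-1], 10 ** 0.2)

    def test_single_band(self):
        bank = design_filterbank(1, 100.0, 10000.0, 4, 44100.0)
        assert len(bank) == 1
        assert bank.bands[0].f_lo == 100.0
        assert bank.bands[0].f_hi == 10000.0

    def test_neighbors_share_edges(self):
        bank = design_filterbank(5, 100.0, 10000.0, 4, 22050.0)
        for a, b in zip(bank.bands, bank.bands[1:]):
            assert a.f_hi == b.f_lo

    def test_minus_3db_at_edges(self):
        bank = design_filterbank(10, 100.0, 10000.0, 4, 22050.0)
        for band in bank.bands:
            sos = band.sos(22050.0)
            w, h = scipy.signal.sosfreqz(sos, worN=[band.f_lo, band.f_hi], fs=22050.0)
            gains_db = 20 * np.log10(np.abs(h))
            np.testing.assert_allclose(gains_db, -3.0, atol=0.5)

    def test_rejects_f_max_at_nyquist(self):
        with pytest.raises(ValueError):
            design_filterbank(10, 100.0, 12000.0, 4, 22050.0)

    def test_rejects_zero_bands(self):
        with pytest.raises(ValueError):
            design_filterbank(0, 100.0, 10000.0, 4, 22050.0)


class TestBandFilter:
    def test_stopband_rejection(self):
        noise = make_noise("white", 5.0, 22050.0, 0.1, 4)
        out = band_filter(noise, BandSpec(1000.0, 2000.0))
        f, p = scipy.signal.welch(out.samples, fs=out.fs, nperseg=4096)
        in_band = p[(f > 1100) & (f < 1900)].mean()
        at_4k = p[np.abs(f - 4000) < 100].mean()
        assert 10 * np.log10(in_band / at_4k) > 24.0

    def test_zero_in_zero_out(self):
        out = band_filter(Waveform(np.zeros(1000), 22050.0), BandSpec(1000.0, 2000.0))
        assert not np.any(out.samples)

    def test_length_preserved(self):
        noise = make_noise("white", 0.3, 22050.0, 0.1, 4)
        assert len(band_filter(noise, BandSpec(500.0, 900.0))) == len(noise)

    def test_center_tone_passes_unity(self):
        band = BandSpec(1000.0, 2000.0)
        fc = np.sqrt(band.f_lo * band.f_hi)
        w, h = scipy.signal.sosfreqz(band.sos(22050.0), worN=[fc], fs=22050.0)
        assert 20 * np.log10(np.abs(h[0])) == pytest.approx(0.0, abs=1.0)


class TestStochasticSpikeTrain:
    def test_zero_input_no_spikes(self, rng):
        train = stochastic_spike_train(Waveform(np.zeros(1000), 22050.0), rng)
        assert train.rate() == 0.0

    def test_constant_half_rate(self, rng):
        # binomial oracle: 1e5 draws at p=0.5, 3 sigma = 3*sqrt(0.25/1e5) ~ 0.0047
        train = stochastic_spike_train(constant_wave(0.5), rng)
        assert train.rate() == pytest.approx(0.5, abs=0.005)

    def test_rate_equals_rectified_amplitude(self, rng):
        train = stochastic_spike_train(constant_wave(-0.2), rng)
        sigma = np.sqrt(0.2 * 0.8 / 100_000)
        assert train.rate() == pytest.approx(0.2, abs=3 * sigma)

    def test_determinism(self):
        w = make_noise("white", 0.1, 22050.0, 0.1, 0)
        a = stochastic_spike_train(w, np.random.default_rng(42))
        b = stochastic_spike_train(w, np.random.default_rng(42))
        np.testing.assert_array_equal(a.spikes, b.spikes)

    def test_rejects_full_scale(self, rng):
        with pytest.raises(ValueError):
            stochastic_spike_train(constant_wave(1.0, n=10), rng)


class TestAggregateOr:
    def test_empty_list(self):
        with pytest.raises(ValueError):
            aggregate_or([])

    def test_all_zero_identity(self):
        trains = [SpikeTrain(np.zeros(100), 22050.0) for _ in range(5)]
        assert aggregate_or(trains).rate() == 0.0

    def test_all_ones_absorption(self):
        trains = [
            SpikeTrain(np.zeros(100), 22050.0),
            SpikeTrain(np.ones(100), 22050.0),
        ]
        assert aggregate_or(trains).rate() == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            aggregate_or([SpikeTrain(np.zeros(10), 22050.0), SpikeTrain(np.zeros(11), 22050.0)])

    @pytest.mark.parametrize("a,n", [(0.05, 1), (0.05, 10), (0.2, 10), (0.5, 3)])
    def test_rate_matches_analytic(self, a, n, rng):
        w = constant_wave(a, n=50_000)
        agg = aggregate_or([stochastic_spike_train(w, rng) for _ in range(n)])
        p = spike_probability(a, n)
        sigma = np.sqrt(p * (1 - p) / len(w))
        assert agg.rate() == pytest.approx(p, abs=max(3 * sigma, 1e-4))


class TestSpikeProbability:
    def test_zero_samplers(self):
        assert spike_probability(0.7, 0) == 0.0

    def test_two_fair_samplers(self):
        # enumerating the four joint outcomes of two Bernoulli(0.5) samplers:
        # {00, 01, 10, 11} -> at least one fires in 3 of 4
        assert spike_probability(0.5, 2) == pytest.approx(0.75, abs=1e-15)

    def test_large_n_saturates(self):
        assert spike_probability(0.1, 300) == pytest.approx(1 - 0.9**300, rel=1e-12)
        assert spike_probability(0.1, 300) > 1 - 1e-13

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            spike_probability(1.0, 10)
        with pytest.raises(ValueError):
            spike_probability(-0.1, 10)

    def test_array_input(self):
        a = np.array([0.0, 0.25, 0.5])
        np.testing.assert_allclose(spike_probability(a, 1), a)

    @given(
        a=st.floats(0.0, 0.99),
        n1=st.integers(0, 500),
        n2=st.integers(0, 500),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_n(self, a, n1, n2):
        lo, hi = sorted((n1, n2))
        assert spike_probability(a, lo) <= spike_probability(a, hi) + 1e-15

    @given(
        a1=st.floats(0.0, 0.99),
        a2=st.floats(0.0, 0.99),
        n=st.integers(1, 500),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_amplitude(self, a1, a2, n):
        lo, hi = sorted((a1, a2))
        assert spike_probability(lo, n) <= spike_probability(hi, n) + 1e-12


class TestReconstructBand:
    def test_all_ones_identity(self):
        w = make_noise("white", 0.05, 22050.0, 0.1, 0)
        out = reconstruct_band(SpikeTrain(np.ones(len(w)), w.fs), w)
        np.testing.assert_array_equal(out.samples, w.samples)

    def test_all_zero_silence(self):
        w = make_noise("white", 0.05, 22050.0, 0.1, 0)
        out = reconstruct_band(SpikeTrain(np.zeros(len(w)), w.fs), w)
        assert not np.any(out.samples)

    def test_samples_are_kept_or_zeroed(self, rng):
        w = make_noise("white", 0.05, 22050.0, 0.1, 0)
        train = stochastic_spike_train(w, rng)
        out = reconstruct_band(train, w)
        kept = out.samples == w.samples
        zeroed = out.samples == 0.0
        assert np.all(kept | zeroed)

    def test_length_mismatch(self):
        w = make_noise("white", 0.05, 22050.0, 0.1, 0)
        with pytest.raises(ValueError):
            reconstruct_band(SpikeTrain(np.zeros(len(w) - 1), w.fs), w)


class TestVocoderConfig:
    def test_n_total(self):
        assert VocoderConfig(n_samplers=300).n_total == 3000
        assert VocoderConfig(n_samplers=200, n_bands=5).n_total == 1000

    def test_rejects_negative_n(self):
        with pytest.raises(ValueError):
            VocoderConfig(n_samplers=-1)

    def test_order_conventions(self):
        assert VocoderConfig(n_samplers=1).effective_order() == 4
        assert VocoderConfig(n_samplers=1, order_convention="total").effective_order() == 2
        with pytest.raises(ValueError):
            VocoderConfig(n_samplers=1, order_convention="weird")


class TestVocode:
    def test_control_equals_analysis_synthesis(self, demo_chirp):
        cfg = VocoderConfig(n_samplers=0, control=True)
        out, bands = vocode_channels(demo_chirp, cfg)
        # all-spikes reconstruction is the plain filterbank analysis-synthesis
        acc = np.zeros(len(demo_chirp))
        fb = design_filterbank(10, 100.0, 10000.0, 4, demo_chirp.fs)
        for sos in fb.sos():
            y = scipy.signal.sosfilt(sos, demo_chirp.samples)
            acc += scipy.signal.sosfilt(sos, y)
        np.testing.assert_allclose(out.samples, acc, atol=1e-12)

    def test_control_is_deterministic(self, demo_chirp):
        cfg = VocoderConfig(n_samplers=10, control=True, seed=0)
        a = vocode(demo_chirp, cfg)
        b = vocode(demo_chirp, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_n0_silent(self, word):
        out = vocode(word, VocoderConfig(n_samplers=0))
        assert not np.any(out.samples)

    def test_n0_with_equalize_raises(self, word):
        with pytest.raises(ValueError, match="no energy"):
            vocode(word, VocoderConfig(n_samplers=0, equalize_rms=True))

    def test_seed_contract(self, word):
        cfg = VocoderConfig(n_samplers=30, seed=77)
        a = vocode(word, cfg)
        b = vocode(word, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)
        c = vocode(word, VocoderConfig(n_samplers=30, seed=78))
        assert not np.array_equal(a.samples, c.samples)

    def test_large_n_converges_to_control(self, demo_chirp):
        cfg = VocoderConfig(n_samplers=1000, seed=5)
        ctrl = vocode(demo_chirp, control_config(cfg))
        voc = vocode(demo_chirp, cfg)
        rel_err = np.sqrt(np.mean((voc.samples - ctrl.samples) ** 2)) / ctrl.rms()
        assert rel_err < 0.01

    def test_equalize_rms_matches_input(self, word):
        out = vocode(word, VocoderConfig(n_samplers=10, seed=3, equalize_rms=True))
        assert out.rms() == pytest.approx(word.rms(), rel=1e-9)

    def test_literal_and_aggregated_paths_agree_in_rate(self):
        # both sampling paths must have the same per-sample spike distribution
        from stochvoc.vocoder import _aggregated_train

        w = constant_wave(0.2, n=50_000)
        n = 10
        p = spike_probability(0.2, n)
        sigma = np.sqrt(p * (1 - p) / len(w))
        for literal in (False, True):
            cfg = VocoderConfig(n_samplers=n, seed=6, literal_or=literal)
            train = _aggregated_train(w, 0, cfg)
            assert train.rate() == pytest.approx(p, abs=3 * sigma)

    def test_monotone_fidelity_in_n(self, word):
        # expected reconstruction error decreases with more samplers
        errs = []
        for n in (3, 30, 300):
            cfg = VocoderConfig(n_samplers=n, seed=9)
            ctrl = vocode(word, control_config(cfg))
            voc = vocode(word, cfg)
            errs.append(np.mean((voc.samples - ctrl.samples) ** 2))
        assert errs[0] > errs[1] > errs[2]

    def test_monotone_fidelity_in_level(self, word):
        from stochvoc.signals import rms_equalize

        errs = []
        for rms in (0.001, 0.01, 0.1):
            scaled = rms_equalize(word, rms)
            cfg = VocoderConfig(n_samplers=30, seed=9)
            ctrl = vocode(scaled, control_config(cfg))
            voc = vocode(scaled, cfg)
            errs.append(np.mean((voc.samples - ctrl.samples) ** 2) / np.mean(ctrl.samples**2))
        assert errs[0] > errs[1] > errs[2]

    def test_rejects_full_scale_input(self):
        w = Waveform(np.linspace(-1.0, 1.0, 1000), 22050.0)
        with pytest.raises(ValueError):
            vocode(w, VocoderConfig(n_samplers=1))
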