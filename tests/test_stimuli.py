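import numpy as np
import pytest
from scipy.signal import fftconvolve
from scipy.stats import kstest

from revspeech import room as rm
from revspeech import stimuli as st

FS = 16000.0


@pytest.fixture(scope="module")
def speech_like():
    corpus = st.synthetic_corpus(8, rng_seed=11, duration=0.8)
    return st.Signal(np.concatenate([s.samples for s in corpus]), FS)


@pytest.fixture(scope="module")
def small_corpus():
    return st.synthetic_corpus(20, rng_seed=5, duration=0.6)


class TestPhaseRandomize:
    def test_magnitude_spectrum_preserved(self, speech_like):
        out = st.phase_randomize(speech_like, rng_seed=3)
        m_in = np.abs(np.fft.rfft(speech_like.samples))
        m_out = np.abs(np.fft.rfft(out.samples))
        np.testing.assert_allclose(m_out, m_in, rtol=1e-6, atol=1e-9)

    def test_output_is_real_and_same_length(self, speech_like):
        out = st.phase_randomize(speech_like, rng_seed=3)
        assert out.samples.dtype.kind == "f"
        assert len(out.samples) == len(speech_like.samples)

    def test_modulation_power_strongly_reduced(self, speech_like):
        out = st.phase_randomize(speech_like, rng_seed=3)
        p_in = st.modulation_spectrum(speech_like).total_power
        p_out = st.modulation_spectrum(out).total_power
        assert 10 * np.log10(p_in / p_out) >= 10.0

    def test_deterministic(self, speech_like):
        a = st.phase_randomize(speech_like, rng_seed=9)
        b = st.phase_randomize(speech_like, rng_seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            st.phase_randomize(st.Signal(np.array([]), FS), 0)


class TestVocode:
    def test_silent_corpus_silent_output(self):
        silent = [st.Signal(np.zeros(8000), FS)]
        out = st.vocode(silent, rng_seed=0)
        assert np.all(out.samples == 0.0)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            st.vocode([], rng_seed=0)

    def test_envelope_correlation_with_am_input(self):
        # band-limited AM input: output envelope should track it
        rng = np.random.default_rng(2)
        t = np.arange(int(4 * FS)) / FS
        am = (1.0 + 0.95 * np.sin(2 * np.pi * 4.0 * t))
        x = am * rng.standard_normal(len(t))
        out = st.vocode([st.Signal(x, FS)], rng_seed=1)
        env_in = st.envelope(st.Signal(x, FS))
        env_out = st.envelope(out)
        r = np.corrcoef(env_in, env_out)[0, 1]
        assert r > 0.8

    def test_split_corpus_two_equal_streams(self):
        corpus = [st.Signal(np.zeros(10), FS) for _ in range(288)]
        a, b = st.split_corpus(corpus)
        assert len(a) == 144 and len(b) == 144

    def test_split_odd_corpus_rejected(self):
        with pytest.raises(ValueError):
            st.split_corpus([st.Signal(np.zeros(10), FS)] * 3)


class TestSpectralMatch:
    def test_identity_reference(self, speech_like):
        out = st.spectral_match(speech_like, speech_like)
        _, lv_in = st.band_levels_db(speech_like)
        _, lv_out = st.band_levels_db(out)
        dev = (lv_out - lv_out.mean()) - (lv_in - lv_in.mean())
        assert np.max(np.abs(dev)) < 0.5

    def test_white_to_pink_slope(self):
        rng = np.random.default_rng(0)
        n = int(4 * FS)
        white = st.Signal(rng.standard_normal(n), FS)
        f = np.fft.rfftfreq(n, 1 / FS)
        shaping = np.where(f > 0, 1 / np.sqrt(np.maximum(f, 1.0)), 0.0)
        pink = st.Signal(
            np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * shaping, n),
            FS)
        out = st.spectral_match(white, pink)
        # per-band agreement with the pink reference within 1 dB
        _, lv = st.band_levels_db(out)
        _, lv_ref = st.band_levels_db(pink)
        dev = (lv - lv.mean()) - (lv_ref - lv_ref.mean())
        assert np.max(np.abs(dev)) < 1.0
        # PSD slope of -3 dB/octave recovered
        from scipy.signal import welch
        freqs, psd = welch(out.samples, fs=FS, nperseg=4096)
        m = (freqs >= 100) & (freqs <= 6000)
        slope = np.polyfit(np.log2(freqs[m]), 10 * np.log10(psd[m]), 1)[0]
        assert slope == pytest.approx(-3.0, abs=1.0)

    def test_stationary_masker_matches_target_spectrum(self, small_corpus):
        target_ref = st.Signal(
            np.concatenate([s.samples for s in small_corpus]), FS)
        stat = st.make_stationary_masker(small_corpus, rng_seed=4)
        matched = st.spectral_match(stat, target_ref)
        _, lv_ref = st.band_levels_db(target_ref)
        _, lv_out = st.band_levels_db(matched)
        dev = (lv_out - lv_out.mean()) - (lv_ref - lv_ref.mean())
        assert np.max(np.abs(dev)) < 1.0

    def test_silent_input_rejected(self, speech_like):
        with pytest.raises(ValueError):
            st.spectral_match(st.Signal(np.zeros(1000), FS), speech_like)


class TestModulationSpectrum:
    def test_constant_tone_near_zero_power(self):
        t = np.arange(int(4 * FS)) / FS
        tone = st.Signal(np.sin(2 * np.pi * 1000 * t), FS)
        ms = st.modulation_spectrum(tone)
        assert ms.total_power < 1e-4

    def test_4hz_am_dominant_band(self):
        rng = np.random.default_rng(1)
        t = np.arange(int(8 * FS)) / FS
        x = (1 + np.sin(2 * np.pi * 4.0 * t)) * rng.standard_normal(len(t))
        ms = st.modulation_spectrum(st.Signal(x, FS))
        assert ms.band_centres[int(np.argmax(ms.power))] == 4.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            st.modulation_spectrum(st.Signal(np.ones(int(FS)), FS))

    def test_silent_rejected(self):
        with pytest.raises(ValueError):
            st.modulation_spectrum(st.Signal(np.zeros(int(4 * FS)), FS))

    def test_reverberation_reduces_modulated_masker_power(
            self, small_corpus, reference_rirs):
        masker = st.make_speech_modulated_masker(small_corpus, rng_seed=7)
        dry = rm.normalize_energy(reference_rirs[0.15])
        wet = rm.normalize_energy(reference_rirs[1.5])
        p_dry = st.modulation_spectrum(st.Signal(
            fftconvolve(masker.samples, dry.samples), FS))
        p_wet = st.modulation_spectrum(st.Signal(
            fftconvolve(masker.samples, wet.samples), FS))
        assert np.all(p_wet.power < p_dry.power)


class TestMakeTrialStimulus:
    @pytest.fixture(scope="class")
    def target_and_masker(self, small_corpus):
        target = small_corpus[0]
        masker = st.make_stationary_masker(small_corpus, rng_seed=9)
        return target, masker

    def test_snr_calibration_exact(self, target_and_masker):
        target, masker = target_and_masker
        trial = st.make_trial_stimulus(target, masker, snr=0.0,
                                       reverb_application="none",
                                       rirs=None, rng_seed=1)
        fs = trial.target.sample_rate
        i0 = int(round(trial.onset_lead * fs))
        seg = trial.masker.samples[i0:i0 + len(trial.target.samples)]
        diff = (20 * np.log10(trial.target.rms)
                - 20 * np.log10(np.sqrt(np.mean(seg**2))))
        assert diff == pytest.approx(0.0, abs=0.1)

    def test_masker_one_second_longer(self, target_and_masker):
        target, masker = target_and_masker
        trial = st.make_trial_stimulus(target, masker, snr=-4.0,
                                       reverb_application="none",
                                       rirs=None, rng_seed=2)
        assert trial.masker.duration == pytest.approx(
            trial.target.duration + 1.0, abs=0.01)

    def test_speech_only_leaves_masker_dry(self, target_and_masker,
                                           reference_rirs):
        target, masker = target_and_masker
        rirs = {"target": rm.normalize_energy(reference_rirs[0.5])}
        trial = st.make_trial_stimulus(target, masker, snr=0.0,
                                       reverb_application="speech_only",
                                       rirs=rirs, rng_seed=3)
        # reverberant target is longer than the dry one
        assert len(trial.target.samples) > len(target.samples)
        # masker excerpt has exactly target + 1 s duration (not convolved)
        assert trial.masker.duration == pytest.approx(
            trial.target.duration + 1.0, abs=0.01)

    def test_onset_lead_uniform(self, target_and_masker):
        target, masker = target_and_masker
        leads = np.array([
            st.make_trial_stimulus(target, masker, 0.0, "none", None,
                                   rng_seed=i).onset_lead
            for i in range(400)])
        assert leads.min() >= 0.300 and leads.max() <= 0.700
        stat = kstest(leads, "uniform", args=(0.300, 0.400))
        assert stat.pvalue > 0.01

    def test_short_masker_rejected(self, target_and_masker):
        target, _ = target_and_masker
        short = st.Signal(np.random.default_rng(0).standard_normal(
            len(target.samples)), FS)
        with pytest.raises(ValueError):
            st.make_trial_stimulus(target, short, 0.0, "none", None, 0)

    def test_seed_deterministic(self, target_and_masker):
        target, masker = target_and_masker
        a = st.make_trial_stimulus(target, masker, -8.0, "none", None, 42)
        b = st.make_trial_stimulus(target, masker, -8.0, "none", None, 42)
        np.testing.assert_array_equal(a.masker.samples, b.masker.samples)
        assert a.onset_lead == b.onset_lead
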