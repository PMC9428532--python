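"""Target and masker signal construction, and envelope modulation spectra.

Builds the two masker families used throughout: a speech-modulated masker
(two summed single-voice noise-vocoded streams) and a stationary noise
with the same long-term spectrum (phase randomization + FIR spectral
matching), plus reverberant mixing of target and masker at a prescribed
SNR with calibrated levels, raised-cosine gating and a randomized masker
onset lead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .room import RIR

__all__ = [
    "Signal",
    "TrialStimulus",
    "ModulationSpectrum",
    "MODULATION_BANDS",
    "phase_randomize",
    "vocode",
    "split_corpus",
    "make_speech_modulated_masker",
    "make_stationary_masker",
    "spectral_match",
    "band_levels_db",
    "envelope",
    "modulation_spectrum",
    "make_trial_stimulus",
    "synthetic_sentence",
    "synthetic_corpus",
]

#: Modulation-spectrum octave-band centres (Hz).
MODULATION_BANDS: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)

#: Digital full-scale reference: an RMS of 1.0 corresponds to this dB SPL.
SPL_REF_DB: float = 100.0


@dataclass(frozen=True)
class Signal:
    """A mono waveform with a role tag."""

    samples: np.ndarray
    sample_rate: float
    label: str = "target"

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def level_db(self) -> float:
        """Broadband level in model dB SPL (RMS 1.0 == SPL_REF_DB)."""
        if self.rms <= 0:
            raise ValueError("silent signal has no level")
        return SPL_REF_DB + 20.0 * math.log10(self.rms)


@dataclass(frozen=True)
class TrialStimulus:
    """Target and masker of one trial, calibrated to a prescribed SNR."""

    target: Signal
    masker: Signal
    snr: float
    reverb_application: str
    rt_label: float
    onset_lead: float          # seconds before target onset
    target_level: float        # model dB SPL

    def __post_init__(self):
        if self.reverb_application not in (
            "speech_only", "noise_only", "both", "none"
        ):
            raise ValueError(
                f"bad reverb_application {self.reverb_application!r}")

    def mixture(self) -> Signal:
        """Masker with the target added at its onset lead."""
        fs = self.target.sample_rate
        start = int(round(self.onset_lead * fs))
        mix = self.masker.samples.copy()
        seg = mix[start:start + len(self.target.samples)]
        seg += self.target.samples[: len(seg)]
        return Signal(samples=mix, sample_rate=fs, label="mixture")


@dataclass(frozen=True)
class ModulationSpectrum:
    """Envelope modulation power integrated in octave bands."""

    band_centres: tuple[float, ...]
    power: np.ndarray           # linear modulation power per band

    @property
    def power_db(self) -> np.ndarray:
        return 10.0 * np.log10(np.maximum(self.power, 1e-30))

    @property
    def total_power(self) -> float:
        return float(np.sum(self.power))


def phase_randomize(signal: Signal, rng_seed: int) -> Signal:
    """Replace the phase spectrum with random phases (magnitudes kept).

    DC and Nyquist bins are left untouched so the output is exactly real
    and the magnitude spectrum is preserved bin by bin.
    """
    x = signal.samples
    if len(x) == 0:
        raise ValueError("empty input")
    rng = np.random.default_rng(rng_seed)
    spec = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2.0 * np.pi, len(spec))
    mags = np.abs(spec)
    out_spec = mags * np.exp(1j * phases)
    out_spec[0] = spec[0]
    if len(x) % 2 == 0:
        out_spec[-1] = spec[-1]
    out = np.fft.irfft(out_spec, n=len(x))
    return replace(signal, samples=out, label="masker_stat")


def _erb_number(f: np.ndarray | float):
    return 21.4 * np.log10(4.37e-3 * np.asarray(f, dtype=float) + 1.0)


def _erb_to_hz(e: np.ndarray | float):
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) / 4.37e-3


def _channel_edges(n_channels: int, fs: float,
                   f_lo: float = 100.0, f_hi: float = 8000.0) -> np.ndarray:
    hi = min(f_hi, 0.45 * fs)
    edges = _erb_to_hz(np.linspace(_erb_number(f_lo), _erb_number(hi),
                                   n_channels + 1))
    return np.asarray(edges)


def vocode(
    corpus: list[Signal],
    n_channels: int = 3,
    env_cutoff: float = 60.0,
    rng_seed: int = 0,
) -> Signal:
    """Noise-vocode a concatenated sentence corpus into one stream.

    Channel edges are equally spaced on an ERB scale over 100-8000 Hz;
    each channel's envelope (rectify + low-pass at ``env_cutoff``) is
    imposed on a band-limited noise carrier, and the channels are summed.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    fs = corpus[0].sample_rate
    if env_cutoff >= fs / 2:
        raise ValueError("env_cutoff must be below Nyquist")
    x = np.concatenate([s.samples for s in corpus])
    rng = np.random.default_rng(rng_seed)
    edges = _channel_edges(n_channels, fs)
    env_sos = sps.butter(4, env_cutoff, btype="lowpass", fs=fs, output="sos")
    out = np.zeros(len(x))
    if np.max(np.abs(x)) == 0.0:
        return Signal(samples=out, sample_rate=fs, label="masker_mod")
    for lo, hi in zip(edges[:-1], edges[1:]):
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        band = sps.sosfiltfilt(sos, x)
        env = sps.sosfiltfilt(env_sos, np.abs(band))
        env = np.maximum(env, 0.0)
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(len(x)))
        carrier_rms = np.sqrt(np.mean(carrier**2))
        if carrier_rms > 0:
            carrier /= carrier_rms
        out += env * carrier
    return Signal(samples=out, sample_rate=fs, label="masker_mod")


def split_corpus(corpus: list[Signal]) -> tuple[list[Signal], list[Signal]]:
    """Split an even-sized corpus into the two single-voice halves."""
    if len(corpus) % 2 != 0:
        raise ValueError(
            f"corpus size {len(corpus)} cannot be split into two equal "
            "streams")
    half = len(corpus) // 2
    return corpus[:half], corpus[half:]


def make_speech_modulated_masker(
    corpus: list[Signal],
    n_channels: int = 3,
    env_cutoff: float = 60.0,
    rng_seed: int = 0,
) -> Signal:
    """Two-voice vocoded masker: the sum of two vocoded half-corpora."""
    first, second = split_corpus(corpus)
    v1 = vocode(first, n_channels, env_cutoff, rng_seed)
    v2 = vocode(second, n_channels, env_cutoff, rng_seed + 1)
    n = min(len(v1.samples), len(v2.samples))
    return Signal(samples=v1.samples[:n] + v2.samples[:n],
                  sample_rate=v1.sample_rate, label="masker_mod")


def make_stationary_masker(corpus: list[Signal], rng_seed: int = 0) -> Signal:
    """Phase-randomized concatenation of the corpus (stationary noise)."""
    if not corpus:
        raise ValueError("empty corpus")
    concat = Signal(
        samples=np.concatenate([s.samples for s in corpus]),
        sample_rate=corpus[0].sample_rate,
        label="masker_stat",
    )
    return phase_randomize(concat, rng_seed)


def _third_octave_centres(f_lo: float = 100.0, f_hi: float = 8000.0):
    n = np.arange(-30, 31)
    centres = 1000.0 * 2.0 ** (n / 3.0)
    return centres[(centres >= f_lo) & (centres <= f_hi)]


def band_levels_db(signal: Signal, f_lo: float = 100.0,
                   f_hi: float = 8000.0) -> tuple[np.ndarray, np.ndarray]:
    """Long-term third-octave band levels (dB) via a Welch PSD."""
    fs = signal.sample_rate
    nper = min(len(signal.samples), 4096)
    freqs, psd = sps.welch(signal.samples, fs=fs, nperseg=nper)
    centres = _third_octave_centres(f_lo, min(f_hi, 0.499 * fs))
    levels = np.empty(len(centres))
    for i, fc in enumerate(centres):
        lo, hi = fc * 2 ** (-1 / 6), fc * 2 ** (1 / 6)
        m = (freqs >= lo) & (freqs < hi)
        if not np.any(m):
            raise ValueError(f"no PSD support in band {fc:.0f} Hz")
        levels[i] = 10.0 * np.log10(np.trapezoid(psd[m], freqs[m]) + 1e-30)
    return centres, levels


def spectral_match(signal: Signal, reference: Signal,
                   fir_length: int = 512) -> Signal:
    """FIR-filter ``signal`` so its long-term spectrum matches ``reference``.

    The correction gains are measured in third-octave bands over
    100-8000 Hz and realized with a linear-phase FIR (delay compensated).
    """
    if signal.rms <= 0 or reference.rms <= 0:
        raise ValueError("both signals must be non-silent")
    fs = signal.sample_rate
    centres, sig_lv = band_levels_db(signal)
    _, ref_lv = band_levels_db(reference)
    gains_db = ref_lv - sig_lv
    gains_db -= np.mean(gains_db)        # overall level handled elsewhere
    nyq = fs / 2.0
    freqs = np.concatenate(([0.0], centres, [nyq]))
    g = 10.0 ** (gains_db / 20.0)
    gains = np.concatenate(([g[0]], g, [g[-1]]))
    fir = sps.firwin2(fir_length | 1, freqs, gains, fs=fs)
    out = sps.fftconvolve(signal.samples, fir, mode="full")
    delay = (len(fir) - 1) // 2
    out = out[delay:delay + len(signal.samples)]
    return replace(signal, samples=out)


def envelope(signal: Signal, cutoff: float = 30.0) -> np.ndarray:
    """Low-passed magnitude of the analytic signal."""
    env = np.abs(sps.hilbert(signal.samples))
    sos = sps.butter(4, cutoff, btype="lowpass", fs=signal.sample_rate,
                     output="sos")
    return np.maximum(sps.sosfiltfilt(sos, env), 0.0)


def modulation_spectrum(signal: Signal) -> ModulationSpectrum:
    """Envelope modulation power in octave bands centred at 1-16 Hz.

    The envelope is divided by its mean (so the result is level
    independent), its DC removed, and the power spectrum integrated over
    each octave band.
    """
    if signal.duration < 2.0:
        raise ValueError("need >= 2 s of signal to resolve the 1 Hz band")
    env = envelope(signal)
    mean = env.mean()
    if mean <= 0:
        raise ValueError("silent signal: mean envelope is zero")
    env = env / mean - 1.0
    # decimate the envelope to ease the PSD of very long signals
    fs = signal.sample_rate
    factor = max(1, int(fs // 64))
    if factor > 1:
        env = sps.decimate(env, factor, ftype="fir", zero_phase=True)
    fs_env = fs / factor
    nper = int(min(len(env), 8 * fs_env))
    freqs, psd = sps.welch(env, fs=fs_env, nperseg=nper)
    power = np.empty(len(MODULATION_BANDS))
    for i, fc in enumerate(MODULATION_BANDS):
        lo, hi = fc / math.sqrt(2), fc * math.sqrt(2)
        m = (freqs >= lo) & (freqs < hi)
        power[i] = np.trapezoid(psd[m], freqs[m]) if np.any(m) else 0.0
    return ModulationSpectrum(band_centres=MODULATION_BANDS, power=power)


def _raised_cosine_gate(n: int, fs: float, ramp: float = 0.010) -> np.ndarray:
    k = min(int(round(ramp * fs)), n // 2)
    window = np.ones(n)
    if k > 0:
        ramp_up = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
        window[:k] = ramp_up
        window[-k:] = ramp_up[::-1]
    return window


def _convolve_trim(x: np.ndarray, rir: RIR) -> np.ndarray:
    return sps.fftconvolve(x, rir.samples)[: len(x) + len(rir.samples) - 1]


def make_trial_stimulus(
    target: Signal,
    masker: Signal,
    snr: float,
    reverb_application: str,
    rirs: dict[str, RIR] | None,
    rng_seed: int = 0,
    rt_label: float = 0.15,
    target_level: float = 50.0,
    ramp: float = 0.010,
) -> TrialStimulus:
    """Assemble a calibrated reverberant trial.

    The masker excerpt is one second longer than the target, begins a
    uniformly random 300-700 ms before it, and is gated with 10 ms
    raised-cosine ramps.  The target is calibrated to ``target_level``
    (model dB SPL); the masker level is then set so the broadband level
    difference over the target's duration equals ``snr`` -- measured
    after reverberation is applied.
    """
    if not math.isfinite(snr):
        raise ValueError("snr must be finite")
    fs = target.sample_rate
    rng = np.random.default_rng(rng_seed)

    tgt = target.samples
    if reverb_application in ("speech_only", "both"):
        tgt = _convolve_trim(tgt, rirs["target"])

    onset_lead = float(rng.uniform(0.300, 0.700))
    need = len(tgt) + int(round(1.0 * fs))
    if len(masker.samples) < need:
        raise ValueError(
            f"masker ({len(masker.samples)} samples) shorter than "
            f"target + 1 s ({need} samples)")
    start = int(rng.integers(0, len(masker.samples) - need + 1))
    excerpt = masker.samples[start:start + need].copy()
    excerpt *= _raised_cosine_gate(len(excerpt), fs, ramp)
    if reverb_application in ("noise_only", "both"):
        excerpt = _convolve_trim(excerpt, rirs["masker"])

    # calibrate: target to target_level, masker to target_level - snr,
    # with the masker level measured over the target's duration
    tgt_rms = np.sqrt(np.mean(tgt**2))
    if tgt_rms <= 0:
        raise ValueError("silent target")
    tgt = tgt * (10.0 ** ((target_level - SPL_REF_DB) / 20.0) / tgt_rms)
    i0 = int(round(onset_lead * fs))
    seg = excerpt[i0:i0 + len(tgt)]
    seg_rms = np.sqrt(np.mean(seg**2))
    if seg_rms <= 0:
        raise ValueError("silent masker excerpt")
    excerpt = excerpt * (
        10.0 ** ((target_level - snr - SPL_REF_DB) / 20.0) / seg_rms)

    return TrialStimulus(
        target=Signal(samples=tgt, sample_rate=fs, label="target"),
        masker=Signal(samples=excerpt, sample_rate=fs,
                      label=masker.label or "masker_stat"),
        snr=snr,
        reverb_application=reverb_application,
        rt_label=rt_label,
        onset_lead=onset_lead,
        target_level=target_level,
    )


# ---------------------------------------------------------------------------
# synthetic speech stand-in (the real matrix corpus audio is copyrighted)

def _speech_shaping_fir(fs: float, n_taps: int = 255) -> np.ndarray:
    """FIR approximating a long-term speech spectrum: flat to 500 Hz,
    then -6 dB/octave."""
    freqs = np.array([0.0, 100.0, 500.0, 1000.0, 2000.0, 4000.0,
                      min(8000.0, 0.499 * fs), fs / 2.0])
    gains_db = np.array([-6.0, 0.0, 0.0, -6.0, -12.0, -18.0, -24.0, -30.0])
    return sps.firwin2(n_taps, freqs, 10 ** (gains_db / 20), fs=fs)


def synthetic_sentence(
    rng_seed: int,
    duration: float = 1.6,
    sample_rate: float = 16000.0,
    syllable_rate: float = 4.0,
) -> Signal:
    """A speech-like token: speech-shaped noise with a syllabic envelope.

    Bursts at roughly ``syllable_rate`` per second (3-5 Hz jitter)
    modulate a speech-spectrum noise carrier, giving the syllable-rate
    envelope fluctuations the modulation analyses rely on.
    """
    rng = np.random.default_rng(rng_seed)
    fs = sample_rate
    n = int(round(duration * fs))
    carrier = sps.fftconvolve(rng.standard_normal(n),
                              _speech_shaping_fir(fs), mode="same")
    env = np.zeros(n)
    t = 0.0
    while t < duration:
        rate = rng.uniform(0.75, 1.25) * syllable_rate
        syl_dur = min(rng.uniform(0.6, 0.9) / rate, duration - t)
        k = int(syl_dur * fs)
        i = int(t * fs)
        if k > 4:
            env[i:i + k] = np.hanning(k)[: len(env[i:i + k])] \
                * rng.uniform(0.5, 1.0)
        t += 1.0 / rate
    out = carrier * env
    rms = np.sqrt(np.mean(out**2))
    if rms > 0:
        out /= rms
    return Signal(samples=out, sample_rate=fs, label="target")


def synthetic_corpus(n_sentences: int, rng_seed: int = 0,
                     duration: float = 1.6,
                     sample_rate: float = 16000.0) -> list[Signal]:
    """A corpus of independent synthetic sentences."""
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_sentences)
    return [synthetic_sentence(int(s), duration, sample_rate)
            for s in seeds]
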