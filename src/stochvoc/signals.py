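"""Synthetic stimulus generation: chirps, tones, noises, a word-like token,
SNR mixing and rms equalization.

All generators return :class:`Waveform` objects whose samples are dimensionless
digital amplitudes. Signals destined for the stochastic vocoder must keep every
sample strictly inside (-1, +1); generators raise rather than clip when a
parameter combination would violate that.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

__all__ = [
    "Waveform",
    "make_chirp",
    "make_tone",
    "make_noise",
    "make_word_like",
    "mix_at_snr",
    "scale_noise_for_snr",
    "rms_equalize",
    "raised_cosine_envelope",
]

logger = logging.getLogger(__name__)

NOISE_KINDS = ("white", "pink", "speech_shaped")

#: amplitude slope (dB per octave) of the speech-shaped noise above its corner
_SPEECH_SHAPE_CORNER_HZ = 500.0
_SPEECH_SHAPE_DB_PER_OCT = -9.0


@dataclass(frozen=True)
class Waveform:
    """A finite mono signal: amplitude samples plus a sampling rate in Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size < 1:
            raise ValueError("waveform must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.samples)))

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def with_samples(self, samples: np.ndarray) -> "Waveform":
        return Waveform(samples, self.fs)


def raised_cosine_envelope(n_samples: int, ramp: float, fs: float) -> np.ndarray:
    """Unit-plateau envelope with half-cosine onset/offset ramps of ``ramp`` s."""
    n_ramp = int(round(ramp * fs))
    if 2 * n_ramp > n_samples:
        raise ValueError("ramps longer than the signal")
    env = np.ones(n_samples)
    if n_ramp > 0:
        # ramp sample k sits at time (k+1)/fs so the envelope reaches 1 at t=ramp
        t = np.arange(1, n_ramp + 1) / n_ramp
        half = 0.5 * (1.0 - np.cos(np.pi * t))
        env[:n_ramp] = half
        env[-n_ramp:] = half[::-1]
    return env


def _check_vocoder_range(samples: np.ndarray, what: str) -> None:
    peak = np.max(np.abs(samples))
    if peak >= 1.0:
        raise ValueError(
            f"{what}: peak amplitude {peak:.4g} is outside the open interval (-1, 1)"
        )


def make_chirp(
    f0: float,
    f1: float,
    duration: float,
    peak: float,
    ramp: float,
    fs: float,
) -> Waveform:
    """Exponential (constant log-Hz sweep rate) chirp with raised-cosine ramps.

    The instantaneous frequency at time ``t`` is ``f0 * (f1/f0)**(t/duration)``;
    ``f0 == f1`` degenerates to a ramped pure tone.
    """
    if not (0 < f0 <= f1):
        raise ValueError(f"need 0 < f0 <= f1, got f0={f0}, f1={f1}")
    if f1 >= fs / 2:
        raise ValueError(f"f1={f1} Hz must be below the Nyquist frequency {fs / 2} Hz")
    if not (0 < peak < 1):
        raise ValueError(f"peak must lie in (0, 1), got {peak}")
    if 2 * ramp > duration:
        raise ValueError("ramps longer than the chirp")

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if f0 == f1:
        x = np.sin(2 * np.pi * f0 * t)
    else:
        x = scipy.signal.chirp(t, f0=f0, t1=duration, f1=f1, method="logarithmic", phi=-90)
    x = peak * x * raised_cosine_envelope(n, ramp, fs)
    return Waveform(x, fs)


def make_tone(freq: float, duration: float, ramp: float, fs: float, rms: float) -> Waveform:
    """Ramped sinusoid scaled so its rms over the full duration equals ``rms``."""
    if freq >= fs / 2:
        raise ValueError(f"freq={freq} Hz must be below the Nyquist frequency {fs / 2} Hz")
    if 2 * ramp > duration:
        raise ValueError("ramps longer than the tone")
    if rms <= 0:
        raise ValueError("rms must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * freq * t) * raised_cosine_envelope(n, ramp, fs)
    x *= rms / np.sqrt(np.mean(x**2))
    _check_vocoder_range(x, "make_tone")
    return Waveform(x, fs)


def _shape_spectrum(white: np.ndarray, fs: float, kind: str) -> np.ndarray:
    """Impose a target magnitude spectrum on Gaussian white noise via the DFT."""
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(white.size, d=1.0 / fs)
    gain = np.ones_like(freqs)
    if kind == "pink":
        gain[1:] = 1.0 / np.sqrt(freqs[1:])  # power ~ 1/f
        gain[0] = 0.0
    elif kind == "speech_shaped":
        above = freqs > _SPEECH_SHAPE_CORNER_HZ
        # -9 dB/octave in power: power ~ f**(slope_db / (10*log10 2))
        power_exp = _SPEECH_SHAPE_DB_PER_OCT / (10.0 * math.log10(2.0))
        gain[above] = (freqs[above] / _SPEECH_SHAPE_CORNER_HZ) ** (power_exp / 2.0)
    return np.fft.irfft(spec * gain, n=white.size)


def make_noise(kind: str, duration: float, fs: float, rms: float, seed: int) -> Waveform:
    """Gaussian noise with a flat, 1/f ("pink") or speech-shaped spectrum.

    Deterministic for a fixed ``(kind, duration, fs, rms, seed)`` tuple.
    """
    if kind not in NOISE_KINDS:
        raise ValueError(f"unknown noise kind {kind!r}; expected one of {NOISE_KINDS}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = rng.standard_normal(n)
    if kind != "white":
        x = _shape_spectrum(x, fs, kind)
    x *= rms / np.sqrt(np.mean(x**2))
    _check_vocoder_range(x, f"make_noise(kind={kind!r}, rms={rms})")
    return Waveform(x, fs)


def make_word_like(
    duration: float,
    fs: float,
    f0: float = 120.0,
    seed: int = 0,
    *,
    formants: tuple[float, ...] = (500.0, 1500.0, 2500.0),
    am_rate: float = 4.0,
    peak: float = 0.5,
) -> Waveform:
    """Broadband word-like token: a harmonic complex with formant-like
    resonances and syllable-rate raised-cosine amplitude modulation.

    A deterministic stand-in for a spoken word; the phase of each harmonic is
    drawn from the seeded generator so different seeds give different tokens
    with the same spectral envelope.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    bandwidths = tuple(60.0 + 0.06 * f for f in formants)
    x = np.zeros(n)
    k = 1
    while k * f0 < 0.45 * fs:
        f = k * f0
        # one-pole-pair style resonance gains, plus a gentle overall tilt
        gain = sum(
            1.0 / (1.0 + ((f - fc) / bw) ** 2) for fc, bw in zip(formants, bandwidths)
        )
        gain *= (1.0 + f / 1000.0) ** -0.5
        phase = rng.uniform(0, 2 * np.pi)
        x += gain * np.sin(2 * np.pi * f * t + phase)
        k += 1

    am = 0.5 * (1.0 - np.cos(2 * np.pi * am_rate * t))
    x *= am
    x *= peak / np.max(np.abs(x))
    return Waveform(x, fs)


def _center_trim(noise: Waveform, n: int) -> Waveform:
    if len(noise) < n:
        raise ValueError("noise shorter than signal")
    start = (len(noise) - n) // 2
    return noise.with_samples(noise.samples[start : start + n])


def scale_noise_for_snr(signal: Waveform, noise: Waveform, snr_db: float) -> Waveform:
    """Trim the noise to the signal's length and scale it so that
    ``20*log10(rms(signal)/rms(noise))`` equals ``snr_db`` exactly."""
    if signal.fs != noise.fs:
        raise ValueError(f"sampling rates differ: {signal.fs} vs {noise.fs}")
    noise = _center_trim(noise, len(signal))
    factor = signal.rms() / (noise.rms() * 10.0 ** (snr_db / 20.0))
    return noise.with_samples(noise.samples * factor)


def mix_at_snr(
    signal: Waveform,
    noise: Waveform,
    snr_db: float,
    *,
    rescale: bool = False,
) -> Waveform:
    """Add noise to the signal at the requested SNR (rms-based, in dB).

    ``snr_db = inf`` returns the signal unchanged (the quiet condition). If the
    mixture peak reaches 1 the call fails, unless ``rescale`` is set, in which
    case the whole mixture is scaled to peak 0.99 (factor logged).
    """
    if math.isinf(snr_db) and snr_db > 0:
        return signal.with_samples(signal.samples.copy())
    scaled = scale_noise_for_snr(signal, noise, snr_db)
    mix = signal.samples + scaled.samples
    peak = np.max(np.abs(mix))
    if peak >= 1.0:
        if not rescale:
            raise ValueError(
                f"mixture peak {peak:.3f} >= 1; pass rescale=True to scale to 0.99"
            )
        factor = 0.99 / peak
        logger.warning("mixture peak %.3f >= 1; rescaled by %.4g", peak, factor)
        mix *= factor
    return signal.with_samples(mix)


def rms_equalize(wave: Waveform, target_rms: float) -> Waveform:
    """Scale a copy of the waveform so its rms equals ``target_rms``."""
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    rms = wave.rms()
    if rms == 0.0:
        raise ValueError("waveform has no energy to equalize")
    return wave.with_samples(wave.samples * (target_rms / rms))
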