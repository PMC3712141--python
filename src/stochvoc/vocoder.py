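"""Stochastic-undersampling vocoder.

The pipeline, per frequency band: causal Butterworth band-pass filtering, N
independent per-sample Bernoulli "spike" samplers whose firing probability
equals the rectified band amplitude, sample-wise OR aggregation of the N spike
trains, multiplication of the aggregated train with the band signal, re-filtering
through the same band filter, and summation across bands. Setting ``control=True``
bypasses the stochastic stage (all spikes present) while keeping the filterbank
coloration identical, which defines the reference condition for every
comparison. ``n_samplers=0`` yields an all-zero output (no functional samplers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .signals import Waveform, rms_equalize

__all__ = [
    "BandSpec",
    "FilterBank",
    "SpikeTrain",
    "VocoderConfig",
    "design_filterbank",
    "band_filter",
    "stochastic_spike_train",
    "aggregate_or",
    "spike_probability",
    "reconstruct_band",
    "vocode",
    "vocode_channels",
    "control_config",
]

logger = logging.getLogger(__name__)

# spawn-key tag for the single-stream (aggregated) sampling path; outside the
# 0..N-1 range of per-sampler streams so the two paths never share a stream
_AGGREGATE_STREAM_TAG = 0xFFFFFFFF


@dataclass(frozen=True)
class BandSpec:
    """One band-pass specification: edge frequencies and filter order.

    ``order`` is the order of the low-pass prototype; the band-pass
    transformation doubles the number of poles.
    """

    f_lo: float
    f_hi: float
    order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"need 0 < f_lo < f_hi, got {self.f_lo}, {self.f_hi}")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        """Second-order-section realization at sampling rate ``fs``."""
        if self.f_hi >= fs / 2:
            raise ValueError(f"f_hi={self.f_hi} >= Nyquist frequency {fs / 2}")
        return scipy.signal.butter(
            self.order, [self.f_lo, self.f_hi], btype="bandpass", output="sos", fs=fs
        )


@dataclass(frozen=True)
class FilterBank:
    """Ordered set of contiguous band-pass specs; neighbors share an edge."""

    bands: tuple[BandSpec, ...]
    fs: float

    def __post_init__(self) -> None:
        for a, b in zip(self.bands, self.bands[1:]):
            if a.f_hi != b.f_lo:
                raise ValueError("adjacent bands must share an edge frequency")

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.bands[0].f_lo] + [b.f_hi for b in self.bands])

    def sos(self) -> list[np.ndarray]:
        return [b.sos(self.fs) for b in self.bands]


@dataclass(frozen=True)
class SpikeTrain:
    """Binary (0/1) sequence aligned sample-for-sample with a band signal."""

    spikes: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        spikes = np.asarray(self.spikes)
        if spikes.ndim != 1:
            raise ValueError("spikes must be 1-D")
        if spikes.size and not np.isin(spikes, (0, 1)).all():
            raise ValueError("spike values must be 0 or 1")
        object.__setattr__(self, "spikes", spikes.astype(np.uint8))

    def __len__(self) -> int:
        return self.spikes.size

    def rate(self) -> float:
        """Fraction of samples carrying a spike."""
        return float(np.mean(self.spikes))


@dataclass(frozen=True)
class VocoderConfig:
    """All free parameters of the vocoder.

    ``order_convention`` selects how "order" is read: ``"prototype"`` (default)
    applies the order to the low-pass prototype (2*order poles per band-pass),
    ``"total"`` halves it so the band-pass filter itself has ``order`` poles.
    ``literal_or`` materializes all N spike trains and ORs them; the default
    draws the aggregated train in one pass from the equivalent per-sample
    probability 1-(1-|x|)**N (identical distribution, O(1) in N).
    """

    n_samplers: int
    n_bands: int = 10
    f_min: float = 100.0
    f_max: float = 10000.0
    order: int = 4
    order_convention: str = "prototype"
    seed: int = 0
    equalize_rms: bool = False
    control: bool = False
    literal_or: bool = False

    def __post_init__(self) -> None:
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if self.n_samplers < 0:
            raise ValueError("n_samplers must be >= 0")
        if self.order_convention not in ("prototype", "total"):
            raise ValueError("order_convention must be 'prototype' or 'total'")

    @property
    def n_total(self) -> int:
        """Total sampler budget across all bands."""
        return self.n_bands * self.n_samplers

    def effective_order(self) -> int:
        if self.order_convention == "total":
            if self.order % 2:
                raise ValueError("'total' order convention requires an even order")
            return self.order // 2
        return self.order


def design_filterbank(
    n_bands: int,
    f_min: float,
    f_max: float,
    order: int,
    fs: float,
) -> FilterBank:
    """Contiguous band-pass bank with logarithmically spaced edge frequencies.

    Edge k sits at ``f_min * (f_max/f_min)**(k/n_bands)`` for k = 0..n_bands.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    if f_max >= fs / 2:
        raise ValueError(f"f_max={f_max} >= Nyquist frequency {fs / 2}")
    edges = np.geomspace(f_min, f_max, n_bands + 1)
    bands = tuple(
        BandSpec(float(lo), float(hi), order) for lo, hi in zip(edges[:-1], edges[1:])
    )
    return FilterBank(bands, float(fs))


def band_filter(wave: Waveform, band: BandSpec) -> Waveform:
    """Causal forward band-pass filtering; preserves length."""
    return wave.with_samples(scipy.signal.sosfilt(band.sos(wave.fs), wave.samples))


def _check_sampling_range(x: np.ndarray) -> None:
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak >= 1.0:
        raise ValueError(
            f"band signal peak {peak:.4g} >= 1: per-sample firing probability "
            "must stay below 1 (amplitude invariant violated)"
        )


def stochastic_spike_train(band_signal: Waveform, rng: np.random.Generator) -> SpikeTrain:
    """One stochastic sampler: spike at t iff |x[t]| exceeds an independent
    Uniform(0,1) draw, so P(spike at t) = |x[t]| exactly."""
    x = band_signal.samples
    _check_sampling_range(x)
    u = rng.uniform(size=x.size)
    return SpikeTrain((np.abs(x) > u).astype(np.uint8), band_signal.fs)


def aggregate_or(trains: list[SpikeTrain]) -> SpikeTrain:
    """Sample-wise logical OR of spike trains: a spike survives aggregation
    if any constituent train fired at that sample."""
    if not trains:
        raise ValueError("cannot aggregate an empty list of spike trains")
    n = len(trains[0])
    if any(len(t) != n for t in trains):
        raise ValueError("all spike trains must have equal length")
    out = np.zeros(n, dtype=bool)
    for t in trains:
        np.logical_or(out, t.spikes, out=out)
    return SpikeTrain(out.astype(np.uint8), trains[0].fs)


def spike_probability(a, n_samplers: int):
    """Probability that at least one of ``n_samplers`` independent Bernoulli(a)
    samplers fires: ``1 - (1-a)**n_samplers``. Accepts scalars or arrays."""
    if n_samplers < 0:
        raise ValueError("n_samplers must be >= 0")
    arr = np.asarray(a, dtype=np.float64)
    if np.any((arr < 0) | (arr >= 1)):
        raise ValueError("amplitude must lie in [0, 1)")
    # -expm1(n*log1p(-a)) is 1-(1-a)**n, stable for a near 0 and large n
    out = -np.expm1(n_samplers * np.log1p(-arr))
    return out if isinstance(a, np.ndarray) else float(out)


def reconstruct_band(spikes: SpikeTrain, band_signal: Waveform) -> Waveform:
    """Restore sign and amplitude where spikes occurred: spikes[t] * x[t]."""
    if len(spikes) != len(band_signal):
        raise ValueError(
            f"length mismatch: {len(spikes)} spikes vs {len(band_signal)} samples"
        )
    return band_signal.with_samples(spikes.spikes * band_signal.samples)


def _band_rng(seed: int, band: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(band, tag)))


def _aggregated_train(
    band_signal: Waveform, band_index: int, config: VocoderConfig
) -> SpikeTrain:
    """Aggregated spike train for one band under the configured sampling path."""
    n = len(band_signal)
    if config.control:
        return SpikeTrain(np.ones(n, dtype=np.uint8), band_signal.fs)
    if config.n_samplers == 0:
        return SpikeTrain(np.zeros(n, dtype=np.uint8), band_signal.fs)
    if config.literal_or:
        trains = [
            stochastic_spike_train(band_signal, _band_rng(config.seed, band_index, j))
            for j in range(config.n_samplers)
        ]
        return aggregate_or(trains)
    _check_sampling_range(band_signal.samples)
    p = spike_probability(np.abs(band_signal.samples), config.n_samplers)
    u = _band_rng(config.seed, band_index, _AGGREGATE_STREAM_TAG).uniform(size=n)
    return SpikeTrain((u < p).astype(np.uint8), band_signal.fs)


def vocode_channels(
    wave: Waveform, config: VocoderConfig
) -> tuple[Waveform, list[Waveform]]:
    """Run the vocoder and return ``(output, per_band_outputs)``.

    Each per-band output has been through the full band pipeline including the
    back-end re-filtering; the first element is their sample-wise sum (after
    optional rms equalization applied to the sum only).
    """
    if wave.peak >= 1.0:
        raise ValueError("input peak must stay strictly below 1")
    bank = design_filterbank(
        config.n_bands, config.f_min, config.f_max, config.effective_order(), wave.fs
    )
    sos_list = bank.sos()
    band_out: list[Waveform] = []
    total = np.zeros(len(wave))
    for b, sos in enumerate(sos_list):
        y = scipy.signal.sosfilt(sos, wave.samples)
        band_signal = wave.with_samples(y)
        train = _aggregated_train(band_signal, b, config)
        recon = reconstruct_band(train, band_signal)
        z = scipy.signal.sosfilt(sos, recon.samples)
        band_out.append(wave.with_samples(z))
        total += z
    out = wave.with_samples(total)
    if config.equalize_rms:
        out = rms_equalize(out, wave.rms())
    return out, band_out


def vocode(wave: Waveform, config: VocoderConfig) -> Waveform:
    """Apply the full stochastic-undersampling vocoder to a waveform."""
    out, _ = vocode_channels(wave, config)
    return out


def control_config(config: VocoderConfig) -> VocoderConfig:
    """The matching control condition: same filterbank, sampling bypassed."""
    return replace(config, control=True)
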