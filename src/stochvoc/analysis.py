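"""Similarity analysis between control and stochastically vocoded stimuli.

Two statistics quantify how faithfully the stochastic sampling stage preserves
a waveform: frequency-resolved magnitude-squared coherence, and the maximum
lag-normalized temporal correlation R in [0, 1]. On top of these sit grid
sweeps: correlation maps over SNR x sampler count at fixed signal rms, and
band-count sweeps at a matched total sampler budget.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.signal

from .signals import Waveform, make_chirp, make_noise, make_word_like, mix_at_snr, rms_equalize
from .vocoder import VocoderConfig, control_config, vocode

__all__ = [
    "CoherenceResult",
    "CorrelationMap",
    "coherence",
    "temporal_correlation",
    "correlation_map",
    "filter_count_sweep",
    "reproduce_figure",
    "DEFAULT_SNR_GRID",
    "DEFAULT_N_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_SNR_GRID = tuple(float(s) for s in range(-20, 25, 5))
DEFAULT_N_GRID = (1, 3, 10, 30, 100, 300, 1000)

#: Welch estimator parameters: Hann window, 50% overlap
COHERENCE_NPERSEG = 1024

DEFAULT_MAX_LAG_S = 0.010


@dataclass(frozen=True)
class CoherenceResult:
    """Magnitude-squared coherence on a frequency grid; values in [0, 1]."""

    freqs: np.ndarray
    coherence: np.ndarray

    def band_mean(self, f_lo: float, f_hi: float) -> float:
        """Mean coherence over the frequency interval [f_lo, f_hi]."""
        mask = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if not mask.any():
            raise ValueError(f"no coherence estimates in [{f_lo}, {f_hi}] Hz")
        return float(np.mean(self.coherence[mask]))

    def band_median(self, f_lo: float, f_hi: float) -> float:
        mask = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if not mask.any():
            raise ValueError(f"no coherence estimates in [{f_lo}, {f_hi}] Hz")
        return float(np.median(self.coherence[mask]))


@dataclass(frozen=True)
class CorrelationMap:
    """Matrix of temporal-correlation values R over an SNR grid (rows) and a
    per-band sampler-count grid (columns), at one signal rms level."""

    snr_grid: tuple[float, ...]
    n_grid: tuple[int, ...]
    R: np.ndarray
    rms_level: float
    n_bands: int

    def __post_init__(self) -> None:
        if self.R.shape != (len(self.snr_grid), len(self.n_grid)):
            raise ValueError("R shape does not match the grids")

    @property
    def n_total_grid(self) -> tuple[int, ...]:
        return tuple(self.n_bands * n for n in self.n_grid)

    def to_csv(self, path: str | Path) -> None:
        """snr rows x N columns, with grid values as header row/column."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["snr_db\\N"] + list(self.n_grid))
            for snr, row in zip(self.snr_grid, self.R):
                writer.writerow([snr] + [f"{v:.6f}" for v in row])


def coherence(
    control: Waveform, vocoded: Waveform, nperseg: int = COHERENCE_NPERSEG
) -> CoherenceResult:
    """Welch magnitude-squared coherence between two equal-length waveforms."""
    if control.fs != vocoded.fs:
        raise ValueError("sampling rates differ")
    if len(control) != len(vocoded):
        raise ValueError("lengths differ")
    f, cxy = scipy.signal.coherence(
        control.samples,
        vocoded.samples,
        fs=control.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
    )
    cxy = np.clip(np.nan_to_num(cxy, nan=0.0), 0.0, 1.0)
    return CoherenceResult(f, cxy)


def temporal_correlation(
    control: Waveform,
    vocoded: Waveform,
    max_lag: float = DEFAULT_MAX_LAG_S,
) -> float:
    """Maximum normalized cross-correlation over lags |tau| <= max_lag,
    clamped to [0, 1].

    Normalization uses the full-signal energies, so the statistic is invariant
    to positive rescaling of either input and equals exactly 1 for identical
    signals at zero lag.
    """
    if control.fs != vocoded.fs:
        raise ValueError("sampling rates differ")
    if len(vocoded) < len(control):
        raise ValueError("vocoded input must be at least as long as the control")
    c = control.samples
    v = vocoded.samples
    norm = np.linalg.norm(c) * np.linalg.norm(v)
    if norm == 0.0:
        raise ValueError("zero-energy input")
    xc = scipy.signal.correlate(v, c, mode="full") / norm
    zero_lag = len(c) - 1  # index of lag 0 in the full correlation
    lag_span = int(round(max_lag * control.fs))
    lo = max(0, zero_lag - lag_span)
    hi = min(xc.size, zero_lag + lag_span + 1)
    r = float(np.max(xc[lo:hi]))
    return min(max(r, 0.0), 1.0)


def _cell_seed(master: int, *key: int) -> int:
    """Deterministic per-cell seed derived from the master seed and indices."""
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0])


def correlation_map(
    signal: Waveform,
    noise_kind: str,
    rms_level: float,
    snr_grid=DEFAULT_SNR_GRID,
    n_grid=DEFAULT_N_GRID,
    n_bands: int = 10,
    reps: int = 10,
    seed: int = 0,
    *,
    order: int = 4,
    f_min: float = 100.0,
    f_max: float = 10000.0,
) -> CorrelationMap:
    """Temporal-correlation map over (SNR, samplers per band) at one rms level.

    Each cell: scale the signal to ``rms_level``, add fresh noise at the cell
    SNR, vocode with N samplers per band, and correlate against the control
    rendering (sampling bypassed) of the clean signal; average over ``reps``
    repetitions with fresh noise and sampler seeds. A vocoded stimulus with no
    energy (e.g. N so small that no spike fired) scores R = 0.
    """
    snr_grid = tuple(float(s) for s in snr_grid)
    n_grid = tuple(int(n) for n in n_grid)
    if not snr_grid or not n_grid:
        raise ValueError("grids must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    scaled = rms_equalize(signal, rms_level)
    base = VocoderConfig(
        n_samplers=0, n_bands=n_bands, order=order, f_min=f_min, f_max=f_max
    )
    control = vocode(scaled, control_config(base))

    R = np.zeros((len(snr_grid), len(n_grid)))
    for i, snr in enumerate(snr_grid):
        for j, n in enumerate(n_grid):
            acc = 0.0
            for rep in range(reps):
                noise = make_noise(
                    noise_kind,
                    scaled.duration,
                    scaled.fs,
                    rms=rms_level,
                    seed=_cell_seed(seed, i, j, rep, 0),
                )
                mixture = mix_at_snr(scaled, noise, snr, rescale=True)
                cfg = VocoderConfig(
                    n_samplers=n,
                    n_bands=n_bands,
                    order=order,
                    f_min=f_min,
                    f_max=f_max,
                    seed=_cell_seed(seed, i, j, rep, 1),
                )
                vocoded = vocode(mixture, cfg)
                if not np.any(vocoded.samples):
                    continue  # dead output scores 0
                acc += temporal_correlation(control, vocoded)
            R[i, j] = acc / reps
    return CorrelationMap(snr_grid, n_grid, R, rms_level, n_bands)


def filter_count_sweep(
    signal: Waveform,
    noise_kind: str,
    rms_level: float,
    snr_grid,
    n_total_grid,
    band_counts,
    reps: int = 10,
    seed: int = 0,
) -> list[CorrelationMap]:
    """Correlation maps for several band counts at a matched total sampler
    budget: each cell uses N = n_total // n_bands samplers per band."""
    maps = []
    for bc in band_counts:
        n_grid = []
        for n_total in n_total_grid:
            if n_total % bc:
                logger.warning(
                    "n_total=%d not divisible by %d bands; rounding N down", n_total, bc
                )
            n_grid.append(max(int(n_total) // int(bc), 0))
        maps.append(
            correlation_map(
                signal,
                noise_kind,
                rms_level,
                snr_grid,
                n_grid,
                n_bands=int(bc),
                reps=reps,
                seed=_cell_seed(seed, int(bc)),
            )
        )
    return maps


# ---------------------------------------------------------------------------
# figure regeneration


def _chirp_demo(n_samplers: int, seed: int):
    """Chirp demo shared by the first two figures: quiet and 0 dB pink noise."""
    chirp = make_chirp(20.0, 12000.0, 1.0, 0.1, 0.02, 44100.0)
    noise = make_noise("pink", chirp.duration, chirp.fs, rms=chirp.rms(), seed=seed + 1)
    noisy = mix_at_snr(chirp, noise, 0.0)
    cfg = VocoderConfig(n_samplers=n_samplers, seed=seed)
    results = {}
    from .vocoder import vocode_channels

    for label, stim in (("quiet", chirp), ("noise", noisy)):
        ctrl, ctrl_bands = vocode_channels(stim, control_config(cfg))
        voc, voc_bands = vocode_channels(stim, cfg)
        coh = coherence(ctrl, voc)
        results[label] = {
            "control": ctrl,
            "vocoded": voc,
            "control_bands": ctrl_bands,
            "vocoded_bands": voc_bands,
            "coherence": coh,
        }
    return results


def _save_coherence_csv(path: Path, coh: CoherenceResult) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["freq_hz", "coherence"])
        for f, c in zip(coh.freqs, coh.coherence):
            w.writerow([f"{f:.2f}", f"{c:.6f}"])


def _plot_chirp_figure(results: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 2, figsize=(10, 10))
    for col, label in enumerate(("quiet", "noise")):
        res = results[label]
        ax = axes[0, col]
        n_bands = len(res["control_bands"])
        for b in range(n_bands):
            off = b * 0.25
            t = np.arange(len(res["control_bands"][b])) / res["control"].fs
            ax.plot(t, res["control_bands"][b].samples + off, "b", lw=0.3)
            ax.plot(t, res["vocoded_bands"][b].samples + off, "r", lw=0.3)
        ax.set_title(f"band outputs ({label})")
        ax.set_xlabel("time (s)")
        ax = axes[1, col]
        t = np.arange(len(res["control"])) / res["control"].fs
        ax.plot(t, res["control"].samples, "b", lw=0.3, label="control")
        ax.plot(t, res["vocoded"].samples, "r", lw=0.3, label="vocoded")
        ax.legend(loc="upper right")
        ax.set_xlabel("time (s)")
        ax = axes[2, col]
        coh = res["coherence"]
        ax.semilogx(coh.freqs[1:], coh.coherence[1:])
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("coherence")
        ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_maps(maps: list[CorrelationMap], titles: list[str], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(maps)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.5), squeeze=False)
    for ax, m, title in zip(axes[0], maps, titles):
        im = ax.imshow(
            m.R,
            origin="lower",
            aspect="auto",
            vmin=0,
            vmax=1,
            cmap="jet",
            extent=(-0.5, len(m.n_grid) - 0.5, -0.5, len(m.snr_grid) - 0.5),
        )
        ax.set_xticks(range(len(m.n_grid)), [str(v) for v in m.n_grid])
        ax.set_yticks(range(len(m.snr_grid)), [str(v) for v in m.snr_grid])
        ax.set_xlabel("samplers per band N")
        ax.set_ylabel("SNR (dB)")
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def reproduce_figure(
    which: str,
    seed: int = 0,
    out_dir: str | Path = "figures",
    *,
    fast: bool = False,
) -> dict:
    """Regenerate the computational content of one of the built-in figures.

    ``fig1``/``fig2``: chirp demo (N = 10 / 300) in quiet and 0 dB pink noise —
    waveform panels plus coherence curves. ``fig5``: correlation maps at four
    signal rms levels. ``fig6``: maps for 20/5/1 bands at matched total sampler
    budget. Writes a PNG and the underlying CSV tables; returns the numeric
    results. ``fast`` shrinks grids/reps for smoke testing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"figure": which, "seed": seed}

    if which in ("fig1", "fig2"):
        n_samplers = 10 if which == "fig1" else 300
        results = _chirp_demo(n_samplers, seed)
        _plot_chirp_figure(results, out_dir / f"{which}.png")
        for label in ("quiet", "noise"):
            _save_coherence_csv(
                out_dir / f"{which}_coherence_{label}.csv", results[label]["coherence"]
            )
        summary["results"] = results
        summary["median_coherence"] = {
            label: results[label]["coherence"].band_median(100.0, 10000.0)
            for label in ("quiet", "noise")
        }
    elif which == "fig5":
        word = make_word_like(0.5, 22050.0, seed=seed)
        reps = 2 if fast else 10
        snr_grid = (-20.0, -10.0, 0.0, 10.0, 20.0) if fast else DEFAULT_SNR_GRID
        n_grid = (10, 100, 1000) if fast else DEFAULT_N_GRID
        levels = (0.1, 0.01, 0.001, 0.0001)
        maps = [
            correlation_map(
                word, "white", lvl, snr_grid, n_grid, reps=reps, seed=seed + k
            )
            for k, lvl in enumerate(levels)
        ]
        for lvl, m in zip(levels, maps):
            m.to_csv(out_dir / f"fig5_rms{lvl}.csv")
        _plot_maps(maps, [f"rms = {lvl}" for lvl in levels], out_dir / "fig5.png")
        summary["maps"] = maps
    elif which == "fig6":
        word = make_word_like(0.5, 22050.0, seed=seed)
        reps = 2 if fast else 10
        snr_grid = (-20.0, -10.0, 0.0, 10.0, 20.0) if fast else DEFAULT_SNR_GRID
        n_total_grid = (20, 100, 1000) if fast else (20, 60, 100, 300, 1000, 3000, 10000)
        band_counts = (20, 5, 1)
        maps = filter_count_sweep(
            word, "white", 0.01, snr_grid, n_total_grid, band_counts, reps=reps, seed=seed
        )
        for bc, m in zip(band_counts, maps):
            m.to_csv(out_dir / f"fig6_{bc}bands.csv")
        _plot_maps(maps, [f"{bc} bands" for bc in band_counts], out_dir / "fig6.png")
        summary["maps"] = maps
    else:
        raise ValueError(f"unknown figure id {which!r}")
    return summary
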