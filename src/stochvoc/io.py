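"""Audio file I/O and run manifests.

WAV support covers mono 16/24-bit PCM and 32-bit float, any sampling rate.
Samples are exchanged with :class:`~stochvoc.signals.Waveform` as dimensionless
amplitudes in (-1, 1]; integer containers are normalized by their full scale.
"""

from __future__ import annotations

import hashlib
import json
import logging
import wave as wave_module
from pathlib import Path

import numpy as np
import scipy.io.wavfile

from .signals import Waveform

__all__ = ["read_wav", "write_wav", "run_manifest", "load_manifest"]

logger = logging.getLogger(__name__)

MANIFEST_VERSION = 1

_INT_SCALES = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
}


def read_wav(path: str | Path) -> Waveform:
    """Read a WAV file as a mono waveform normalized to dimensionless amplitude.

    Multi-channel files are reduced to their first channel (with a warning).
    24-bit PCM arrives from the decoder as int32 and is normalized accordingly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fs, data = scipy.io.wavfile.read(path)
    if data.ndim == 2:
        logger.warning("%s has %d channels; using the first", path, data.shape[1])
        data = data[:, 0]
    if data.dtype in _INT_SCALES:
        samples = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    return Waveform(samples, float(fs))


def _write_pcm24(wave: Waveform, path: Path) -> None:
    scaled = np.clip(np.round(wave.samples * (2.0**23 - 1)), -(2.0**23), 2.0**23 - 1)
    as32 = scaled.astype("<i4")
    raw = as32.view(np.uint8).reshape(-1, 4)[:, :3].tobytes()  # drop the high byte
    with wave_module.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(3)
        fh.setframerate(int(round(wave.fs)))
        fh.writeframes(raw)


def write_wav(wave: Waveform, path: str | Path, bits: int = 32) -> None:
    """Write a waveform to a mono WAV file.

    ``bits``: 16 or 24 for PCM (samples must satisfy |x| <= 1, else error —
    never silent clipping), 32 for IEEE float (lossless round-trip).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if bits in (16, 24) and np.max(np.abs(wave.samples)) > 1.0:
        raise ValueError(
            f"samples exceed full scale (peak {wave.peak:.4g}); "
            "integer formats would clip"
        )
    if bits == 16:
        scipy.io.wavfile.write(
            path,
            int(round(wave.fs)),
            np.clip(np.round(wave.samples * 32767), -32768, 32767).astype(np.int16),
        )
    elif bits == 24:
        _write_pcm24(wave, path)
    elif bits == 32:
        scipy.io.wavfile.write(path, int(round(wave.fs)), wave.samples.astype(np.float32))
    else:
        raise ValueError(f"bits must be 16, 24 or 32, got {bits}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_manifest(
    config: dict,
    outputs: list[str | Path],
    path: str | Path,
) -> dict:
    """Write a JSON manifest recording all run parameters plus sha256 hashes
    of the produced output files, sufficient for bit-exact replay."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "manifest_version": MANIFEST_VERSION,
        "config": config,
        "outputs": {
            str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_manifest(path: str | Path) -> dict:
    """Load and validate a run manifest."""
    with open(path) as fh:
        manifest = json.load(fh)
    for key in ("manifest_version", "config", "outputs"):
        if key not in manifest:
            raise ValueError(f"manifest missing required key {key!r}")
    return manifest
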