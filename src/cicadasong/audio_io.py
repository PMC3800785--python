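"""Mono 16-bit PCM WAV input/output and full-scale (dBFS) amplitude arithmetic.

Everything downstream works on :class:`Waveform` objects: floating-point
samples normalized to the 16-bit full-scale range [-1, +1] plus a sample rate.
0 dBFS is defined by sample value (|x| = 1), so half of the maximum sample
value is -6.02 dBFS.
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Scale factor between 16-bit integer codes and float samples.  Dividing by
#: 32768 maps the most negative code (-32768) to -1.0 exactly and keeps
#: |sample| <= 1 for every code.
INT16_FULL_SCALE = 32768.0

#: The sample rate all analysis defaults are expressed at.
REFERENCE_RATE = 44100


class AudioFileError(Exception):
    """Base class for WAV reading/writing problems."""


class MissingFileError(AudioFileError):
    """The requested audio file does not exist."""


class UnsupportedFormatError(AudioFileError):
    """The file is not PCM WAV (or is corrupt/truncated)."""


class EmptyAudioError(AudioFileError):
    """The file decodes to zero samples."""


@dataclass
class Waveform:
    """Uniformly sampled audio in full-scale float units.

    Parameters
    ----------
    samples
        1-D float array, all values finite with ``|x| <= 1``.
    sample_rate
        Sampling frequency in Hz (positive integer).
    source_bit_depth
        Bit depth of the source material; informational only.
    """

    samples: np.ndarray
    sample_rate: int
    source_bit_depth: int = 16

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform contains non-finite samples")
        if np.max(np.abs(self.samples), initial=0.0) > 1.0 + 1e-12:
            raise ValueError("Waveform samples exceed full scale (|x| > 1)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Length of the waveform in seconds."""
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(len(self.samples)) / self.sample_rate


def read_wav(path: str | Path) -> Waveform:
    """Read a PCM WAV file into a mono, full-scale-normalized :class:`Waveform`.

    Multi-channel input is averaged down to mono.  Integer samples are scaled
    by 1/32768 (16-bit) so that the most negative code maps to -1 exactly.

    Raises
    ------
    MissingFileError
        If ``path`` does not exist.
    UnsupportedFormatError
        If the file is not integer PCM WAV or is corrupt.
    EmptyAudioError
        If the file contains no frames.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"audio file not found: {path}")
    try:
        with wave.open(str(path), "rb") as wf:
            sampwidth = wf.getsampwidth()
            n_channels = wf.getnchannels()
            sample_rate = wf.getframerate()
            n_frames = wf.getnframes()
            if wf.getcomptype() != "NONE":
                raise UnsupportedFormatError(
                    f"{path}: compressed WAV ({wf.getcomptype()}) is not supported"
                )
            raw = wf.readframes(n_frames)
    except wave.Error as exc:
        raise UnsupportedFormatError(f"{path}: not a readable PCM WAV file ({exc})") from exc
    if sampwidth != 2:
        raise UnsupportedFormatError(
            f"{path}: only 16-bit PCM is supported, got {8 * sampwidth}-bit"
        )
    data = np.frombuffer(raw, dtype="<i2").astype(np.float64) / INT16_FULL_SCALE
    if n_channels > 1:
        data = data[: (len(data) // n_channels) * n_channels]
        data = data.reshape(-1, n_channels).mean(axis=1)
    if len(data) == 0:
        raise EmptyAudioError(f"{path}: file contains no audio samples")
    if sample_rate != REFERENCE_RATE:
        logger.warning(
            "%s: sample rate %d Hz differs from the reference 44100 Hz; "
            "sample-count-based analysis parameters keep their nominal sizes",
            path,
            sample_rate,
        )
    return Waveform(samples=data, sample_rate=sample_rate, source_bit_depth=8 * sampwidth)


def write_wav(wf: Waveform, path: str | Path) -> None:
    """Write a :class:`Waveform` to disk as mono 16-bit PCM WAV.

    Samples are rounded to the nearest 16-bit code; a read-back round-trips
    within one quantization step (2**-15).
    """
    codes = np.clip(np.round(wf.samples * INT16_FULL_SCALE), -32768, 32767).astype("<i2")
    path = Path(path)
    try:
        with wave.open(str(path), "wb") as out:
            out.setnchannels(1)
            out.setsampwidth(2)
            out.setframerate(wf.sample_rate)
            out.writeframes(codes.tobytes())
    except OSError as exc:
        raise AudioFileError(f"cannot write WAV to {path}: {exc}") from exc


def amplitude_to_dbfs(a: float | np.ndarray, *, allow_zero: bool = False) -> float | np.ndarray:
    """Convert linear amplitude (full scale = 1) to dBFS: ``20*log10(a)``.

    ``amplitude_to_dbfs(1.0) == 0.0`` and ``amplitude_to_dbfs(0.5) == -6.02``
    (to two decimals).  Non-positive amplitudes raise a ``ValueError`` unless
    ``allow_zero`` is set, in which case they map to ``-inf``.
    """
    arr = np.asarray(a, dtype=np.float64)
    if np.any(arr < 0) or (not allow_zero and np.any(arr == 0)):
        raise ValueError("amplitude must be > 0 for a dBFS level")
    with np.errstate(divide="ignore"):
        out = 20.0 * np.log10(arr)
    return float(out) if np.isscalar(a) or arr.ndim == 0 else out


def dbfs_to_amplitude(db: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`amplitude_to_dbfs`."""
    out = 10.0 ** (np.asarray(db, dtype=np.float64) / 20.0)
    return float(out) if np.isscalar(db) or out.ndim == 0 else out


def normalize_peak(wf: Waveform) -> Waveform:
    """Rescale so that the maximum absolute sample sits at 0 dBFS (|x| = 1).

    Relative sample ratios are preserved exactly; an already-normalized
    waveform is returned with identical samples.  All-zero input has no
    reference amplitude and raises ``ValueError``.
    """
    peak = float(np.max(np.abs(wf.samples), initial=0.0))
    if peak == 0.0:
        raise ValueError("cannot peak-normalize an all-zero waveform")
    if peak == 1.0:
        return Waveform(wf.samples, wf.sample_rate, wf.source_bit_depth)
    return Waveform(wf.samples / peak, wf.sample_rate, wf.source_bit_depth)
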