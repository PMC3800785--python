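"""Spectrogram and oscillogram rendering for visual inspection of calls."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import signal

from cicadasong.audio_io import Waveform
from cicadasong.config import AnalysisConfig


def plot_spectrogram(
    wf: Waveform,
    config: AnalysisConfig | None = None,
    ax=None,
    fmax: float | None = 12000.0,
):
    """Spectrogram with a 256-sample Hamming-window FFT (50% overlap)."""
    config = config or AnalysisConfig()
    n = config.spectrogram_fft_size
    f, t, sxx = signal.spectrogram(
        wf.samples,
        fs=wf.sample_rate,
        window="hamming",
        nperseg=n,
        noverlap=n // 2,
        detrend=False,
    )
    db = 10.0 * np.log10(np.maximum(sxx, sxx.max() * 1e-12) / sxx.max())
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    mask = f <= (fmax or f[-1])
    ax.pcolormesh(t, f[mask], db[mask], shading="auto", vmin=-80, vmax=0, cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    return ax


def plot_call(wf: Waveform, config: AnalysisConfig | None = None, path: str | Path | None = None):
    """Stacked spectrogram + oscillogram of a call; optionally saved as PNG."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    plot_spectrogram(wf, config, ax=ax1)
    ax2.plot(wf.times, wf.samples, lw=0.2, color="k")
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("amplitude (full scale)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
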