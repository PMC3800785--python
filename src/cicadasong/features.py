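"""Core acoustic measurements of a calling song.

Peak frequency from an averaged 512-sample Hamming-window power spectral
density; amplitude envelope by full-wave rectification and zero-phase low-pass
filtering; amplitude-burst detection with a hysteresis gate; burst rate from
detected onsets; pulses per burst via the normalized 12-burst / -6.02 dBFS
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from cicadasong.audio_io import Waveform, amplitude_to_dbfs
from cicadasong.config import AnalysisConfig

DEFAULT_CONFIG = AnalysisConfig()


class FeatureError(Exception):
    """A measurement stage could not run on the given input."""


@dataclass
class PowerSpectrum:
    """Averaged periodogram on the FFT bin grid, in dB relative to its maximum."""

    bin_frequencies: np.ndarray
    power_db: np.ndarray

    @property
    def bin_spacing(self) -> float:
        return float(self.bin_frequencies[1] - self.bin_frequencies[0])


@dataclass
class Envelope:
    """Non-negative amplitude envelope sampled at the waveform rate."""

    times: np.ndarray
    level: np.ndarray
    sample_rate: int

    @property
    def duration(self) -> float:
        return len(self.level) / self.sample_rate


@dataclass
class Burst:
    """One detected amplitude burst: a gate-open interval of the envelope."""

    onset: float
    offset: float
    peak_level_dbfs: float
    pulse_count: int | None = None

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("burst onset must precede offset")


@dataclass
class CallFeatures:
    """The four headline acoustic measurements of one call."""

    peak_frequency: float
    burst_rate: float
    mean_pulses_per_burst: float
    phrase_durations: tuple[float, float, float]
    pulse_counts: list[int] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "peak_frequency_hz": self.peak_frequency,
            "burst_rate_hz": self.burst_rate,
            "mean_pulses_per_burst": self.mean_pulses_per_burst,
            "phrase1_s": round(self.phrase_durations[0], 3),
            "phrase2_s": round(self.phrase_durations[1], 3),
            "phrase3_s": round(self.phrase_durations[2], 3),
            **self.provenance,
        }


# ---------------------------------------------------------------------------
# spectral features
# ---------------------------------------------------------------------------


def power_spectrum(wf: Waveform, config: AnalysisConfig = DEFAULT_CONFIG) -> PowerSpectrum:
    """Welch-averaged power spectral density, 512-sample Hamming segments.

    Segments overlap by 50%.  The result is expressed in dB relative to its
    maximum (so the strongest bin sits at 0 dB).  Requires at least one full
    FFT segment of input.
    """
    n = config.fft_size
    if len(wf.samples) < n:
        raise FeatureError(
            f"waveform has {len(wf.samples)} samples; need at least {n} for the PSD"
        )
    freqs, psd = signal.welch(
        wf.samples,
        fs=wf.sample_rate,
        window="hamming",
        nperseg=n,
        noverlap=n // 2,
        detrend=False,
        scaling="density",
    )
    peak = psd.max()
    if peak <= 0:
        raise FeatureError("input has no spectral power (silent waveform)")
    floor = peak * 1e-20
    power_db = 10.0 * np.log10(np.maximum(psd, floor) / peak)
    return PowerSpectrum(bin_frequencies=freqs, power_db=power_db)


def peak_frequency(ps: PowerSpectrum) -> float:
    """Peak frequency of a PSD, averaging near-tied peaks.

    Candidate peaks are local maxima of the spectrum (including the edge bins
    when they dominate their neighbor).  If two or more candidates lie within
    0.5 dB of the global maximum, the arithmetic mean of their bin frequencies
    is returned; otherwise the global maximum's bin frequency.
    """
    p = ps.power_db
    if len(p) == 0:
        raise FeatureError("empty power spectrum")
    if len(p) == 1:
        return float(ps.bin_frequencies[0])
    cand, _ = signal.find_peaks(p)
    cand = set(cand.tolist())
    if p[0] > p[1]:
        cand.add(0)
    if p[-1] > p[-2]:
        cand.add(len(p) - 1)
    cand.add(int(np.argmax(p)))
    cand = np.asarray(sorted(cand))
    top = p[cand].max()
    near = cand[top - p[cand] < 0.5]
    if len(near) >= 2:
        return float(np.mean(ps.bin_frequencies[near]))
    return float(ps.bin_frequencies[near[0]])


# ---------------------------------------------------------------------------
# envelope and burst detection
# ---------------------------------------------------------------------------


def estimate_envelope(
    wf: Waveform,
    cutoff_hz: float | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Envelope:
    """Amplitude envelope: full-wave rectify, then zero-phase low-pass.

    The Butterworth low-pass (order ``config.env_filter_order``, run forward
    and backward so burst timing is not skewed) is followed by a pi/2 gain
    correction so a constant-amplitude sinusoid reads its peak amplitude
    rather than its mean absolute value.  Default cutoff is the burst-band
    value from the config; pass ``config.pulse_env_cutoff_hz`` to resolve
    individual pulses.
    """
    if len(wf.samples) == 0:
        raise FeatureError("cannot estimate the envelope of an empty waveform")
    cutoff = cutoff_hz if cutoff_hz is not None else config.burst_env_cutoff_hz
    nyq = wf.sample_rate / 2.0
    if cutoff >= nyq:
        raise FeatureError(f"envelope cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    rect = np.abs(wf.samples)
    sos = signal.butter(config.env_filter_order, cutoff, fs=wf.sample_rate, output="sos")
    # Even-type edge padding: the rectified signal is non-negative, and an odd
    # extension would inject a sign discontinuity whose transient can poke
    # above the noise gate at the array edges.
    padlen = min(len(rect) - 1, int(3 * wf.sample_rate / cutoff))
    level = signal.sosfiltfilt(sos, rect, padlen=padlen, padtype="even") * (np.pi / 2.0)
    level = np.clip(level, 0.0, None)
    return Envelope(times=wf.times, level=level, sample_rate=wf.sample_rate)


def _hysteresis_state(level: np.ndarray, open_thr: float, close_thr: float) -> np.ndarray:
    """Gate state per sample: 1 above the open threshold until the close
    threshold is crossed downward (classic Schmitt trigger), else 0."""
    s = np.full(len(level), np.nan)
    s[level > open_thr] = 1.0
    s[level < close_thr] = 0.0
    valid = ~np.isnan(s)
    idx = np.where(valid, np.arange(len(s)), -1)
    np.maximum.accumulate(idx, out=idx)
    state = np.where(idx >= 0, s[np.maximum(idx, 0)], 0.0)
    return state.astype(np.int8)


def detect_bursts(
    env: Envelope,
    config: AnalysisConfig = DEFAULT_CONFIG,
    waveform: Waveform | None = None,
) -> list[Burst]:
    """Detect amplitude bursts with a hysteresis gate on the envelope.

    The gate opens when the envelope rises above ``gate_open_frac`` and closes
    when it falls below ``gate_close_frac``, both relative to the envelope's
    ``gate_ref_percentile`` level (a robust stand-in for the burst peak).  One
    :class:`Burst` is emitted per gate-open interval.

    When ``waveform`` is supplied, each burst's peak level (dBFS) is the
    maximum absolute *sample* value inside the interval — the quantity the
    -3 dBFS phrase criteria are defined on; otherwise the (smoothed, hence
    attenuated) envelope peak is used.
    """
    level = env.level
    if len(level) == 0 or level.max() <= 0:
        return []
    ref = float(np.percentile(level, config.gate_ref_percentile))
    if ref <= 0:
        return []
    open_thr = config.gate_open_frac * ref
    close_thr = config.gate_close_frac * ref
    state = _hysteresis_state(level, open_thr, close_thr)
    edges = np.diff(state, prepend=0, append=0)
    starts = np.where(edges == 1)[0]
    stops = np.where(edges == -1)[0]  # exclusive
    fs = env.sample_rate
    bursts: list[Burst] = []
    for i0, i1 in zip(starts, stops):
        if i1 <= i0 + 1:
            continue
        if waveform is not None:
            peak = float(np.max(np.abs(waveform.samples[i0:i1])))
        else:
            peak = float(np.max(level[i0:i1]))
        peak_db = amplitude_to_dbfs(max(peak, 1e-12))
        bursts.append(Burst(onset=i0 / fs, offset=(i1 - 1) / fs, peak_level_dbfs=peak_db))
    return bursts


def burst_rate(bursts: list[Burst], window: tuple[float, float] | None = None) -> float:
    """Amplitude-burst rate: (onset count - 1) / (last onset - first onset).

    ``window`` restricts the computation to onsets inside ``[t_lo, t_hi)`` —
    the caller passes the phrase-2 interval when boundaries are known.
    """
    onsets = np.asarray([b.onset for b in bursts])
    if window is not None:
        lo, hi = window
        onsets = onsets[(onsets >= lo) & (onsets < hi)]
    if len(onsets) < 2:
        raise FeatureError(
            f"burst rate needs at least 2 burst onsets in the window, got {len(onsets)}"
        )
    onsets = np.sort(onsets)
    return float((len(onsets) - 1) / (onsets[-1] - onsets[0]))


# ---------------------------------------------------------------------------
# pulses per burst
# ---------------------------------------------------------------------------


def _middle_indices(n: int, k: int) -> tuple[int, int]:
    """Start/stop (half-open) of the k bursts centered on ceil(n/2), ties toward the start."""
    center = (n + 1) // 2 - 1  # 0-based index of the ceil(n/2)-th burst
    start = center - k // 2
    start = max(0, min(start, n - k))
    return start, start + k


def _merge_rippled_peaks(
    level: np.ndarray, peaks: np.ndarray, trough_frac: float
) -> np.ndarray:
    """Collapse runs of envelope maxima not separated by a real dip.

    Two adjacent maxima belong to the same pulse when the envelope between
    them never falls below ``trough_frac`` of the lower maximum (flat-top
    ripple); each run is represented by its tallest maximum.
    """
    if len(peaks) < 2:
        return peaks
    kept = [int(peaks[0])]
    for p in peaks[1:]:
        p = int(p)
        prev = kept[-1]
        trough = float(level[prev : p + 1].min())
        if trough > trough_frac * min(level[prev], level[p]):
            if level[p] > level[prev]:
                kept[-1] = p
        else:
            kept.append(p)
    return np.asarray(kept)


def pulses_per_burst(
    wf: Waveform,
    bursts: list[Burst],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[list[int], float]:
    """Count sound pulses per amplitude burst over the middle of the call.

    The ``n_middle_bursts`` (12) bursts centered on the midpoint of the burst
    sequence are selected; the audio span they cover is normalized to 0 dBFS;
    pulses are local maxima of a wide-band envelope separated by at least
    ``pulse_min_separation_s``; within each burst, the count runs from the
    first to the last pulse whose peak absolute sample exceeds
    ``pulse_amp_frac`` (50%, i.e. -6.02 dBFS) of the span maximum.

    Returns the per-burst counts and their mean.
    """
    k = config.n_middle_bursts
    if len(bursts) < k:
        raise FeatureError(
            f"pulse counting needs at least {k} detected bursts, got {len(bursts)} "
            f"(short by {k - len(bursts)})"
        )
    lo, hi = _middle_indices(len(bursts), k)
    sel = bursts[lo:hi]
    fs = wf.sample_rate

    # Pulse-collection window per burst: midpoints to the neighboring bursts,
    # so gate-timing lag cannot clip a burst's first or last pulse.  The 50%
    # amplitude criterion is what actually excludes inter-burst fill pulses.
    def mid(a: float, b: float) -> float:
        return 0.5 * (a + b)

    win_lo = [
        mid(bursts[lo + i - 1].offset, b.onset) if lo + i > 0 else max(0.0, 2 * b.onset - b.offset)
        for i, b in enumerate(sel)
    ]
    win_hi = [
        mid(b.offset, bursts[lo + i + 1].onset)
        if lo + i + 1 < len(bursts)
        else min(wf.duration, 2 * b.offset - b.onset)
        for i, b in enumerate(sel)
    ]

    i0 = max(0, int(win_lo[0] * fs))
    i1 = min(len(wf.samples), int(np.ceil(win_hi[-1] * fs)) + 1)
    span = wf.samples[i0:i1]
    span_max = float(np.max(np.abs(span)))
    if span_max <= 0:
        raise FeatureError("selected burst span is silent")
    span = span / span_max  # normalize the selected audio to 0 dBFS

    wide = estimate_envelope(
        Waveform(span, fs), cutoff_hz=config.pulse_env_cutoff_hz, config=config
    )
    dist = max(1, int(round(config.pulse_min_separation_s * fs)))
    env_max = float(wide.level.max())
    peaks, _ = signal.find_peaks(
        wide.level, distance=dist, height=0.1 * env_max, prominence=0.02 * env_max
    )
    peaks = _merge_rippled_peaks(wide.level, peaks, config.pulse_merge_trough_frac)
    if len(peaks) == 0:
        raise FeatureError("no pulses found in the selected burst span")
    spacing = int(np.median(np.diff(peaks))) if len(peaks) > 1 else dist
    half = max(1, spacing // 4)
    peak_amp = np.array(
        [np.max(np.abs(span[max(0, p - half) : p + half + 1])) for p in peaks]
    )
    peak_t = (peaks + i0) / fs

    counts: list[int] = []
    for b, w0, w1 in zip(sel, win_lo, win_hi):
        in_win = (peak_t >= w0) & (peak_t < w1)
        exceeds = in_win & (peak_amp > config.pulse_amp_frac)
        idx = np.where(exceeds)[0]
        if len(idx) == 0:
            counts.append(0)
            continue
        first, last = idx[0], idx[-1]
        within = np.where(in_win)[0]
        counts.append(int(np.sum((within >= first) & (within <= last))))
        b.pulse_count = counts[-1]
    return counts, float(np.mean(counts))
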