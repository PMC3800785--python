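"""Objective three-phrase segmentation of a calling song.

Both species' calls divide into a crescendo (phrase 1), a main phrase
(phrase 2), and a terminal phrase (phrase 3).  After whole-call peak
normalization:

* phrase 1 -> 2: onset of the first amplitude burst whose peak reaches
  -3 dBFS;
* phrase 2 -> 3, chiricahua rule: offset of the last burst whose peak reaches
  -3 dBFS;
* phrase 2 -> 3, neomexicensis rule: end of the modulated portion of the
  call — a sliding-window modulation index localizes where amplitude
  modulation is present, and the boundary snaps to the offset of the last
  detected burst inside that region;
* call start / termination: first and last crossing of the burst-band
  envelope above the assumed noise floor plus a safety margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cicadasong.audio_io import Waveform, dbfs_to_amplitude
from cicadasong.config import AnalysisConfig
from cicadasong.features import Burst, Envelope, estimate_envelope

DEFAULT_CONFIG = AnalysisConfig()


class SegmentationError(Exception):
    """The phrase criteria could not be applied to this call."""


@dataclass
class PhraseBoundaries:
    """Call start, the two phrase boundaries, and call termination (seconds)."""

    t0: float
    t12: float
    t23: float
    t_end: float
    rule_set: str

    def __post_init__(self) -> None:
        if not (self.t0 < self.t12 < self.t23 < self.t_end):
            raise SegmentationError(
                "phrase boundaries must be strictly increasing: "
                f"t0={self.t0:.3f}, t12={self.t12:.3f}, t23={self.t23:.3f}, "
                f"t_end={self.t_end:.3f}"
            )

    @property
    def durations(self) -> tuple[float, float, float]:
        return (self.t12 - self.t0, self.t23 - self.t12, self.t_end - self.t23)


def _call_extent(env: Envelope, config: AnalysisConfig) -> tuple[float, float]:
    """First/last time the envelope exceeds (noise floor + margin)."""
    thr = dbfs_to_amplitude(config.noise_floor_dbfs + config.call_edge_margin_db)
    above = np.where(env.level > thr)[0]
    if len(above) == 0:
        raise SegmentationError(
            f"envelope never exceeds the noise gate ({config.noise_floor_dbfs:+.0f} dBFS "
            f"+ {config.call_edge_margin_db:.0f} dB)"
        )
    return float(above[0] / env.sample_rate), float(above[-1] / env.sample_rate)


def modulation_index(
    env: Envelope, window_s: float, step_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding (peak - trough)/(peak + trough) of the envelope.

    Returns window-center times and the index per window.  The index is near
    1 where the envelope is strongly amplitude-modulated (deep inter-burst
    troughs) and near 0 over an unmodulated pulse train.
    """
    n = len(env.level)
    w = max(2, int(round(window_s * env.sample_rate)))
    step = max(1, int(round(step_s * env.sample_rate)))
    centers, idx = [], []
    for start in range(0, max(1, n - w + 1), step):
        seg = env.level[start : start + w]
        hi, lo = float(seg.max()), float(seg.min())
        if hi + lo <= 0:
            val = 0.0
        else:
            val = (hi - lo) / (hi + lo)
        centers.append((start + w / 2) / env.sample_rate)
        idx.append(val)
    return np.asarray(centers), np.asarray(idx)


def segment_call(
    wf: Waveform,
    bursts: list[Burst],
    rule_set: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
    envelope: Envelope | None = None,
) -> PhraseBoundaries:
    """Apply the three-phrase criteria to a peak-normalized call.

    ``bursts`` must carry sample-referenced peak levels (i.e. come from
    ``detect_bursts`` with the waveform supplied) on a waveform whose maximum
    absolute sample is 1.
    """
    if rule_set not in ("chiricahua", "neomexicensis"):
        raise ValueError(f"unknown rule set: {rule_set!r}")
    peak = float(np.max(np.abs(wf.samples), initial=0.0))
    if abs(peak - 1.0) > 1e-6:
        raise SegmentationError("waveform must be peak-normalized to 0 dBFS first")
    if envelope is None:
        envelope = estimate_envelope(wf, config=config)

    t0, t_end = _call_extent(envelope, config)

    loud = [b for b in bursts if b.peak_level_dbfs >= config.phrase_threshold_dbfs - 1e-9]
    if not loud:
        raise SegmentationError(
            f"no amplitude burst reaches {config.phrase_threshold_dbfs:g} dBFS"
        )
    t12 = loud[0].onset

    if rule_set == "chiricahua":
        t23 = loud[-1].offset
    else:
        onsets = np.asarray([b.onset for b in bursts])
        period = float(np.median(np.diff(onsets))) if len(onsets) > 1 else 0.02
        window = config.mod_window_periods * period
        centers, idx = modulation_index(envelope, window, step_s=period)
        modulated = idx > config.mod_index_threshold
        if not np.any(modulated):
            raise SegmentationError(
                "modulation never detected: the neomexicensis phrase rule needs "
                "an amplitude-modulated main phrase"
            )
        last_mod = centers[np.where(modulated)[0][-1]] + window / 2
        cand = [b.offset for b in bursts if b.onset <= last_mod + period]
        if not cand:
            raise SegmentationError("no burst inside the modulated portion of the call")
        t23 = max(cand)

    dt = 1.0 / wf.sample_rate
    return PhraseBoundaries(
        t0=min(t0, t12 - dt),
        t12=t12,
        t23=t23,
        t_end=max(t_end, t23 + dt),
        rule_set=rule_set,
    )
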