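"""Analysis configuration: every threshold and cutoff in one serializable object.

All detection stages read their tunables from an :class:`AnalysisConfig`, and
every analysis result records the hash of the config that produced it, so runs
are reproducible from the stored config alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters for the acoustic analysis pipeline.

    Attributes
    ----------
    burst_env_cutoff_hz
        Low-pass cutoff of the burst-band amplitude envelope.  Must pass the
        amplitude-modulation rates of interest (<= 120 bursts/s) while
        rejecting the carrier (>= 5 kHz); default 150 Hz.
    pulse_env_cutoff_hz
        Cutoff of the wide-band envelope used to resolve individual pulses
        inside a burst; default 2000 Hz.
    env_filter_order
        Order of the zero-phase Butterworth low-pass; default 4.
    gate_open_frac, gate_close_frac
        Hysteresis gate thresholds as fractions of the reference envelope
        level (open 0.45, close 0.35).  Open > close avoids chatter on noisy
        troughs.
    gate_ref_percentile
        Percentile of the envelope used as the gate reference level (95, a
        robust stand-in for "burst peak level").
    phrase_threshold_dbfs
        Burst peak level (re full scale, after whole-call normalization) that
        marks the phrase-1/2 boundary and, for the chiricahua rule, the
        phrase-2/3 boundary; -3 dBFS.
    mod_window_periods, mod_index_threshold
        The neomexicensis phrase-2/3 rule: amplitude modulation is "present"
        where the (peak - trough)/(peak + trough) index of the burst-band
        envelope over a sliding window of 5 burst periods exceeds 0.25.
    noise_floor_dbfs, call_edge_margin_db
        Assumed recording noise floor and the margin above it (10 dB) whose
        first/last envelope crossings define call start and termination.
    pulse_min_separation_s
        Minimum spacing between detected pulse peaks (0.5 ms; true pulses at
        a ~7 kHz carrier cannot be closer).
    pulse_merge_trough_frac
        Adjacent envelope maxima are treated as the same pulse when the
        trough between them stays above this fraction (0.7) of the lower
        maximum — distinct pulses are separated by a real envelope dip,
        ripple on a pulse's top is not a new pulse.
    pulse_amp_frac
        Fraction of the normalized span maximum a pulse must exceed to count
        as part of a burst (0.5, i.e. -6.02 dBFS).
    n_middle_bursts
        Number of bursts taken from the middle of the call for pulse counting
        (12).
    fft_size
        FFT length for the power spectral density (512 samples, Hamming).
    spectrogram_fft_size
        FFT length for rendered spectrograms (256 samples, Hamming).
    species
        Phrase-segmentation rule set: "chiricahua" or "neomexicensis".
    """

    burst_env_cutoff_hz: float = 150.0
    pulse_env_cutoff_hz: float = 2000.0
    env_filter_order: int = 4
    gate_open_frac: float = 0.45
    gate_close_frac: float = 0.35
    gate_ref_percentile: float = 95.0
    phrase_threshold_dbfs: float = -3.0
    mod_window_periods: float = 5.0
    mod_index_threshold: float = 0.25
    noise_floor_dbfs: float = -60.0
    call_edge_margin_db: float = 10.0
    pulse_min_separation_s: float = 0.0005
    pulse_amp_frac: float = 0.5
    pulse_merge_trough_frac: float = 0.7
    n_middle_bursts: int = 12
    fft_size: int = 512
    spectrogram_fft_size: int = 256
    species: str = "chiricahua"

    def __post_init__(self) -> None:
        if not (0 < self.gate_close_frac < self.gate_open_frac < 1):
            raise ValueError("gate thresholds must satisfy 0 < close < open < 1")
        if self.burst_env_cutoff_hz <= 0 or self.pulse_env_cutoff_hz <= 0:
            raise ValueError("envelope cutoffs must be positive")
        if self.phrase_threshold_dbfs >= 0:
            raise ValueError("phrase_threshold_dbfs must be below full scale")
        if not 0 < self.mod_index_threshold < 1:
            raise ValueError("mod_index_threshold must lie in (0, 1)")
        if self.species not in ("chiricahua", "neomexicensis"):
            raise ValueError(f"unknown species rule set: {self.species!r}")
        if self.fft_size < 2 or self.fft_size & (self.fft_size - 1):
            raise ValueError("fft_size must be a power of two")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short stable hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def replace(self, **kwargs) -> "AnalysisConfig":
        d = self.to_dict()
        d.update(kwargs)
        return AnalysisConfig(**d)
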