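"""Parametric synthesis of cicada calling songs with exact ground truth.

A calling song is modeled as a continuous train of short damped-sinusoid
pulses at a carrier frequency.  Pulses are grouped into periodic high-amplitude
*bursts* (the amplitude modulation), with low-amplitude "fill" pulses in the
inter-burst gaps so the train never goes silent.  Bursts are organized into
three phrases:

* ``chiricahua`` template — crescendo, full-amplitude plateau, then a gradual
  decrescendo with bursts continuing throughout;
* ``neomexicensis`` template — modulated crescendo, modulated plateau, then an
  abrupt amplitude drop into an *unmodulated* uniform pulse-train tail.

The generator is built so that its nominal phrase durations coincide exactly
with the operational boundary definitions the analysis uses (first burst to
reach -3 dBFS; last burst to reach -3 dBFS, or modulation cessation):

* all pulse slots sit on one global grid anchored at the phrase-1/2 boundary,
  so a burst onset falls exactly at ``d1``;
* the burst period is adjusted slightly from ``1/burst_rate`` to
  ``T' = d2 / (N2 - 1 + duty)`` so that the *offset* of the last phrase-2
  burst falls exactly at ``d1 + d2`` (the adjustment is below 0.15% for
  realistic parameters and the realized rate is recorded in the ground truth);
* crescendo and decrescendo burst peaks stay safely below the -3 dBFS
  threshold while plateau bursts sit at 0 dBFS.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sps

from cicadasong.audio_io import Waveform, dbfs_to_amplitude

#: Minimum pulse length, in carrier cycles, for a pulse to be well formed.
MIN_PULSE_CYCLES = 3


@dataclass(frozen=True)
class CallSpec:
    """Generative parameters of one synthetic calling song.

    Parameters
    ----------
    species_template
        "chiricahua" or "neomexicensis" phrase-envelope template.
    carrier_freq
        Pulse carrier frequency in Hz (the song's spectral peak).
    burst_rate
        Nominal amplitude-burst rate in bursts/s during the main phrase.
    pulses_per_burst
        Number of high-amplitude pulses in each burst.
    phrase_durations
        Nominal (and, by construction, operational) durations of the three
        phrases in seconds.
    modulation_depth
        Amplitude of inter-burst fill pulses relative to the local burst
        peak; the trough/peak ratio of the amplitude modulation.
    noise_floor_dbfs
        RMS level of the additive Gaussian recording noise (< -40 dBFS).
    seed
        Seed for the noise generator; same spec + same seed is bit-identical.
    duty
        Fraction of each burst period occupied by the high-amplitude pulse
        group.
    crescendo_start, crescendo_stop
        Burst peak amplitudes (linear, re full scale) at the beginning and
        end of phrase 1.  ``crescendo_stop`` must stay below the -3 dBFS
        boundary criterion (0.708).
    tail_start, tail_stop
        Envelope of phrase 3: for chiricahua a decrescendo of burst peaks
        from ``crescendo_stop`` down to ``tail_stop``; for neomexicensis a
        uniform unmodulated pulse train from ``tail_start`` down to
        ``tail_stop``.
    fm_depth
        Fractional carrier deviation synchronous with the amplitude bursts
        (the neomexicensis template's frequency modulation); 0 disables it.
    continuous_carrier_phase
        Keep the carrier phase continuous across pulses, as a resonant
        sound-producing system does, so the call is an amplitude-modulated
        carrier whose spectrum has a line exactly at ``carrier_freq``.  If
        instead every pulse restarts at phase zero, the strictly periodic
        identical pulses form a comb spectrum at harmonics of the pulse
        repetition rate, which can displace the spectral peak from the
        carrier by up to half the repetition rate.
    pad_s
        Leading/trailing noise-only padding in seconds.
    sample_rate
        Output sample rate in Hz.
    pulse_decay, pulse_max_len_s
        Residual amplitude fraction at the end of each pulse and the cap on
        pulse length.
    """

    species_template: str = "chiricahua"
    carrier_freq: float = 7120.0
    burst_rate: float = 54.0
    pulses_per_burst: int = 5
    phrase_durations: tuple[float, float, float] = (1.72, 7.82, 3.75)
    modulation_depth: float = 0.2
    noise_floor_dbfs: float = -60.0
    seed: int = 0
    duty: float = 0.5
    crescendo_start: float = 0.08
    crescendo_stop: float = 0.55
    tail_start: float = 0.25
    tail_stop: float = 0.05
    fm_depth: float = 0.0
    pad_s: float = 0.25
    sample_rate: int = 44100
    pulse_decay: float = 0.05
    pulse_max_len_s: float = 0.005
    continuous_carrier_phase: bool = True

    def __post_init__(self) -> None:
        if self.species_template not in ("chiricahua", "neomexicensis"):
            raise ValueError(f"unknown species template: {self.species_template!r}")
        if not 1000.0 < self.carrier_freq < 20000.0:
            raise ValueError("carrier_freq must lie in (1, 20) kHz")
        if self.burst_rate <= 0:
            raise ValueError("burst_rate must be positive")
        if self.pulses_per_burst < 1:
            raise ValueError("pulses_per_burst must be a positive integer")
        if any(d <= 0 for d in self.phrase_durations) or len(self.phrase_durations) != 3:
            raise ValueError("phrase_durations must be three positive values")
        if not 0.0 <= self.modulation_depth < 1.0:
            raise ValueError("modulation_depth must lie in [0, 1)")
        if self.noise_floor_dbfs >= -40.0:
            raise ValueError("noise_floor_dbfs must be below -40 dBFS")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must lie in (0, 1)")
        # The pulses_per_burst pulses must fit in the duty portion of one
        # burst period with at least MIN_PULSE_CYCLES carrier cycles each.
        slot = self.duty / (self.burst_rate * self.pulses_per_burst)
        if slot < MIN_PULSE_CYCLES / self.carrier_freq:
            raise ValueError(
                f"{self.pulses_per_burst} pulses do not fit in one burst period "
                f"at {self.burst_rate} bursts/s (pulse slot {slot * 1e3:.3f} ms < "
                f"{MIN_PULSE_CYCLES} carrier cycles)"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phrase_durations"] = list(self.phrase_durations)
        return d


@dataclass
class GroundTruth:
    """Operational ground truth implied by a :class:`CallSpec`.

    Times are in seconds from the start of the emitted waveform (i.e. they
    include the leading noise padding).  The operational phrase boundaries
    coincide with the analysis criteria by construction.
    """

    spec: CallSpec
    t0: float
    t12: float
    t23: float
    t_end: float
    burst_onsets: np.ndarray
    burst_offsets: np.ndarray
    pulse_times: list[np.ndarray]
    realized_burst_rate: float

    @property
    def phrase_durations(self) -> tuple[float, float, float]:
        return (self.t12 - self.t0, self.t23 - self.t12, self.t_end - self.t23)

    def phrase2_burst_onsets(self) -> np.ndarray:
        m = (self.burst_onsets >= self.t12 - 1e-9) & (self.burst_onsets < self.t23 - 1e-9)
        return self.burst_onsets[m]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": self.spec.to_dict(),
            "t0": round(self.t0, 6),
            "t12": round(self.t12, 6),
            "t23": round(self.t23, 6),
            "t_end": round(self.t_end, 6),
            "realized_burst_rate": round(self.realized_burst_rate, 6),
            "burst_onsets": np.round(self.burst_onsets, 6).tolist(),
            "burst_offsets": np.round(self.burst_offsets, 6).tolist(),
            "pulse_times": [np.round(p, 6).tolist() for p in self.pulse_times],
        }
        Path(path).write_text(json.dumps(payload))


@dataclass(frozen=True)
class MorphGroupSpec:
    """One species x sex morphometric group: normal(mean, sd) with n members."""

    species: str
    sex: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 1:
            raise ValueError("n must be at least 1")


# ---------------------------------------------------------------------------
# species defaults: the field-measured means that parameterize realistic calls
# ---------------------------------------------------------------------------

#: Species-mean acoustic parameters (carrier in Hz, rate in bursts/s,
#: integer pulses/burst nearest the measured mean, phrase durations in s).
SPECIES_ACOUSTIC_MEANS: dict[str, dict] = {
    "chiricahua": {
        "carrier_freq": 7120.0,
        "burst_rate": 54.0,
        "pulses_per_burst": 5,
        "phrase_durations": (1.72, 7.82, 3.75),
        "fm_depth": 0.0,
        "n": 11,
    },
    "neomexicensis": {
        "carrier_freq": 7270.0,
        "burst_rate": 27.8,
        "pulses_per_burst": 8,
        "phrase_durations": (2.04, 6.68, 1.65),
        "fm_depth": 0.005,
        "n": 15,
    },
}

#: Between-individual coefficients of variation (sd/mean of the measured
#: species samples) for population synthesis.
SPECIES_ACOUSTIC_CV: dict[str, dict[str, float]] = {
    "chiricahua": {
        "carrier_freq": 0.82 / 7.12,
        "burst_rate": 2.32 / 54.0,
        "pulses_per_burst": 0.723 / 5.02,
        "phrase1": 0.758 / 1.72,
        "phrase2": 1.286 / 7.82,
        "phrase3": 0.963 / 3.75,
    },
    "neomexicensis": {
        "carrier_freq": 0.45 / 7.27,
        "burst_rate": 0.86 / 27.8,
        "pulses_per_burst": 1.066 / 8.34,
        "phrase1": 0.60 / 2.04,
        "phrase2": 1.575 / 6.68,
        "phrase3": 0.479 / 1.65,
    },
}


def default_call_spec(species: str, seed: int = 0, **overrides) -> CallSpec:
    """A :class:`CallSpec` at the measured species-mean parameters."""
    if species not in SPECIES_ACOUSTIC_MEANS:
        raise ValueError(f"unknown species: {species!r}")
    base = SPECIES_ACOUSTIC_MEANS[species]
    kwargs = dict(
        species_template=species,
        carrier_freq=base["carrier_freq"],
        burst_rate=base["burst_rate"],
        pulses_per_burst=base["pulses_per_burst"],
        phrase_durations=base["phrase_durations"],
        fm_depth=base["fm_depth"],
        seed=seed,
    )
    kwargs.update(overrides)
    return CallSpec(**kwargs)


def default_morph_groups() -> list[MorphGroupSpec]:
    """Fore-wing-length groups at the measured species x sex means (mm)."""
    return [
        MorphGroupSpec("chiricahua", "M", 31.3, 1.06, 11),
        MorphGroupSpec("neomexicensis", "M", 28.1, 0.76, 11),
        MorphGroupSpec("chiricahua", "F", 29.1, 0.88, 5),
        MorphGroupSpec("neomexicensis", "F", 26.7, 0.48, 5),
    ]


# ---------------------------------------------------------------------------
# pulse and call synthesis
# ---------------------------------------------------------------------------


def synth_pulse(
    carrier_freq: float,
    duration: float,
    sample_rate: int,
    *,
    amplitude: float = 1.0,
    decay_target: float = 0.05,
) -> np.ndarray:
    """One sound pulse: an exponentially damped sinusoid at the carrier.

    The pulse peaks near its onset (first quarter carrier cycle) and decays to
    ``decay_target`` of its peak by the end of ``duration``.  Requires at
    least :data:`MIN_PULSE_CYCLES` carrier cycles.
    """
    if duration < MIN_PULSE_CYCLES / carrier_freq:
        raise ValueError(
            f"pulse duration {duration * 1e3:.3f} ms is shorter than "
            f"{MIN_PULSE_CYCLES} cycles of the {carrier_freq:.0f} Hz carrier"
        )
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    tau = duration / math.log(1.0 / decay_target)
    return amplitude * np.exp(-t / tau) * np.sin(2.0 * math.pi * carrier_freq * t)


def _quadrature_templates(
    carriers: dict[int, float], pulse_len: float, fs: int, decay: float
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Sine/cosine damped-pulse pair per carrier, for arbitrary-phase pulses."""
    out = {}
    n = int(round(pulse_len * fs))
    t = np.arange(n) / fs
    tau = pulse_len / math.log(1.0 / decay)
    damp = np.exp(-t / tau)
    for key, f in carriers.items():
        w = 2.0 * math.pi * f * t
        out[key] = (damp * np.sin(w), damp * np.cos(w))
    return out


def _pulse_with_phase(
    templates: dict[int, tuple[np.ndarray, np.ndarray]],
    key: int,
    phase: float | None,
) -> np.ndarray:
    """Damped pulse whose carrier starts at the given phase (None -> 0)."""
    tpl_sin, tpl_cos = templates[key]
    if phase is None:
        return tpl_sin
    return math.cos(phase) * tpl_sin + math.sin(phase) * tpl_cos


def _grid_layout(spec: CallSpec) -> tuple[int, float, float, int, float]:
    """Pulse-slot geometry: (slots/period m, period T', slot s', N2, burst_dur)."""
    t_nom = 1.0 / spec.burst_rate
    m = max(spec.pulses_per_burst + 1, int(round(spec.pulses_per_burst / spec.duty)))
    duty_eff = spec.pulses_per_burst / m
    d2 = spec.phrase_durations[1]
    # round-half-down keeps the phrase-2 burst count at rate*d2 when the
    # grid could align either way
    n2 = max(2, math.ceil(d2 / t_nom - duty_eff - 0.5) + 1)
    t_adj = d2 / (n2 - 1 + duty_eff)
    slot = t_adj / m
    burst_dur = spec.pulses_per_burst * slot
    return m, t_adj, slot, n2, burst_dur


def synth_call(spec: CallSpec) -> tuple[Waveform, GroundTruth]:
    """Synthesize one full three-phrase calling song with its ground truth.

    Returns a peak-normalized waveform (lead/trail noise padding of
    ``spec.pad_s``) and a :class:`GroundTruth` whose phrase boundaries equal
    the operational -3 dBFS / modulation-cessation definitions exactly.
    """
    fs = spec.sample_rate
    d1, d2, d3 = spec.phrase_durations
    total = d1 + d2 + d3
    m, t_adj, slot, n2, burst_dur = _grid_layout(spec)

    pulse_len = min(spec.pulse_max_len_s, 0.9 * slot)
    if pulse_len < MIN_PULSE_CYCLES / spec.carrier_freq:
        raise ValueError(
            "pulses do not fit the burst period: pulse slot too short for "
            f"{MIN_PULSE_CYCLES} carrier cycles at {spec.carrier_freq:.0f} Hz"
        )

    neo = spec.species_template == "neomexicensis"
    carriers = {0: spec.carrier_freq}
    if neo and spec.fm_depth > 0:
        carriers[+1] = spec.carrier_freq * (1.0 + spec.fm_depth)
        carriers[-1] = spec.carrier_freq * (1.0 - spec.fm_depth)
    templates = _quadrature_templates(carriers, pulse_len, fs, spec.pulse_decay)
    rng = np.random.default_rng(spec.seed)

    def phrase_gain(onset: float) -> float:
        if onset < d1:
            frac = max(onset, 0.0) / d1
            return spec.crescendo_start + (spec.crescendo_stop - spec.crescendo_start) * frac
        if onset < d2 + d1 - 1e-12:
            return 1.0
        # chiricahua decrescendo (neomexicensis tail slots never reach here)
        frac = min((onset - d1 - d2) / d3, 1.0)
        return spec.crescendo_stop + (spec.tail_stop - spec.crescendo_stop) * frac

    n_total = int(round((total + 2 * spec.pad_s) * fs))
    x = np.zeros(n_total)

    j_min = -int(math.floor(d1 / slot + 1e-9))
    j_max = int(math.ceil((d2 + d3) / slot)) + 1

    onsets: list[float] = []
    offsets: list[float] = []
    pulse_times: list[list[float]] = []

    for j in range(j_min, j_max + 1):
        t_j = d1 + j * slot
        if t_j < -1e-12 or t_j >= total - 1e-12:
            continue
        k = math.floor(j / m + 1e-12)
        p = j - m * k
        onset_k = d1 + k * t_adj
        high = p < spec.pulses_per_burst
        in_tail = neo and t_j >= d1 + d2 - 1e-12
        if in_tail:
            frac = (t_j - d1 - d2) / d3
            amp = spec.tail_start + (spec.tail_stop - spec.tail_start) * frac
            carrier_key = 0
        else:
            g = phrase_gain(onset_k)
            amp = g if high else g * spec.modulation_depth
            carrier_key = 0
            if neo and spec.fm_depth > 0:
                carrier_key = +1 if high else -1
        if amp <= 0:
            continue
        start = int(round((spec.pad_s + t_j) * fs))
        phase = (
            2.0 * math.pi * carriers[carrier_key] * (start / fs)
            if spec.continuous_carrier_phase
            else None
        )
        tpl = _pulse_with_phase(templates, carrier_key, phase)
        stop = min(start + len(tpl), n_total)
        if stop > start:
            x[start:stop] += amp * tpl[: stop - start]
        if high and not in_tail and 0.0 - 1e-12 <= onset_k < total:
            if p == 0:
                onsets.append(onset_k)
                offsets.append(onset_k + burst_dur)
                pulse_times.append([])
            if pulse_times:
                pulse_times[-1].append(t_j)

    sigma = dbfs_to_amplitude(spec.noise_floor_dbfs)
    x += rng.normal(0.0, sigma, n_total)
    x /= np.max(np.abs(x))

    lead = spec.pad_s
    first_slot = d1 + j_min * slot  # earliest pulse time, in [0, slot)
    gt = GroundTruth(
        spec=spec,
        t0=lead + max(first_slot, 0.0),
        t12=lead + d1,
        t23=lead + d1 + d2,
        t_end=lead + total,
        burst_onsets=np.asarray(onsets) + lead,
        burst_offsets=np.asarray(offsets) + lead,
        pulse_times=[np.asarray(p) + lead for p in pulse_times],
        realized_burst_rate=1.0 / t_adj,
    )
    return Waveform(x, fs), gt


def synth_burst_train(
    burst_rate: float,
    pulses_per_burst: int,
    carrier_freq: float,
    duration: float,
    *,
    species_template: str = "chiricahua",
    sample_rate: int = 44100,
    modulation_depth: float = 0.2,
    duty: float = 0.5,
    noise_floor_dbfs: float = -60.0,
    fm_depth: float | None = None,
    seed: int = 0,
) -> tuple[Waveform, np.ndarray]:
    """A steady main-phrase pulse train with the first burst onset at t = 0.

    Bursts repeat at exactly the nominal ``1/burst_rate`` period (no grid
    adjustment — there are no phrase boundaries to align).  Returns the
    peak-normalized waveform and the array of true burst onset times; onsets
    strictly inside ``[0, duration)``.
    """
    spec = CallSpec(
        species_template=species_template,
        carrier_freq=carrier_freq,
        burst_rate=burst_rate,
        pulses_per_burst=pulses_per_burst,
        modulation_depth=modulation_depth,
        duty=duty,
        noise_floor_dbfs=noise_floor_dbfs,
        fm_depth=(
            fm_depth
            if fm_depth is not None
            else SPECIES_ACOUSTIC_MEANS[species_template]["fm_depth"]
        ),
        seed=seed,
        sample_rate=sample_rate,
        pad_s=0.0,
    )
    fs = sample_rate
    t_nom = 1.0 / burst_rate
    m = max(pulses_per_burst + 1, int(round(pulses_per_burst / duty)))
    slot = t_nom / m
    pulse_len = min(spec.pulse_max_len_s, 0.9 * slot)
    if pulse_len < MIN_PULSE_CYCLES / carrier_freq:
        raise ValueError("pulses do not fit the burst period")

    neo = species_template == "neomexicensis"
    carriers = {0: carrier_freq}
    if neo and spec.fm_depth > 0:
        carriers[+1] = carrier_freq * (1.0 + spec.fm_depth)
        carriers[-1] = carrier_freq * (1.0 - spec.fm_depth)
    templates = _quadrature_templates(carriers, pulse_len, fs, spec.pulse_decay)
    rng = np.random.default_rng(seed)

    n_total = int(round(duration * fs))
    x = np.zeros(n_total)
    onsets = []
    j = 0
    while True:
        t_j = j * slot
        if t_j >= duration - 1e-12:
            break
        p = j % m
        high = p < pulses_per_burst
        amp = 1.0 if high else modulation_depth
        key = 0
        if neo and spec.fm_depth > 0:
            key = +1 if high else -1
        if p == 0:
            onsets.append(t_j)
        start = int(round(t_j * fs))
        phase = (
            2.0 * math.pi * carriers[key] * (start / fs)
            if spec.continuous_carrier_phase
            else None
        )
        tpl = _pulse_with_phase(templates, key, phase)
        stop = min(start + len(tpl), n_total)
        if stop > start:
            x[start:stop] += amp * tpl[: stop - start]
        j += 1

    x += rng.normal(0.0, dbfs_to_amplitude(noise_floor_dbfs), n_total)
    x /= np.max(np.abs(x))
    return Waveform(x, fs), np.asarray(onsets)


# ---------------------------------------------------------------------------
# population and morphometric synthesis
# ---------------------------------------------------------------------------


def _truncnorm_draw(rng: np.random.Generator, mean: float, cv: float) -> float:
    """One truncated-normal draw (±3 SD) around mean with coefficient of variation cv."""
    if cv == 0.0:
        return mean
    sd = cv * mean
    return float(
        sps.truncnorm.rvs(-3.0, 3.0, loc=mean, scale=sd, random_state=rng)
    )


def synth_population(
    base: CallSpec,
    cv_per_parameter: dict[str, float] | None = None,
    n: int = 10,
    seed: int = 0,
) -> list[tuple[Waveform, GroundTruth]]:
    """Synthesize ``n`` calls with between-individual parameter variation.

    Per call, each parameter named in ``cv_per_parameter`` (keys:
    ``carrier_freq``, ``burst_rate``, ``pulses_per_burst``, ``phrase1``,
    ``phrase2``, ``phrase3``) is drawn from a truncated normal (±3 SD) with
    the given coefficient of variation around the base value.  ``cv = None``
    uses the measured species CVs.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if cv_per_parameter is None:
        cv_per_parameter = SPECIES_ACOUSTIC_CV[base.species_template]
    if any(v < 0 for v in cv_per_parameter.values()):
        raise ValueError("coefficients of variation must be non-negative")
    cv = dict(cv_per_parameter)
    rng = np.random.default_rng(seed)
    calls = []
    for i in range(n):
        d1 = _truncnorm_draw(rng, base.phrase_durations[0], cv.get("phrase1", 0.0))
        d2 = _truncnorm_draw(rng, base.phrase_durations[1], cv.get("phrase2", 0.0))
        d3 = _truncnorm_draw(rng, base.phrase_durations[2], cv.get("phrase3", 0.0))
        ppb = max(
            1,
            int(round(_truncnorm_draw(rng, float(base.pulses_per_burst), cv.get("pulses_per_burst", 0.0)))),
        )
        spec = CallSpec(
            **{
                **base.to_dict(),
                "carrier_freq": _truncnorm_draw(rng, base.carrier_freq, cv.get("carrier_freq", 0.0)),
                "burst_rate": _truncnorm_draw(rng, base.burst_rate, cv.get("burst_rate", 0.0)),
                "pulses_per_burst": ppb,
                "phrase_durations": (d1, d2, d3),
                "seed": int(rng.integers(0, 2**31 - 1)),
            }
        )
        calls.append(synth_call(spec))
    return calls


def synth_morphometrics(groups: list[MorphGroupSpec], seed: int = 0):
    """Synthetic morphometric table: per group, ``n`` normal(mean, sd) draws.

    Returns a pandas DataFrame with columns ``species``, ``sex``,
    ``value_mm``.  ``sd = 0`` yields exactly constant groups.
    """
    import pandas as pd

    if not groups:
        raise ValueError("groups must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        values = g.mean + g.sd * rng.standard_normal(g.n)
        for v in values:
            rows.append({"species": g.species, "sex": g.sex, "value_mm": float(v)})
    return pd.DataFrame(rows)
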