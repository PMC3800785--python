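# Methods

## Signal model

A calling song is modeled as an amplitude-modulated carrier.  The elemental
unit is the **pulse**: an exponentially damped sinusoid at the carrier
frequency (5.7–8.5 kHz for these species), a few milliseconds long, decaying
to 5% of its peak by its end.  The carrier phase is kept continuous across
pulses, as a resonant sound-producing system would: the song is then a pure
amplitude modulation of one carrier, and its power spectral density has a
line exactly at the carrier frequency.  (If instead every pulse restarted at
phase zero, the strictly periodic identical pulses would form a comb spectrum
at harmonics of the pulse repetition rate, displacing the PSD peak from the
carrier by up to half that rate — an artifact of perfect periodicity, not a
property of real songs.)

Pulses sit on a uniform slot grid.  Each burst period contains
`pulses_per_burst` high-amplitude slots followed by low-amplitude "fill"
slots at `modulation_depth` (default 0.2) of the local burst peak, so the
train is continuous rather than silent between bursts.  The duty cycle of
the high-amplitude group is 0.5 by default.

Two phrase templates:

* **chiricahua** — bursts throughout: linear crescendo of burst peaks
  (0.08 → 0.55 of full scale) over phrase 1, plateau at full scale over
  phrase 2, linear decrescendo (0.55 → 0.05) over phrase 3;
* **neomexicensis** — modulated crescendo and plateau as above, then an
  abrupt drop into an *unmodulated* uniform pulse train (0.25 → 0.05) over
  phrase 3.  A small carrier deviation (`fm_depth`, default 0.5%)
  synchronous with the bursts models this species' frequency modulation; it
  is decorative for the pipeline, which measures peak frequency from the
  whole-phrase PSD.

Additive Gaussian noise at `noise_floor_dbfs` (default −60 dBFS RMS) plus
0.25 s of noise-only padding at each end stand in for the recording chain.
All randomness (noise, population draws) is controlled by explicit seeds.

## Ground-truth / criterion alignment

The phrase boundaries are *operational*: phrase 1 ends at the onset of the
first burst whose peak reaches −3 dBFS after whole-call peak normalization;
phrase 2 ends at the offset of the last −3 dBFS burst (chiricahua) or where
modulation ceases (neomexicensis).  The generator is constructed so its
nominal durations equal these operational boundaries exactly:

* the pulse-slot grid is anchored at the phrase-1/2 boundary, so a burst
  onset falls exactly at `d1`; crescendo peaks stay below −3 dBFS
  (0.55 < 0.708) while plateau bursts sit at 0 dBFS;
* the burst period is adjusted from the nominal `1/burst_rate` to
  `T' = d2/(N2 − 1 + duty)`, with `N2` the rounded-half-down burst count,
  so the *offset* of the last phrase-2 burst lands exactly at `d1 + d2`.
  The adjustment is < 0.15% at realistic parameters; the realized rate
  (`1/T'`) is recorded in the ground truth and equals the nominal rate at
  one-decimal precision;
* phrase 3 ends exactly at `d1 + d2 + d3` (the tail stops at 0.05 of full
  scale, well above the noise gate, so termination is detected sharply).

Half-integer burst-count cases round down so that a `rate × duration`
main phrase holds exactly `rate × duration` bursts.

## Measurement pipeline

All thresholds live in one `AnalysisConfig`; every result records the
config hash.  Defaults, and why:

| parameter | default | role |
|---|---|---|
| `burst_env_cutoff_hz` | 150 Hz | envelope low-pass; passes ≤120 bursts/s modulation, rejects the ≥5 kHz carrier |
| `pulse_env_cutoff_hz` | 2 kHz | wide-band envelope that resolves single pulses |
| `env_filter_order` | 4 | Butterworth order (run zero-phase, forward–backward) |
| `gate_open_frac` / `gate_close_frac` | 0.45 / 0.35 | hysteresis gate, relative to the 95th-percentile envelope level |
| `phrase_threshold_dbfs` | −3 | phrase-boundary burst criterion |
| `mod_window_periods` / `mod_index_threshold` | 5 / 0.25 | sliding-window modulation index for the neomexicensis rule |
| `noise_floor_dbfs` + `call_edge_margin_db` | −60 + 10 | call start/termination = first/last envelope crossing of this gate |
| `pulse_min_separation_s` | 0.5 ms | true pulses at a ~7 kHz carrier cannot be closer |
| `pulse_amp_frac` | 0.5 | the −6.02 dBFS pulse-inclusion criterion |
| `pulse_merge_trough_frac` | 0.7 | adjacent envelope maxima without a real dip between them are one pulse |
| `n_middle_bursts` | 12 | bursts taken from the call's middle for pulse counting |
| `fft_size` | 512 | PSD segment length (Hamming window, 50% overlap, Welch average) |

Numerical choices worth noting:

* **Envelope.** Full-wave rectification followed by a zero-phase low-pass,
  scaled by π/2 so a constant sinusoid reads its peak amplitude.  Edge
  padding is *even*-type: the rectified signal is non-negative, and an odd
  extension would inject a sign discontinuity whose filter transient can
  poke above the noise gate at the array ends.
* **Burst peak level.** The −3 dBFS criteria are evaluated on the maximum
  absolute *sample* inside each gate interval, not on the smoothed envelope:
  the envelope of damped pulses averages well below their peaks, which would
  make even a full-scale burst read below −3 dBFS.
* **Phrase-2/3 boundary, neomexicensis rule.** The modulation index
  ((peak − trough)/(peak + trough) of the burst-band envelope over a sliding
  window of 5 burst periods, threshold 0.25) localizes the modulated region;
  the boundary then snaps to the offset of the last detected burst inside
  it.  The window alone would bias the boundary by up to half a window;
  snapping to a burst offset removes that bias, and bursts cannot be
  detected in the unmodulated tail (its level sits below the gate-open
  threshold).
* **Pulse counting.** The 12-burst span is normalized to 0 dBFS; pulse
  candidates are local maxima of the wide-band envelope at least 0.5 ms
  apart; runs of maxima whose intervening trough stays above 0.7 of the
  lower maximum are merged (ripple on a flat-topped pulse is not a new
  pulse).  Each burst's window extends to the midpoints toward its
  neighbors, so gate-timing lag cannot clip a burst's first pulse; the 50%
  amplitude criterion is what excludes inter-burst fill pulses.  The span
  maximum is taken over the normalized 12-burst span, not per burst.
* **Peak frequency.** Candidate peaks are local maxima of the dB spectrum
  (edge bins included when they dominate their neighbor).  If ≥ 2 candidates
  lie within 0.5 dB of the global maximum their bin frequencies are
  averaged; a difference of exactly 0.5 dB does not tie.  The PSD is
  computed over phrase 2 when boundaries are available.
* **Burst rate** is `(n − 1)/(t_last − t_first)` over phrase-2 onsets —
  invariant to overall amplitude scaling and to any uniform detection lag.

## Statistics

Group summaries use the n−1 SD and t-based 95% CIs.  Linear models are
ordinary least squares with treatment coding, the alphabetically first
factor level as reference (so the species coefficient for
{chiricahua, neomexicensis} is "neomexicensis minus chiricahua"; at the
generator's fore-wing group means it is −2.95 mm).  Nested models are
compared with F = ((RSS_r − RSS_f)/Δdf)/(RSS_f/df_f); in the one-factor
two-level case this equals the squared pooled t.  The six acoustic
comparisons are reported as one family with no multiplicity correction, and
the report flags this.  Standardized (internally studentized) residuals are
attached to every fit for diagnostic plots.  A preliminary locality-nested
model comparison can be run with the same `f_test_nested` machinery by
passing a locality factor.

## What the generator does and does not emulate

It reproduces the statistical structure the measurements assume: carrier
periodicity, burst periodicity with realistic rates and pulse counts,
species-templated phrase envelopes, between-individual parameter variation
(truncated normal at ±3 SD, CVs taken from the measured species samples),
and a stationary Gaussian noise floor.  It does **not** emulate overlapping
singers, wind/handling noise, reverberation, temperature dependence, the
occasional return of modulation at the very end of a neomexicensis call, or
drift of burst rate within a call.  Passing recovery tests therefore shows
the pipeline is correct under clean single-singer conditions, not that it is
robust to adverse field recordings.

## Problem sizes

The parameter-recovery grid runs 160 calls (5 burst rates × 4 pulse counts ×
4 carriers × 2 templates) with 0.6 / 2.5 / 0.6 s phrases — long enough for
≥ 60 main-phrase bursts at the slowest rate while keeping the grid fast.
Statistical calibration uses 500 null replicates (type-I error) and 200
replicates each for interaction power and CI coverage.

## Known limitations

* The gate and envelope parameters were chosen for the 26–60 bursts/s,
  5.7–8.5 kHz regime; far outside it (e.g. burst rates above ~120/s) the
  envelope cutoff must be raised via the config.
* Peak frequency is reported on the 86.13 Hz FFT bin grid (or an average of
  near-tied bins), so it carries quantization of that order by design.
* Multi-call recordings are out of scope: the segmenter assumes one call per
  file, framed by its noise padding.
* WAV I/O is deliberately minimal: mono/stereo 16-bit PCM only.
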