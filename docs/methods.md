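# Methods

This note documents the models, detection rules, numerical choices and
limitations behind `epivent`. Units are seconds, Hz and arbitrary amplitude
units (a.u.) throughout; all times are recording-relative with half-open
intervals, and sample *i* of a channel covers `[start + i/rate, start +
(i+1)/rate)`.

## Signal model and conventions

A recording is two uniformly sampled channels: cortical EEG (default 500 Hz)
and raw diaphragm EMG (default 1000 Hz), plus an optional movement mask
(sorted, non-overlapping intervals during which the animal is moving; its
derivation from video is outside the package — it is an input). Amplitudes
are treated as arbitrary units everywhere because chronic telemetry
amplitude depends on electrode placement; all amplitude comparisons are
ratios within one animal. EDF physical-dimension fields are carried but not
interpreted.

## Diaphragm EMG processing

1. **High-pass, 60 Hz** (4th-order Butterworth, zero-phase via
   forward–backward filtering so burst timing is unbiased). Requires a
   sampling rate above twice the cutoff.
2. **Rectify–integrate**: trailing moving average of |x| over a 36–50 ms
   window (default 40 ms, the middle of the allowed range). The window is
   ~5× wider than an ECG R-wave, so cardiac spikes are attenuated by
   roughly the width ratio (≈1/5) while the ~80 ms inspiratory burst
   envelope is preserved. Partial windows at the start of the record
   average over the samples available.
3. **Burst segmentation** on the integrated trace. The procedure itself is
   under-specified in chart-software practice, so the rule here is explicit
   and exposed as parameters:
   * threshold = rolling median (5 s, evaluated on a 1 s grid and
     interpolated) + 4 × rolling MAD;
   * the local MAD is floored at 0.5 × its recording-wide median, so a
     silent stretch (after a terminal apnea only integrated ECG bumps
     remain) cannot collapse the threshold onto artifacts;
   * threshold crossings define bursts; crossings separated by < 30 ms are
     merged; a crossing starting within 50 ms of the previous burst's end
     is treated as a continuation of that burst and absorbed (an
     unusually long contraction with a ragged decay must not fragment into
     spurious "breaths" — for the same reason a trailing fragment smaller
     than 25 % of its predecessor's peak within 0.2 s is folded back);
   * bursts shorter than 20 ms are dropped;
   * onsets are refined by walking back from the threshold crossing to 5 %
     of the threshold excess (the trailing integration window delays the
     crossing by several ms relative to the burst foot).

   Each burst yields peak amplitude, inspiratory duration (onset→offset of
   the suprathreshold envelope), area under the integrated curve, period
   (onset-to-next-onset; the most robustly detected landmark) and
   instantaneous frequency 1/period (undefined for the last breath).

4. **ECG R-peaks** are detected on the *raw* EMG in a 180–450 Hz band,
   where the sharp R-wave retains energy but the burst carrier does not:
   peaks of the band envelope above median + 14 × MAD with a 30 ms
   refractory. They are used only to time asystole.

## Respiratory event classification

* **Sigh**: peak ≥ 2.0 × the mean peak of the preceding 10 breaths in the
  same sleep/wake state. Earlier sighs are excluded from the baseline so a
  sigh cannot mask the next one.
* **Apnea**: period ≥ 2.5 × the mean period of the preceding 10 same-state
  breaths (sigh periods excluded from the baseline). The event's duration
  is the full long cycle.
* **Post-sigh apnea**: an apnea whose pause (end of the flagged breath's
  burst) begins within 8 s after a sigh's burst end; counted separately and
  excluded from spontaneous apnea counts.
* Ties at the thresholds are inclusive (≥), matching the stated rules.
* With fewer than 10 same-state preceding breaths at least 5 are required
  (mean over those available); otherwise the breath is not classified.
  The trailing window never reaches across a silent gap longer than 60 s
  between consecutive breaths. Both choices fill gaps the verbal rules
  leave open; both are parameters.

**Summaries** over 1–3 min segments of stable breathing (the lowest-CVf
subinterval, stepping every 10 s, excluding movement and detected events;
ties go to the earliest): mean frequency, CVf (SD/mean, ddof = 1),
inspiratory duration, and peak amplitude / burst area normalized to the
animal's pre-seizure mean sigh amplitude (electrode-placement invariant).
Fewer than 10 breaths gives a summary flagged `insufficient`, never a
silent number. Hourly frequency z-scores use the mean and SD (ddof = 1) of
samples in a 6 h pre-seizure baseline, flagging −1 SD and −2 SD.

## Cortical EEG events

* **Seizures** — per 1 s cell of the 1–50 Hz band: cell RMS > 2 × baseline
  RMS *and* 95 % spectral edge frequency > 1.5 × baseline SEF95, where the
  baseline is maintained over the trailing 60 s of non-ictal, non-movement
  seconds (movement artifacts are broadband and would inflate the baseline
  spectral edge). Ictal runs separated by < 5 s merge; events must exceed
  10 s. Edges are then refined to 0.1 s resolution against the amplitude
  criterion. The SEF95 operationalizes the qualitative "frequency
  increase"; both ratios are parameters.
* **PGES** — power = mean squared 0.5–50 Hz signal in 0.02 s bins.
  Baseline: mean μ and SD σ of power over 5 s windows within the 100 s
  preictal period, with windows overlapping previous seizures/PGES
  excluded. Exit threshold: μ − 3σ, floored at 0.25 μ (a preictal window
  spanning sleep-state transitions can have σ comparable to μ; without the
  floor the threshold goes negative and every suppression would end
  instantly). The suppression ends at the first time t after which a
  trailing 2 s power window (clipped at seizure end) exceeds the threshold
  at every position inside `[t, t + 5 s)` — i.e. power re-enters the 3 SD
  band continuously for at least 5 s; the endpoint is then refined to where
  a 0.5 s window last sat at or below the threshold, so the reported end
  tracks the actual rise of power rather than the certification window.
  Duration is 0 when the criterion holds at seizure end. The exit is
  deliberately a *recovery into* the baseline band rather than an
  overshoot above μ + 3σ: with the overshoot reading, power sitting exactly
  at baseline would never end a suppression, contradicting the defining
  case of no suppression at all.
* **PEA onset** — the start of the first seizure beginning a run of ≥ 3
  consecutive interictal gaps < 5 min with no gap ≥ 5 min for the next
  30 min (the stretch after the last seizure counts as a gap). This is a
  deterministic proxy for the "sustained transition to near-continuous
  activity"; the run length and look-ahead are parameters.
* **Staging** — each day is labeled by its seizure count (0, 1, 2–3, 4–5,
  6–10, 11–20; larger counts clip to the top bin), with `early_PEA` the
  2 h after PEA onset (truncated at death) and `late_PEA` the 2 h before
  death. The two PEA windows may overlap; single-label queries resolve in
  favor of `late_PEA`. `day_s` is a parameter so compressed simulations
  can be staged on their own "virtual day".

## Sleep scoring

10 s epochs tile the recording. Priority: epochs at/after PEA onset are
OTH (sleep state is undefined during PEA), then seizure > PGES > movement
mask > spectral rule. Band powers come from a one-segment Welch
periodogram (10 s at 500 Hz gives 0.1 Hz resolution): delta = 0.5–4 Hz,
theta = 4.5–8 Hz. NREM requires delta/theta ≥ 1.5 with epoch RMS ≥ 0.5 ×
the recording median (high amplitude) and a quiescent EMG (epoch median of
the integrated trace ≤ 3 × the recording median); REM/inactive wake
requires theta/delta ≥ 1.2 (REM and inactive wake cannot be separated
without a nuchal EMG lead and are merged); anything else is OTH. The
ratio/amplitude gates are tuning choices, not protocol constants, and are
exposed in the configuration.

## Terminal analysis

For recordings that end in death (no inspiratory bursts in the final
60 s): last breath = final burst onset; last heartbeat = final R-peak
(absent — not false — when no cardiac signal is detectable);
`apnea_before_asystole` = last breath < last heartbeat. EEG collapse is
the first time broadband power stays below 10 % of a ≤ 6 h pre-terminal
baseline for 60 s. The pre-terminal pattern over the final 10 min:
`tonic_burst` if a burst with inspiratory duration > 5 × the record median
is present, else `irregular_with_apneas` if ≥ 2 apneas occurred, else
`declining_rate` if the linear frequency trend slope < −0.002 breaths/s
per s, else `mixed`; the precedence follows how distinctive each signature
is. The thresholds are this package's own.

## The synthetic recording generator

The generator emulates the statistical structure of chronic mouse
telemetry; it is the oracle for every detector and its defaults are the
study conditions used by the validation suite:

* breathing at 4 breaths/s (240 breaths/min) with 3 % period jitter and
  8 % amplitude jitter; inspiratory bursts are 80 ms envelopes (≈16 ms
  sigmoidal attack — rapid motor-unit recruitment — then raised-cosine
  decay) modulating 60–120 Hz band noise whose envelope-weighted rectified
  level is normalized per burst, so programmed amplitudes are realized
  faithfully and variability is what the jitter says it is;
* sighs as 2.5× amplitude breaths; apneas realized by stretching one
  inter-breath interval by the scheduled ratio (default 3×); post-sigh
  apneas by scheduling an apnea within 8 s of a sigh;
* ECG as sharp biphasic spikes (8 ms, derivative-of-Gaussian) at
  10 beats/s, 0.3 × the burst envelope peak — narrow relative to the
  integration window, as in real diaphragm leads;
* EEG as state-dependent band noise — NREM 0.5–4 Hz at RMS 1.0, REM/
  inactive 4.5–8 Hz at RMS 0.5, movement 4.5–30 Hz — cycling through
  300 s NREM / 120 s REM / 60 s movement blocks;
* seizures as an 8 Hz fundamental plus 2nd/3rd harmonics scaled to
  `amp_ratio` (default 3) × the NREM baseline RMS (generalized seizures
  are large in absolute terms, so the > 2× criterion holds in any state),
  with 0.1 s edge tapers;
* PGES as amplitude scaling to 0.2×, followed by a 0.25 s ramp into a 4 s
  recovery burst at 3× with a broadband (4.5–30 Hz) component: postictal
  recovery begins with mixed-frequency activity rather than a pure slow
  wave, which also makes the power re-entry independent of the phase of
  the ongoing delta oscillation — a 0.5–4 Hz signal alone cannot certify
  power recovery faster than its own period;
* terminal events as a scheduled last breath (optionally preceded by a
  1.5 s tonic burst), EEG collapse to 5 % at the terminal apnea, and ECG
  cessation at the scheduled asystole.

Output is a pure function of (config, seed). Ground truth carries every
programmed time. `random_event_config` draws an event schedule at the
study conditions (events ≥ 25 s apart, clear of state-block edges so a
same-state trailing baseline exists, respiratory events off the
seizure/PGES windows). `generate_disease_course` compresses a disease
course: every `day_s` seconds (default 7200) stand for one day, per-stage
seizure counts are Poisson draws at the stage's daily rate scaled to its
virtual days (with a running maximum when the requested rates are
nondecreasing, so realized counts escalate like the rates do), interictal
apnea density grows with the stage's seizure rate, breathing slows and
deepens via a piecewise-linear frequency/amplitude profile, and a PEA
phase (gaps < 5 min) ends in tonic burst → terminal apnea → asystole.
`day_s = 7200` keeps the densest pre-PEA stage (≈15–20 seizures per
virtual day) below the 5 min PEA gap criterion; stronger compression would
make late stages indistinguishable from PEA.

### What passing tests do and do not show

The generator reproduces the *rule-relevant* structure of the recordings:
burst/pause/amplitude arithmetic, band-limited state spectra, event
amplitude ratios, contamination geometry, schedule escalation. It does not
reproduce real EEG nonstationarity, electrode drift, movement artifact
morphology, spike-wave shape, or breathing's continuous behavioral
modulation. Detector recoveries measured here are therefore upper bounds
for real data; the boundary and oracle-equivalence tests (which exercise
the rules themselves) transfer directly.

## Validation design

* Every threshold constant is pinned by a boundary test on constructed
  inputs (e.g. a pause at exactly 2.5× vs 2.49×, a peak at 2.0× vs 1.99×,
  a pause 8.0 s vs 8.25 s after a sigh, 4 s vs 5 s power excursions,
  290 s vs 310 s interictal gaps).
* The apnea/sigh classifiers are checked against an independent quadratic
  trailing-window scan on 100 seeded irregular trains; PGES against an
  exhaustive endpoint scan on 50 seeded traces; PEA against a brute-force
  run scan.
* Event recovery is scored on ten 1 h recordings at the study conditions
  (greedy one-to-one matching: 1 s tolerance for apneas, 0.5 s for sighs,
  temporal IoU ≥ 0.8 for seizures) and terminal ordering on ten death
  scenarios with 5–120 s apnea-to-asystole lags. Sizes were chosen so the
  whole suite runs in a few minutes on one CPU.

## Known limitations

* Expiratory timing, airway patency and airflow are invisible to diaphragm
  EMG; inspiratory-burst metrics are the analysis boundary.
* The seizure detector sees only cortical events; amplitude/SEF criteria
  on one channel cannot classify spike-wave morphology.
* The PGES exit depends on a preictal baseline; when that window spans
  sleep-state transitions the 3 SD band is wide and the floor dominates.
* Group-level inferential statistics are intentionally out of scope; the
  per-recording tables are the artifact's boundary.
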