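# epivent

Analysis of chronic two-channel telemetry — cortical EEG plus raw diaphragm
EMG — from epileptic mice, built for studies of how progressive epilepsy
disrupts breathing and ultimately causes terminal respiratory failure
(the phenomenology underlying SUDEP, sudden unexpected death in epilepsy).
It is aimed at labs running long-term (days-to-weeks) recordings in rodent
epilepsy models who need reproducible, scriptable event detection in place
of interactive chart-software workflows.

## What it computes

From the **diaphragm EMG** (the inspiratory pump muscle; contraction = one
breath):

* 60 Hz zero-phase high-pass, then rectification and integration over a
  36–50 ms trailing window (∫EMG) — wide enough to crush the narrow ECG
  R-waves that contaminate diaphragm leads;
* segmentation of ∫EMG into inspiratory bursts, each with peak amplitude,
  inspiratory duration T_insp, area under the curve, period T_tot
  (onset-to-onset) and instantaneous frequency f = 1/T_tot;
* **apneas**: cycles with T_tot ≥ 2.5 × the mean of the preceding 10 breaths
  in the same sleep/wake state; **sighs**: breaths with peak ≥ 2 × the
  trailing 10-breath mean; apneas starting within 8 s of a sigh are counted
  separately as post-sigh apneas;
* per-segment summaries over 1–3 min of stable breathing: mean f, CVf
  (SD/mean of f), and peak amplitude / burst area normalized within-animal
  to the pre-seizure mean sigh amplitude;
* breathing-frequency z-scores against a 6 h pre-seizure baseline;
* cardiac R-peak times recovered from the *raw* EMG (used only to time
  asystole).

From the **cortical EEG**:

* **seizures**: abrupt rises in amplitude (> 2 × a trailing 60 s baseline
  RMS of the 1–50 Hz band) and frequency (spectral edge ≥ 1.5 × baseline)
  lasting > 10 s;
* **PGES** (postictal generalized EEG suppression): duration measured
  against the mean ± SD of broadband power over the 100 s preictal
  baseline, ending when power re-enters the 3 SD band for at least 5 s;
* **PEA** (persistent epileptiform activity): onset of a sustained run of
  seizures with interictal gaps < 5 min;
* sleep/wake scoring of 10 s epochs (NREM: high-amplitude 0.5–4 Hz;
  REM/inactive wake: moderate 4.5–8 Hz; movement comes in as a mask);
* disease staging by daily seizure count (0, 1, 2–3, 4–5, 6–10, 11–20 per
  day) plus 2 h early/late PEA windows.

From both channels together: **terminal-event ordering** — time of the last
inspiratory burst (terminal apnea), last R-peak (asystole), EEG power
collapse, and the pre-terminal breathing pattern (declining rate, irregular
with apneas, terminal tonic burst, or mixed).

Because chronic telemetry datasets of this kind are rarely shareable, the
package ships a first-class **synthetic recording generator**
(`epivent.simulate`) that produces coupled EEG/EMG with a fully programmed
event schedule — breaths, sighs, apneas, seizures, PGES, PEA, sleep-state
blocks, terminal events — which serves as ground truth for validating every
detector.

## Worked example

```python
from epivent import RecordingAnalysis
from epivent.simulate import random_event_config

sim = random_event_config(1800.0, seed=42, n_apneas=10, n_sighs=10, n_seizures=2)
model = RecordingAnalysis.from_simulation(sim)   # or .from_file("rec.edf")
results = model.fit()
print(results.summary())
```

```
Recording analysis summary
============================================================
duration: 0.50 h   EEG 500 Hz / EMG 1000 Hz
breaths: 7181   mean rate 4.00 bps
sighs: 10   spontaneous apneas: 10   post-sigh apneas: 0
seizures: 2   PGES measured: 2 (mean 20.2 s)
PEA onset: absent
sleep epochs: NREM 120, REM_IW 32, MVM 17, SEIZ 7, PGES 4
------------------------------------------------------------
stage  start_s    end_s  segment_start_s  mean_freq_bps  cv_freq  norm_amp  mean_insp_dur_s  ...
  2-3    0.000 1800.000         1270.000          4.010    0.038     0.414            0.085  ...
```

Reading the output: all 10 programmed apneas and 10 sighs were recovered
with no false positives; both seizures were found and each was followed by
~20 s of measured postictal suppression. The stage row shows baseline
breathing at 4.0 breaths/s with low variability (CVf 0.038), a normalized
amplitude of 0.41 (ordinary breaths sit well below the sigh amplitude used
as the within-animal unit), and an 85 ms inspiratory duration.
`results.save("out/")` writes the full bundle (breaths.csv, events.csv,
seizures.csv, pges.csv, epochs.csv, stages.csv, summary.csv, terminal.json).

The same pipeline is available from the shell:

```bash
epivent simulate --seed 3 --duration 600 --out sim/
epivent report --in sim/recording.edf --out report/
epivent run-all --seed 5 --duration 900 --out out/
```

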