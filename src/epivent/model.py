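"""End-to-end orchestration: a model/results pair over one recording.

:class:`RecordingAnalysis` holds the raw channels plus a :class:`RunConfig`
whose defaults reproduce every detection constant of the protocol (60 Hz
high-pass; 36-50 ms integration; apnea >= 2.5x the trailing 10-breath mean;
sigh >= 2x; 8 s post-sigh window; seizure > 2x baseline for > 10 s; PGES
100 s baseline, 5 s window, 3 SD / >= 5 s exit; PEA gaps < 5 min; 10 s sleep
epochs with 0.5-4 / 4.5-8 Hz bands; 6 h preseizure z-score baseline; 2 h PEA
stage windows).  ``fit()`` runs the full detector chain and returns a
:class:`RecordingResults` carrying breaths, respiratory and cortical events,
sleep epochs, disease stages, per-stage summaries and (for recordings ending
in death) the terminal report, with ``summary()`` and ``save()`` for
reporting.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import eeg as eeg_mod
from . import emg as emg_mod
from . import resp as resp_mod
from . import sleep as sleep_mod
from . import terminal as term_mod
from .errors import EpiventError
from .io import (
    Interval,
    MovementMask,
    TimeSeries,
    read_recording,
    write_events_csv,
)

logger = logging.getLogger("epivent")

__all__ = ["RunConfig", "RecordingAnalysis", "RecordingResults"]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the protocol constants."""

    # EMG conditioning / breath segmentation
    emg_highpass_hz: float = 60.0
    integrate_window_ms: float = 40.0
    breath_k_mad: float = 4.0
    breath_baseline_window_s: float = 5.0
    breath_min_duration_s: float = 0.020
    breath_merge_gap_s: float = 0.030
    breath_refractory_s: float = 0.050

    # respiratory event classification
    apnea_period_ratio: float = 2.5
    sigh_amp_ratio: float = 2.0
    trailing_breaths: int = 10
    min_baseline_breaths: int = 5
    postsigh_window_s: float = 8.0
    max_lookback_s: float = 60.0

    # seizure detection
    seizure_amp_ratio: float = 2.0
    seizure_freq_ratio: float = 1.5
    seizure_min_duration_s: float = 10.0
    seizure_merge_gap_s: float = 5.0
    seizure_baseline_s: float = 60.0

    # PGES
    pges_baseline_s: float = 100.0
    pges_sustain_s: float = 5.0
    pges_n_sd: float = 3.0

    # PEA and staging
    pea_max_gap_s: float = 300.0
    pea_min_run: int = 3
    pea_lookahead_s: float = 1800.0
    stage_day_s: float = 86400.0
    pea_window_s: float = 7200.0

    # sleep scoring
    epoch_s: float = 10.0
    delta_band: tuple = (0.5, 4.0)
    theta_band: tuple = (4.5, 8.0)
    r_nrem: float = 1.5
    r_rem: float = 1.2
    a_nrem: float = 0.5
    m_max_factor: float = 3.0

    # summaries
    segment_length_s: float = 60.0
    zscore_baseline_s: float = 6 * 3600.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise EpiventError(f"unknown config keys: {sorted(unknown)}")
        for k in ("delta_band", "theta_band"):
            if k in data and isinstance(data[k], list):
                data[k] = tuple(data[k])
        return cls(**data)


class RecordingAnalysis:
    """One recording (EEG + raw diaphragm EMG + optional movement mask)."""

    def __init__(
        self,
        eeg: TimeSeries,
        emg: TimeSeries,
        movement: MovementMask | None = None,
        config: RunConfig | None = None,
    ):
        self.eeg = eeg
        self.emg = emg
        self.movement = movement
        self.config = config or RunConfig()

    @classmethod
    def from_file(cls, path, config: RunConfig | None = None) -> "RecordingAnalysis":
        eeg, emg, movement = read_recording(path)
        return cls(eeg, emg, movement, config)

    @classmethod
    def from_simulation(cls, sim_config, seed=None, config: RunConfig | None = None):
        """Build from a :class:`~epivent.simulate.SimConfig`; the ground
        truth is kept on the instance for validation."""
        from .simulate import generate_recording

        eeg, emg, movement, gt = generate_recording(sim_config, seed=seed)
        obj = cls(eeg, emg, movement, config)
        obj.ground_truth = gt
        return obj

    # ------------------------------------------------------------------
    def fit(self) -> "RecordingResults":
        cfg = self.config
        logger.info("conditioning EMG (%.0f Hz high-pass, %.0f ms integration)",
                    cfg.emg_highpass_hz, cfg.integrate_window_ms)
        emg_f = emg_mod.highpass(self.emg, cfg.emg_highpass_hz)
        emg_i = emg_mod.rectify_integrate(emg_f, cfg.integrate_window_ms)
        breaths = emg_mod.segment_breaths(
            emg_i,
            k_mad=cfg.breath_k_mad,
            baseline_window_s=cfg.breath_baseline_window_s,
            min_duration_s=cfg.breath_min_duration_s,
            merge_gap_s=cfg.breath_merge_gap_s,
            refractory_s=cfg.breath_refractory_s,
        )
        logger.info("segmented %d breaths", len(breaths))

        seizures = eeg_mod.detect_seizures(
            self.eeg,
            movement=self.movement,
            amp_ratio=cfg.seizure_amp_ratio,
            freq_ratio=cfg.seizure_freq_ratio,
            min_duration_s=cfg.seizure_min_duration_s,
            merge_gap_s=cfg.seizure_merge_gap_s,
            baseline_s=cfg.seizure_baseline_s,
        )
        logger.info("detected %d seizures", len(seizures))

        power = eeg_mod.power_series(self.eeg)
        pges: list[eeg_mod.PGESEvent] = []
        occupied: list[Interval] = []
        for s in seizures:
            occupied.append(s.interval)
            try:
                g = eeg_mod.measure_pges(
                    self.eeg,
                    s,
                    exclude=list(occupied),
                    baseline_s=cfg.pges_baseline_s,
                    sustain_s=cfg.pges_sustain_s,
                    n_sd=cfg.pges_n_sd,
                    _power=power,
                )
            except EpiventError as exc:
                logger.warning("PGES skipped for seizure at %.1f s: %s", s.start, exc)
                continue
            pges.append(g)
            if g.duration > 0:
                occupied.append(Interval(g.seizure_end, g.seizure_end + g.duration))

        pea_onset = eeg_mod.detect_pea_onset(
            seizures,
            self.eeg.end,
            max_gap_s=cfg.pea_max_gap_s,
            min_run=cfg.pea_min_run,
            lookahead_s=cfg.pea_lookahead_s,
        )

        epochs = sleep_mod.score_epochs(
            self.eeg,
            emg_i,
            movement=self.movement,
            seizures=seizures,
            pges=pges,
            pea_onset=pea_onset,
            epoch_s=cfg.epoch_s,
            delta_band=cfg.delta_band,
            theta_band=cfg.theta_band,
            r_nrem=cfg.r_nrem,
            r_rem=cfg.r_rem,
            a_nrem=cfg.a_nrem,
            m_max_factor=cfg.m_max_factor,
        )

        def state_of(t: float) -> str:
            try:
                return sleep_mod.state_at(epochs, t)
            except EpiventError:
                return sleep_mod.OTH

        sighs = resp_mod.detect_sighs(
            breaths, state_of,
            amp_ratio=cfg.sigh_amp_ratio,
            window=cfg.trailing_breaths,
            min_baseline=cfg.min_baseline_breaths,
            max_lookback_s=cfg.max_lookback_s,
        )
        apneas = resp_mod.detect_apneas(
            breaths, state_of, sighs,
            period_ratio=cfg.apnea_period_ratio,
            postsigh_window_s=cfg.postsigh_window_s,
            window=cfg.trailing_breaths,
            min_baseline=cfg.min_baseline_breaths,
            max_lookback_s=cfg.max_lookback_s,
        )
        logger.info("classified %d sighs, %d apneas", len(sighs), len(apneas))

        is_terminal = bool(breaths) and (self.eeg.end - breaths[-1].onset >= 60.0)
        death_time = self.eeg.end if is_terminal else None
        stages = eeg_mod.stage_recording(
            seizures, pea_onset, death_time,
            day_s=cfg.stage_day_s, pea_window_s=cfg.pea_window_s,
            end_time=self.eeg.end,
        )

        terminal_report = None
        ecg_peaks: list[float] = []
        if is_terminal:
            ecg_peaks = emg_mod.detect_ecg_peaks(self.emg)
            try:
                terminal_report = term_mod.analyze_terminal(
                    breaths, ecg_peaks, self.eeg,
                    apneas=[a for a in apneas if a.kind == "apnea"],
                )
            except EpiventError as exc:
                logger.warning("terminal analysis skipped: %s", exc)

        return RecordingResults(
            model=self,
            breaths=breaths,
            emg_integrated=emg_i,
            seizures=seizures,
            pges=pges,
            pea_onset=pea_onset,
            epochs=epochs,
            sighs=sighs,
            apneas=apneas,
            stages=stages,
            terminal=terminal_report,
            ecg_peaks=ecg_peaks,
        )


class RecordingResults:
    """Fitted results for one recording; see :class:`RecordingAnalysis`."""

    def __init__(self, model, breaths, emg_integrated, seizures, pges, pea_onset,
                 epochs, sighs, apneas, stages, terminal, ecg_peaks):
        self.model = model
        self.config = model.config
        self.breaths = breaths
        self.emg_integrated = emg_integrated
        self.seizures = seizures
        self.pges = pges
        self.pea_onset = pea_onset
        self.epochs = epochs
        self.sighs = sighs
        self.apneas = apneas
        self.stages = stages
        self.terminal = terminal
        self.ecg_peaks = ecg_peaks
        self._baseline_sigh_amp = None

    # -- derived quantities -------------------------------------------------
    @property
    def spontaneous_apneas(self):
        return [a for a in self.apneas if a.kind == "apnea"]

    @property
    def postsigh_apneas(self):
        return [a for a in self.apneas if a.kind == "postsigh_apnea"]

    def baseline_sigh_amp(self) -> float:
        """Mean sigh peak amplitude during the preseizure baseline.

        The baseline window runs from recording start to the first seizure
        (capped at 6 h).  Falls back to twice the mean breath peak in that
        window when it contains no sighs (the within-animal normalization
        then treats a hypothetical 2x-amplitude breath as the unit).
        """
        if self._baseline_sigh_amp is not None:
            return self._baseline_sigh_amp
        end = min(
            (s.start for s in self.seizures),
            default=self.model.eeg.end,
        )
        end = min(end, self.model.eeg.start + self.config.zscore_baseline_s)
        sigh_onsets = {round(s.time, 9) for s in self.sighs if s.time < end}
        peaks = [
            b.peak for b in self.breaths
            if round(b.onset, 9) in sigh_onsets
        ]
        if peaks:
            amp = float(np.mean(peaks))
        else:
            base = [b.peak for b in self.breaths if b.onset < end]
            amp = 2.0 * float(np.mean(base)) if base else 1.0
            logger.warning("no baseline sighs; normalizing to 2x mean breath peak")
        self._baseline_sigh_amp = amp
        return amp

    def _event_intervals(self) -> list[Interval]:
        iv = [s.interval for s in self.seizures]
        iv += [Interval(g.seizure_end, g.seizure_end + g.duration)
               for g in self.pges if g.duration > 0]
        iv += [Interval(a.time, a.time + a.duration) for a in self.apneas]
        iv += [Interval(s.time, s.time + s.duration) for s in self.sighs]
        return iv

    def stage_summaries(self) -> pd.DataFrame:
        """One row per stage window: breathing metrics over the most stable
        segment plus state-specific apnea/sigh rates (events per hour of
        scored NREM and REM/inactive-wake time)."""
        base_amp = self.baseline_sigh_amp()
        events = self._event_intervals()
        rows = []
        for st in self.stages:
            win = Interval(
                max(st.interval.start, self.model.eeg.start),
                min(st.interval.end, self.model.eeg.end),
            )
            row = {"stage": st.label, "start_s": win.start, "end_s": win.end}
            try:
                seg = resp_mod.select_stable_segment(
                    self.breaths, win, self.config.segment_length_s,
                    movement=self.model.movement, events=events,
                )
                summ = resp_mod.segment_summary(self.breaths, seg, base_amp)
            except EpiventError:
                # PEA/terminal windows have no event-free segment: fall back
                # to the lowest-CV segment ignoring event exclusion
                try:
                    seg = resp_mod.select_stable_segment(
                        self.breaths, win, self.config.segment_length_s,
                        movement=self.model.movement, events=(),
                    )
                    summ = resp_mod.segment_summary(self.breaths, seg, base_amp)
                except EpiventError:
                    summ = None
            if summ is not None and not summ.insufficient:
                row.update(
                    segment_start_s=summ.segment.start,
                    mean_freq_bps=summ.mean_freq,
                    cv_freq=summ.cv_freq,
                    norm_amp=summ.norm_amp,
                    mean_insp_dur_s=summ.mean_insp_dur,
                    mean_area_norm=summ.mean_area_norm,
                )
            for state in (sleep_mod.NREM, sleep_mod.REM_IW):
                hours = sum(
                    ep.length for ep in self.epochs
                    if ep.state == state and win.contains(ep.start)
                ) / 3600.0
                n_ap = sum(
                    1 for a in self.spontaneous_apneas
                    if win.contains(a.time) and a.state == state
                )
                n_sg = sum(
                    1 for s in self.sighs
                    if win.contains(s.time) and s.state == state
                )
                row[f"hours_{state}"] = hours
                row[f"apnea_per_h_{state}"] = n_ap / hours if hours > 0 else np.nan
                row[f"sigh_per_h_{state}"] = n_sg / hours if hours > 0 else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def hourly_frequency_zscores(self) -> list[resp_mod.FreqSample] | None:
        """Hourly stable-segment breathing frequency z-scored against the
        first 6 h (preseizure) baseline; None when the recording is too
        short for at least 3 baseline samples."""
        t0, t1 = self.model.eeg.start, self.model.eeg.end
        samples = []
        t = t0
        while t + 3600.0 <= t1 + 1e-9:
            try:
                seg = resp_mod.select_stable_segment(
                    self.breaths, Interval(t, t + 3600.0),
                    self.config.segment_length_s, movement=self.model.movement,
                    events=self._event_intervals(),
                )
                s = resp_mod.segment_summary(
                    self.breaths, seg, self.baseline_sigh_amp()
                )
                if not s.insufficient:
                    samples.append((seg.start, s.mean_freq))
            except EpiventError:
                pass
            t += 3600.0
        baseline = Interval(t0, t0 + self.config.zscore_baseline_s)
        try:
            return resp_mod.frequency_zscore(samples, baseline)
        except EpiventError:
            return None

    # -- tables --------------------------------------------------------------
    def breaths_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(b) for b in self.breaths])

    def events_frame(self) -> pd.DataFrame:
        evs = sorted(self.sighs + self.apneas, key=lambda e: e.time)
        return pd.DataFrame([dataclasses.asdict(e) for e in evs])

    def epochs_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self.epochs])

    def summary(self) -> str:
        """Human-readable run summary."""
        eeg = self.model.eeg
        lines = [
            "Recording analysis summary",
            "=" * 60,
            f"duration: {eeg.duration / 3600.0:.2f} h   "
            f"EEG {eeg.rate:g} Hz / EMG {self.model.emg.rate:g} Hz",
            f"breaths: {len(self.breaths)}"
            + (
                f"   mean rate {np.mean([b.inst_freq for b in self.breaths if b.inst_freq]):.2f} bps"
                if self.breaths else ""
            ),
            f"sighs: {len(self.sighs)}   spontaneous apneas: "
            f"{len(self.spontaneous_apneas)}   post-sigh apneas: {len(self.postsigh_apneas)}",
            f"seizures: {len(self.seizures)}   PGES measured: {len(self.pges)}"
            + (
                f" (mean {np.mean([g.duration for g in self.pges]):.1f} s)"
                if self.pges else ""
            ),
            f"PEA onset: {'%.1f s' % self.pea_onset if self.pea_onset is not None else 'absent'}",
        ]
        counts = pd.Series([e.state for e in self.epochs]).value_counts()
        lines.append(
            "sleep epochs: "
            + ", ".join(f"{k} {v}" for k, v in counts.items())
        )
        df = self.stage_summaries()
        if len(df):
            lines.append("-" * 60)
            lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        if self.terminal is not None:
            t = self.terminal
            lines.append("-" * 60)
            lines.append(
                f"terminal: last breath {t.last_breath:.2f} s, last ECG "
                f"{'%.2f s' % t.last_ecg if t.last_ecg is not None else 'absent'}, "
                f"apnea before asystole: {t.apnea_before_asystole}, pattern: {t.pattern}"
            )
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write the full report bundle (CSV tables + terminal.json + log)."""
        os.makedirs(out_dir, exist_ok=True)
        self.breaths_frame().to_csv(os.path.join(out_dir, "breaths.csv"), index=False)
        write_events_csv(
            sorted(self.sighs + self.apneas, key=lambda e: e.time),
            os.path.join(out_dir, "events.csv"),
        )
        write_events_csv(self.seizures, os.path.join(out_dir, "seizures.csv"))
        write_events_csv(self.pges, os.path.join(out_dir, "pges.csv"))
        self.epochs_frame().to_csv(os.path.join(out_dir, "epochs.csv"), index=False)
        pd.DataFrame(
            [{"stage": s.label, "start_s": s.interval.start, "end_s": s.interval.end}
             for s in self.stages]
        ).to_csv(os.path.join(out_dir, "stages.csv"), index=False)
        self.stage_summaries().to_csv(os.path.join(out_dir, "summary.csv"), index=False)
        if self.terminal is not None:
            self.terminal.to_json(os.path.join(out_dir, "terminal.json"))
        with open(os.path.join(out_dir, "run.log"), "w") as fh:
            fh.write(self.summary() + "\n")
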