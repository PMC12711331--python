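"""Cortical EEG event detection: seizures, postictal suppression, PEA, staging.

Seizures are abrupt increases in both frequency and amplitude (>2x baseline)
lasting longer than 10 s.  Amplitude is the per-second RMS of the 1-50 Hz
band against a trailing 60 s baseline that excludes previously detected
events; the frequency increase is operationalized as the 95% spectral edge
frequency (SEF95) elevated >= 1.5x over its trailing baseline.

Postictal generalized EEG suppression (PGES) is measured against a 100 s
preictal power baseline: the event ends when broadband power recovers into
the baseline's 3-SD band and stays there for at least 5 s.

Persistent epileptiform activity (PEA) is a sustained run of electrographic
seizures with interictal gaps shorter than 5 min; disease stages bin each
day of recording by its seizure count, with 2 h windows around PEA onset and
death appended.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError
from .io import Interval, TimeSeries, register_event_type

__all__ = [
    "SeizureEvent",
    "PGESEvent",
    "StageWindow",
    "detect_seizures",
    "measure_pges",
    "detect_pea_onset",
    "stage_recording",
    "stage_label_at",
]


@register_event_type("seizure")
@dataclass
class SeizureEvent:
    """A detected electrographic seizure (duration > 10 s, amplitude > 2x)."""

    start: float
    end: float
    duration: float
    peak_ratio: float

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end)


@register_event_type("pges")
@dataclass
class PGESEvent:
    """Postictal generalized EEG suppression following one seizure."""

    seizure_end: float
    duration: float


@dataclass
class StageWindow:
    """One disease-progression stage (daily seizure-count bin or PEA window)."""

    label: str
    interval: Interval


def _band_signal(eeg: TimeSeries, lo: float, hi: float) -> np.ndarray:
    hi = min(hi, 0.45 * eeg.rate)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=eeg.rate, output="sos")
    return sps.sosfiltfilt(sos, eeg.samples)


def _per_second(eeg_rate: float, x: np.ndarray) -> np.ndarray:
    """Reshape a sample array into whole seconds (trailing partial dropped)."""
    spr = int(round(eeg_rate))
    n_sec = x.size // spr
    return x[: n_sec * spr].reshape(n_sec, spr)


def _sef95(seconds: np.ndarray, rate: float, lo: float = 1.0, hi: float = 50.0) -> np.ndarray:
    """95% spectral edge frequency per 1 s window (within the lo-hi band)."""
    freqs = np.fft.rfftfreq(seconds.shape[1], d=1.0 / rate)
    spec = np.abs(np.fft.rfft(seconds, axis=1)) ** 2
    sel = (freqs >= lo) & (freqs <= hi)
    spec = spec[:, sel]
    freqs = freqs[sel]
    c = np.cumsum(spec, axis=1)
    tot = c[:, -1:]
    tot[tot <= 0] = 1.0
    idx = np.argmax(c >= 0.95 * tot, axis=1)
    return freqs[idx]


def detect_seizures(
    eeg: TimeSeries,
    movement=None,
    amp_ratio: float = 2.0,
    freq_ratio: float = 1.5,
    min_duration_s: float = 10.0,
    merge_gap_s: float = 5.0,
    baseline_s: float = 60.0,
    band: tuple[float, float] = (1.0, 50.0),
) -> list[SeizureEvent]:
    """Detect seizures on a 1 s feature grid.

    A second is ictal when its band RMS exceeds ``amp_ratio`` x the trailing
    baseline RMS *and* its SEF95 exceeds ``freq_ratio`` x the trailing
    baseline SEF95; the baseline is maintained over the last ``baseline_s``
    of non-ictal seconds.  Ictal runs separated by less than ``merge_gap_s``
    are merged before the ``min_duration_s`` test.
    """
    if eeg.duration <= baseline_s:
        raise InsufficientDataError(
            f"EEG shorter than the {baseline_s} s seizure baseline window"
        )
    bp = _band_signal(eeg, *band)
    secs = _per_second(eeg.rate, bp)
    r = np.sqrt((secs**2).mean(axis=1))
    sef = _sef95(secs, eeg.rate, band[0], band[1])
    n = r.size

    win = int(round(baseline_s))
    moving = np.zeros(n, dtype=bool)
    if movement is not None:
        for iv in movement.intervals:
            j0 = max(0, int(math.floor(iv.start - eeg.start)))
            j1 = min(n, int(math.ceil(iv.end - eeg.start)))
            moving[j0:j1] = True
    flags = np.zeros(n, dtype=bool)
    base_r: list[float] = []
    base_sef: list[float] = []
    for j in range(n):
        if len(base_r) >= 5:
            br = math.sqrt(float(np.mean(np.square(base_r))))
            bs = float(np.median(base_sef))
            flags[j] = (r[j] > amp_ratio * br) and (sef[j] > freq_ratio * bs)
        if not flags[j] and not moving[j]:
            base_r.append(float(r[j]))
            base_sef.append(float(sef[j]))
            if len(base_r) > win:
                base_r.pop(0)
                base_sef.pop(0)

    # runs of flagged seconds -> merge -> duration filter
    runs: list[list[float]] = []
    j = 0
    while j < n:
        if flags[j]:
            k = j
            while k + 1 < n and flags[k + 1]:
                k += 1
            runs.append([float(j), float(k + 1)])
            j = k + 1
        else:
            j += 1
    merged: list[list[float]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # fine envelope (0.1 s RMS) for sub-second edge refinement
    fine_bin = 0.1
    spb = max(1, int(round(fine_bin * eeg.rate)))
    nfb = bp.size // spb
    r_fine = np.sqrt((bp[: nfb * spb] ** 2).reshape(nfb, spb).mean(axis=1))

    def _refine(coarse_t: float, baseline: float, leading: bool) -> float:
        """Move a coarse (1 s grid) edge to the first/last fine bin whose RMS
        clears the amplitude criterion within +-1.5 s of the coarse edge."""
        thr_f = amp_ratio * baseline
        lo = max(0, int((coarse_t - 1.5) / fine_bin))
        hi = min(nfb, int((coarse_t + 1.5) / fine_bin))
        idx = range(lo, hi) if leading else range(hi - 1, lo - 1, -1)
        for k in idx:
            if r_fine[k] > thr_f:
                return (k if leading else k + 1) * fine_bin
        return coarse_t

    events = []
    for s, e in merged:
        if e - s <= min_duration_s:
            continue
        i0, i1 = int(s), int(e)
        peak_ratio = float(r[i0:i1].max()) / max(
            float(np.sqrt(np.mean(np.square(base_r)))) if base_r else 1e-12, 1e-12
        )
        # ratio against the baseline immediately preceding the event
        pre = r[max(0, i0 - win): i0]
        pre = pre[pre < r[i0:i1].max() / amp_ratio] if pre.size else pre
        baseline = math.sqrt(float(np.mean(pre**2))) if pre.size else float("nan")
        if pre.size:
            peak_ratio = float(r[i0:i1].max() / baseline)
            s = _refine(s, baseline, leading=True)
            e = _refine(e, baseline, leading=False)
        events.append(
            SeizureEvent(
                start=eeg.start + s,
                end=eeg.start + e,
                duration=e - s,
                peak_ratio=peak_ratio,
            )
        )
    return events


def power_series(
    eeg: TimeSeries, bin_s: float = 0.02, band: tuple[float, float] = (0.5, 50.0)
) -> tuple[np.ndarray, float]:
    """Broadband power (mean squared band signal) binned at ``bin_s``.

    Returns ``(power_bins, bin_s)``; bin ``k`` covers
    ``[eeg.start + k*bin_s, eeg.start + (k+1)*bin_s)``.
    """
    bp = _band_signal(eeg, *band)
    spb = max(1, int(round(bin_s * eeg.rate)))
    nb = bp.size // spb
    p = (bp[: nb * spb] ** 2).reshape(nb, spb).mean(axis=1)
    return p, spb / eeg.rate


def measure_pges(
    eeg: TimeSeries,
    seizure: SeizureEvent,
    exclude: Sequence[Interval] = (),
    baseline_s: float = 100.0,
    sustain_s: float = 5.0,
    n_sd: float = 3.0,
    power_window_s: float = 2.0,
    floor_frac: float = 0.25,
    _power: tuple[np.ndarray, float] | None = None,
) -> PGESEvent:
    """Measure postictal suppression duration after one seizure.

    Baseline: mean and SD of broadband power over ``sustain_s``-long windows
    within the 100 s preictal period (intervals in ``exclude`` — prior
    seizures/PGES — are dropped from the baseline); the exit threshold is
    ``mean - n_sd * SD``.  From seizure end, the exceedance signal is the
    power in a trailing ``power_window_s`` window (clipped at seizure end so
    ictal power never leaks in); the suppression ends at the first time
    ``t`` after which the exceedance holds throughout ``[t, t + sustain_s)``
    (evaluated at every trailing-window position inside that span), i.e.
    power must sit above the 3-SD band continuously for at least
    ``sustain_s``.  Duration 0 when the criterion holds at seizure end; if
    power never recovers the suppression is scored to the end of the record.
    """
    if seizure.start - eeg.start < baseline_s:
        raise InsufficientDataError(
            f"need {baseline_s} s of preictal EEG before the seizure at {seizure.start} s"
        )
    p, dt = power_series(eeg) if _power is None else _power
    nb = p.size

    def bin_of(t: float) -> int:
        return min(nb - 1, max(0, int((t - eeg.start) / dt)))

    # --- baseline stats over sustain_s windows of the preictal 100 s -------
    b0, b1 = seizure.start - baseline_s, seizure.start
    wbins = max(1, int(round(sustain_s / dt)))
    means = []
    k = bin_of(b0)
    k_end = bin_of(b1)
    while k + wbins <= k_end:
        t_lo = eeg.start + k * dt
        t_hi = t_lo + sustain_s
        if not any(iv.overlaps(Interval(t_lo, t_hi)) for iv in exclude):
            means.append(p[k: k + wbins].mean())
        k += wbins
    if len(means) < 3:
        raise InsufficientDataError(
            "fewer than 3 clean baseline windows in the preictal period"
        )
    mu = float(np.mean(means))
    sd = float(np.std(means, ddof=1))
    # preictal baselines spanning sleep-state transitions can have a power SD
    # comparable to the mean; floor the exit threshold so the criterion stays
    # meaningful (a negative threshold would end every suppression instantly)
    thr = max(mu - n_sd * sd, floor_frac * mu)

    # --- trailing-window exceedance from seizure end -----------------------
    wsm = max(1, int(round(power_window_s / dt)))
    k0 = bin_of(seizure.end)
    csum = np.concatenate(([0.0], np.cumsum(p[k0:])))
    m = csum.size - 1  # number of post-seizure bins
    idx = np.arange(1, m + 1)
    lo = np.maximum(0, idx - wsm)  # clip the trailing window at seizure end
    ok = (csum[idx] - csum[lo]) / (idx - lo) > thr
    # sustained exceedance: every trailing-window position inside a span of
    # sustain_s must exceed -> run of (sustain_s - power_window_s) positions
    # beyond the first (the first window already certifies its own extent)
    need = max(1, int(round((sustain_s - power_window_s) / dt)) + 1)
    run = 0
    start_of_run = None
    for i, v in enumerate(ok):
        run = run + 1 if v else 0
        if run >= need:
            start_of_run = i - need + 1
            break
    if start_of_run is None:
        return PGESEvent(seizure_end=seizure.end, duration=m * dt)
    if start_of_run == 0:
        return PGESEvent(seizure_end=seizure.end, duration=0.0)
    # the trailing window certifies exceedance somewhere inside its extent;
    # refine the endpoint to where short-window power last sat at/below the
    # threshold, so the reported end tracks the actual rise of power
    wf = max(1, int(round(0.5 / dt)))
    k_lo = max(0, start_of_run - wsm)
    k_star = start_of_run
    for k in range(start_of_run, k_lo - 1, -1):
        lo2 = max(0, k - wf)
        if k == lo2:
            break
        if (csum[k] - csum[lo2]) / (k - lo2) <= thr:
            k_star = k
            break
    return PGESEvent(seizure_end=seizure.end, duration=k_star * dt)


def detect_pea_onset(
    seizures: Sequence[SeizureEvent],
    eeg_end: float,
    max_gap_s: float = 300.0,
    min_run: int = 3,
    lookahead_s: float = 1800.0,
) -> float | None:
    """Onset of persistent epileptiform activity, or None.

    PEA begins at the first seizure starting a run of at least ``min_run``
    consecutive interictal gaps shorter than ``max_gap_s``, with no gap of
    ``max_gap_s`` or more for ``lookahead_s`` after that seizure's start (the
    sustained-transition proxy).  The stretch from the last seizure's end to
    ``min(eeg_end, start + lookahead_s)`` counts as a gap.
    """
    seiz = sorted(seizures, key=lambda s: s.start)
    n = len(seiz)
    for i in range(n):
        t0 = seiz[i].start
        horizon = min(eeg_end, t0 + lookahead_s)
        gaps = []
        k = i
        while k + 1 < n and seiz[k].end <= horizon:
            gaps.append(seiz[k + 1].start - seiz[k].end)
            k += 1
        if k == n - 1 and seiz[k].end < horizon:
            gaps.append(horizon - seiz[k].end)
        if len(gaps) >= min_run and all(g < max_gap_s for g in gaps[:min_run]) and all(
            g < max_gap_s for g in gaps
        ):
            return t0
    return None


_BINS = [(0, 0, "0"), (1, 1, "1"), (2, 3, "2-3"), (4, 5, "4-5"), (6, 10, "6-10"), (11, 10**9, "11-20")]


def _daily_label(count: int) -> str:
    for lo, hi, lab in _BINS:
        if lo <= count <= hi:
            return lab
    return "11-20"


def stage_recording(
    seizures: Sequence[SeizureEvent],
    pea_onset: float | None,
    death_time: float | None,
    t0: float = 0.0,
    day_s: float = 86400.0,
    pea_window_s: float = 7200.0,
    end_time: float | None = None,
) -> list[StageWindow]:
    """Assign disease-progression stage windows.

    Each day (``day_s``-long window from ``t0``) before PEA onset is labeled
    by its seizure-count bin; ``early_PEA`` covers the 2 h after PEA onset
    (truncated at death) and ``late_PEA`` the 2 h before death.  The two PEA
    windows may overlap; :func:`stage_label_at` resolves overlaps in favor of
    ``late_PEA``.  For recordings without PEA or death, daily bins run to
    ``end_time``.
    """
    horizon = pea_onset
    if horizon is None:
        horizon = death_time if death_time is not None else end_time
    out: list[StageWindow] = []
    if horizon is not None and horizon > t0:
        n_days = int(math.ceil((horizon - t0) / day_s))
        for d in range(n_days):
            iv = Interval(t0 + d * day_s, min(t0 + (d + 1) * day_s, horizon))
            cnt = sum(1 for s in seizures if iv.start <= s.start < iv.end)
            out.append(StageWindow(_daily_label(cnt), iv))
    if pea_onset is not None:
        e_end = pea_onset + pea_window_s
        if death_time is not None:
            e_end = min(e_end, death_time)
        if e_end > pea_onset:
            out.append(StageWindow("early_PEA", Interval(pea_onset, e_end)))
    if death_time is not None:
        l_start = death_time - pea_window_s
        if pea_onset is not None:
            l_start = max(l_start, pea_onset)
        if death_time > l_start:
            out.append(StageWindow("late_PEA", Interval(l_start, death_time)))
    return out


def stage_label_at(stages: Sequence[StageWindow], t: float) -> str | None:
    """Stage label at time ``t``; late_PEA > early_PEA > daily bins."""
    hit = [s for s in stages if s.interval.contains(t)]
    if not hit:
        return None
    for lab in ("late_PEA", "early_PEA"):
        for s in hit:
            if s.label == lab:
                return lab
    return hit[0].label
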