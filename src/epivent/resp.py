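"""Apnea / sigh classification and normalized respiratory summary metrics.

Classification follows the trailing-window rules used for manual curation of
chronic diaphragm EMG:

* **sigh** — a breath whose peak amplitude is at least 2x the mean peak of
  the preceding 10 breaths *within the same sleep/wake state* (earlier sighs
  are excluded from the baseline so one sigh cannot mask the next);
* **apnea** — a respiratory cycle whose length (period) is >= 2.5x the mean
  period of the preceding 10 same-state breaths (sigh periods excluded from
  the baseline);
* **post-sigh apnea** — an apnea whose pause starts within 8 s after a sigh;
  counted separately and excluded from spontaneous apnea counts.

With fewer than 10 same-state preceding breaths, at least 5 are required and
the mean is taken over those available; otherwise the breath is not
classified.  The trailing window never reaches across a silent gap longer
than 60 s.

Summary metrics over 1-3 min stable segments: mean breathing frequency, its
coefficient of variation (CVf), inspiratory duration, and peak amplitude /
burst area normalized within-animal to the preseizure mean sigh amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .emg import BreathRecord
from .errors import InsufficientDataError, ParameterError, SegmentError
from .io import Interval, MovementMask, register_event_type

__all__ = [
    "RespEvent",
    "BreathingSummary",
    "FreqSample",
    "detect_sighs",
    "detect_apneas",
    "segment_summary",
    "frequency_zscore",
    "select_stable_segment",
]


@register_event_type("resp")
@dataclass
class RespEvent:
    """A classified respiratory event.

    ``kind`` is ``apnea``, ``sigh`` or ``postsigh_apnea``; ``time`` is the
    onset of the breath concerned; ``duration`` is the long period for
    apneas and the inspiratory duration for sighs; ``ratio`` is the trigger
    ratio against the trailing-window mean.
    """

    kind: str
    time: float
    duration: float
    ratio: float
    state: str = ""


@dataclass
class BreathingSummary:
    """Respiratory metrics over one analysis segment."""

    segment: Interval
    n_breaths: int
    mean_freq: float
    cv_freq: float
    norm_amp: float
    mean_insp_dur: float
    mean_area_norm: float
    insufficient: bool = False


@dataclass
class FreqSample:
    """One breathing-frequency sample with its baseline z-score."""

    time: float
    freq: float
    z: float
    below_1sd: bool
    below_2sd: bool


StateSource = Callable[[float], str] | Sequence[str]


def _breath_states(breaths: Sequence[BreathRecord], states: StateSource) -> list[str]:
    if callable(states):
        return [states(b.onset) for b in breaths]
    states = list(states)
    if len(states) != len(breaths):
        raise ParameterError(
            f"{len(states)} state labels for {len(breaths)} breaths"
        )
    return [str(s) for s in states]


def _trailing(
    breaths: Sequence[BreathRecord],
    labels: Sequence[str],
    i: int,
    skip: Callable[[int], bool],
    window: int,
    max_lookback_s: float,
) -> list[int]:
    """Indices of up to ``window`` preceding same-state breaths, most recent
    first, never reaching back across a silent gap > ``max_lookback_s``."""
    out: list[int] = []
    t_edge = breaths[i].onset
    for j in range(i - 1, -1, -1):
        if t_edge - breaths[j].offset > max_lookback_s:
            break
        t_edge = breaths[j].onset
        if labels[j] != labels[i] or skip(j):
            continue
        out.append(j)
        if len(out) == window:
            break
    return out


def detect_sighs(
    breaths: Sequence[BreathRecord],
    states: StateSource,
    amp_ratio: float = 2.0,
    window: int = 10,
    min_baseline: int = 5,
    max_lookback_s: float = 60.0,
) -> list[RespEvent]:
    """Flag sighs: peak >= ``amp_ratio`` x trailing same-state mean peak."""
    labels = _breath_states(breaths, states)
    is_sigh = [False] * len(breaths)
    events: list[RespEvent] = []
    for i, b in enumerate(breaths):
        idx = _trailing(breaths, labels, i, lambda j: is_sigh[j], window, max_lookback_s)
        if len(idx) < min_baseline:
            continue
        mean_peak = float(np.mean([breaths[j].peak for j in idx]))
        if mean_peak <= 0:
            continue
        if b.peak >= amp_ratio * mean_peak:
            is_sigh[i] = True
            events.append(
                RespEvent(
                    kind="sigh",
                    time=b.onset,
                    duration=b.insp_duration,
                    ratio=b.peak / mean_peak,
                    state=labels[i],
                )
            )
    return events


def detect_apneas(
    breaths: Sequence[BreathRecord],
    states: StateSource,
    sighs: Sequence[RespEvent],
    period_ratio: float = 2.5,
    postsigh_window_s: float = 8.0,
    window: int = 10,
    min_baseline: int = 5,
    max_lookback_s: float = 60.0,
) -> list[RespEvent]:
    """Flag apneas: period >= ``period_ratio`` x trailing same-state mean.

    Requires ``sighs`` (from :func:`detect_sighs`): sigh periods are excluded
    from the trailing baseline, and an apnea whose pause begins within
    ``postsigh_window_s`` after a sigh's burst end is re-labeled
    ``postsigh_apnea``.
    """
    labels = _breath_states(breaths, states)
    sigh_onsets = {round(s.time, 9) for s in sighs}
    sigh_ends = [s.time + s.duration for s in sighs]
    is_sigh = [round(b.onset, 9) in sigh_onsets for b in breaths]
    events: list[RespEvent] = []
    for i, b in enumerate(breaths):
        if b.period is None:
            continue
        idx = _trailing(
            breaths,
            labels,
            i,
            lambda j: is_sigh[j] or breaths[j].period is None,
            window,
            max_lookback_s,
        )
        if len(idx) < min_baseline:
            continue
        mean_period = float(np.mean([breaths[j].period for j in idx]))
        if mean_period <= 0:
            continue
        if b.period >= period_ratio * mean_period:
            pause_start = b.offset
            postsigh = any(
                0.0 <= pause_start - se <= postsigh_window_s for se in sigh_ends
            )
            events.append(
                RespEvent(
                    kind="postsigh_apnea" if postsigh else "apnea",
                    time=b.onset,
                    duration=b.period,
                    ratio=b.period / mean_period,
                    state=labels[i],
                )
            )
    return events


def segment_summary(
    breaths: Sequence[BreathRecord],
    segment: Interval,
    baseline_sigh_amp: float,
    min_breaths: int = 10,
    allow_any_length: bool = False,
) -> BreathingSummary:
    """Respiratory metrics over one segment, amplitude-normalized.

    ``baseline_sigh_amp`` is the animal's mean preseizure sigh peak; peak
    amplitude and burst area are divided by it so recordings with different
    electrode placements are comparable.  Segment length must be 60-180 s
    unless ``allow_any_length``.  Fewer than ``min_breaths`` breaths gives a
    summary flagged ``insufficient`` with NaN metrics.
    """
    if not allow_any_length and not (60.0 <= segment.length <= 180.0):
        raise ParameterError(
            f"segment length {segment.length:.1f} s outside [60, 180] s"
        )
    if baseline_sigh_amp <= 0:
        raise ParameterError("baseline_sigh_amp must be > 0")
    sel = [b for b in breaths if segment.contains(b.onset)]
    if len(sel) < min_breaths:
        nan = float("nan")
        return BreathingSummary(segment, len(sel), nan, nan, nan, nan, nan, True)
    freqs = np.array([b.inst_freq for b in sel if b.inst_freq is not None])
    mean_freq = float(freqs.mean())
    cv = float(freqs.std(ddof=1) / mean_freq) if freqs.size > 1 and mean_freq > 0 else 0.0
    return BreathingSummary(
        segment=segment,
        n_breaths=len(sel),
        mean_freq=mean_freq,
        cv_freq=cv,
        norm_amp=float(np.mean([b.peak for b in sel])) / baseline_sigh_amp,
        mean_insp_dur=float(np.mean([b.insp_duration for b in sel])),
        mean_area_norm=float(np.mean([b.area for b in sel])) / baseline_sigh_amp,
    )


def frequency_zscore(
    samples: Sequence[tuple[float, float]],
    baseline: Interval,
) -> list[FreqSample]:
    """Z-score breathing-frequency samples against a preseizure baseline.

    ``samples`` are ``(time, breaths/s)`` pairs (typically one per hour);
    the baseline mean and SD come from the samples inside ``baseline``
    (at least 3 required).  Samples at or below -1 SD / -2 SD are flagged.
    """
    base = [f for t, f in samples if baseline.contains(t)]
    if len(base) < 3:
        raise InsufficientDataError(
            f"baseline holds {len(base)} samples; need at least 3"
        )
    mu = float(np.mean(base))
    sd = float(np.std(base, ddof=1))
    if sd == 0:
        raise ParameterError("baseline frequency SD is zero; z-scores undefined")
    out = []
    for t, f in samples:
        z = (f - mu) / sd
        out.append(FreqSample(t, f, z, z <= -1.0, z <= -2.0))
    return out


def select_stable_segment(
    breaths: Sequence[BreathRecord],
    window: Interval,
    length: float = 60.0,
    movement: MovementMask | None = None,
    events: Sequence[Interval] = (),
    step_s: float = 10.0,
    min_breaths: int = 10,
) -> Interval:
    """The ``length``-s subinterval of ``window`` with the lowest CVf.

    Candidate segments step through the window every ``step_s``; segments
    overlapping movement or any interval in ``events`` are excluded, as are
    segments with fewer than ``min_breaths`` breaths.  Ties go to the
    earliest candidate.  Raises :class:`SegmentError` when nothing is
    eligible.
    """
    if not (60.0 <= length <= 180.0):
        raise ParameterError(f"segment length {length} s outside [60, 180] s")
    if window.length < length:
        raise ParameterError("window shorter than the requested segment")
    onsets = np.array([b.onset for b in breaths])
    freqs = np.array([b.inst_freq if b.inst_freq is not None else np.nan for b in breaths])
    best: tuple[float, float] | None = None  # (cv, start)
    t = window.start
    while t + length <= window.end + 1e-9:
        seg = Interval(t, t + length)
        t += step_s
        if movement is not None and movement.overlaps(seg):
            continue
        if any(seg.overlaps(iv) for iv in events):
            continue
        sel = (onsets >= seg.start) & (onsets < seg.end)
        f = freqs[sel]
        f = f[~np.isnan(f)]
        if sel.sum() < min_breaths or f.size < 2:
            continue
        m = f.mean()
        if m <= 0:
            continue
        cv = float(f.std(ddof=1) / m)
        if best is None or cv < best[0] - 1e-12:
            best = (cv, seg.start)
    if best is None:
        raise SegmentError(
            f"no eligible {length:.0f} s segment in [{window.start}, {window.end}) s"
        )
    return Interval(best[1], best[1] + length)
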