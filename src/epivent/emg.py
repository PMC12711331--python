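"""Diaphragm EMG conditioning and breath segmentation.

The processing chain mirrors standard chronic diaphragm-EMG practice:

1. zero-phase high-pass at 60 Hz (removes motion/baseline drift and mains-band
   slow components while keeping burst timing unbiased),
2. rectification and integration — a trailing moving average of the absolute
   signal over a 36-50 ms window, which suppresses the narrow ECG artifacts
   that contaminate diaphragm leads while preserving the ~80 ms inspiratory
   burst envelope,
3. burst segmentation on the integrated trace, yielding one
   :class:`BreathRecord` per inspiratory burst with peak amplitude,
   inspiratory duration, area under the curve, and instantaneous frequency.

The raw (unintegrated) trace additionally carries the cardiac R-peaks; they
are detected separately (:func:`detect_ecg_peaks`) purely to time asystole in
terminal recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .io import TimeSeries, register_event_type

__all__ = [
    "BreathRecord",
    "highpass",
    "rectify_integrate",
    "segment_breaths",
    "detect_ecg_peaks",
]


@register_event_type("breath")
@dataclass
class BreathRecord:
    """One inspiratory burst measured on the rectified-integrated trace.

    ``period`` and ``inst_freq`` are onset-to-next-onset and are ``None`` for
    the final breath of a record.
    """

    onset: float
    offset: float
    peak: float
    insp_duration: float
    area: float
    period: float | None = None
    inst_freq: float | None = None


def highpass(ts: TimeSeries, cutoff_hz: float = 60.0, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth high-pass filter.

    Requires ``rate > 2 * cutoff_hz``; output has the same length and rate.
    """
    if ts.rate <= 2 * cutoff_hz:
        raise ParameterError(
            f"rate {ts.rate} Hz too low for a {cutoff_hz} Hz high-pass (need > {2 * cutoff_hz})"
        )
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=ts.rate, output="sos")
    out = sps.sosfiltfilt(sos, ts.samples) if ts.n else ts.samples.copy()
    return ts.copy_with(out)


def rectify_integrate(
    ts: TimeSeries, window_ms: float = 40.0, allow_any_window: bool = False
) -> TimeSeries:
    """Rectify and integrate: trailing moving average of ``|x|``.

    ``output[i]`` is the mean of ``|input|`` over the trailing ``window_ms``
    (partial windows at the start average over the available samples).  The
    window must lie in [36, 50] ms unless ``allow_any_window`` is set; windows
    in that range are wide relative to <=10 ms ECG spikes, which is what makes
    the integrated trace a breath envelope rather than a cardiac one.
    """
    if not allow_any_window and not (36.0 <= window_ms <= 50.0):
        raise ParameterError(
            f"integration window {window_ms} ms outside [36, 50] ms "
            "(pass allow_any_window=True to override)"
        )
    w = max(1, int(round(window_ms * 1e-3 * ts.rate)))
    if ts.n == 0:
        return ts.copy_with(ts.samples.copy())
    a = np.abs(ts.samples)
    c = np.concatenate(([0.0], np.cumsum(a)))
    idx = np.arange(1, ts.n + 1)
    lo = np.maximum(0, idx - w)
    out = (c[idx] - c[lo]) / (idx - lo)
    return ts.copy_with(out)


def _rolling_baseline(x: np.ndarray, rate: float, window_s: float = 5.0,
                      step_s: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Rolling median and MAD of ``x`` on a coarse grid, interpolated back.

    Centered ``window_s`` windows evaluated every ``step_s``; robust to slow
    drift yet cheap on hour-long traces.
    """
    n = x.size
    w = max(1, int(round(window_s * rate)))
    step = max(1, int(round(step_s * rate)))
    centers = np.arange(0, n, step)
    med = np.empty(centers.size)
    mad = np.empty(centers.size)
    for j, c in enumerate(centers):
        lo = max(0, c - w // 2)
        seg = x[lo: min(n, c + w // 2 + 1)]
        m = np.median(seg)
        med[j] = m
        mad[j] = np.median(np.abs(seg - m))
    i = np.arange(n)
    return np.interp(i, centers, med), np.interp(i, centers, mad)


def segment_breaths(
    integrated: TimeSeries,
    k_mad: float = 4.0,
    baseline_window_s: float = 5.0,
    min_duration_s: float = 0.020,
    merge_gap_s: float = 0.030,
    refractory_s: float = 0.050,
    mad_floor_frac: float = 0.5,
    tail_merge_gap_s: float = 0.2,
    tail_merge_ratio: float = 0.25,
) -> list[BreathRecord]:
    """Segment the rectified-integrated trace into inspiratory bursts.

    The detection threshold is a rolling baseline (median over
    ``baseline_window_s``) plus ``k_mad`` x MAD, so slow drift in tonic EMG
    level does not shift burst boundaries.  Onset/offset are the threshold
    crossings; bursts separated by less than ``merge_gap_s`` are merged,
    bursts shorter than ``min_duration_s`` are dropped, and a burst starting
    within ``refractory_s`` of the previous offset is suppressed.  The local
    MAD is floored at ``mad_floor_frac`` x its recording-wide median so that
    silent stretches (e.g. after a terminal apnea, where only integrated ECG
    bumps remain) do not let the threshold collapse onto artifacts.  The
    ragged decay tail of an unusually long burst (a terminal tonic
    contraction) can ripple across the threshold; a trailing fragment much
    smaller than its predecessor (``tail_merge_ratio``) starting within
    ``tail_merge_gap_s`` is folded back into it.

    Returns records sorted by onset; empty list for a flat trace.
    """
    x = integrated.samples
    n = x.size
    if n == 0:
        return []
    if np.ptp(x) <= 1e-12 * max(1.0, float(np.abs(x).max())):
        return []  # flat trace
    med, mad = _rolling_baseline(x, integrated.rate, baseline_window_s)
    mad = np.maximum(mad, mad_floor_frac * float(np.median(mad)))
    thr = med + k_mad * mad
    above = x > thr
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(n)

    rate = integrated.rate
    merge_gap = int(round(merge_gap_s * rate))
    min_dur = int(round(min_duration_s * rate))
    refractory = int(round(refractory_s * rate))

    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    bursts: list[tuple[int, int]] = []
    for s, e in merged:
        if bursts and s - bursts[-1][1] < refractory:
            # within the refractory of the previous burst: continuation or
            # ripple, never an independent breath — absorb it
            bursts[-1] = (bursts[-1][0], e)
            continue
        if e - s < min_dur:
            continue
        bursts.append((s, e))

    # refine onsets: the k*MAD crossing lags the true burst foot by several
    # ms (trailing integration), so walk back to 10% of the threshold excess
    refined: list[tuple[int, int]] = []
    max_back = int(round(0.040 * rate))
    tol = max(1, int(round(0.003 * rate)))  # ride over brief noise dips
    for s, e in bursts:
        foot = med[s] + 0.05 * (thr[s] - med[s])
        s2 = s
        below = 0
        j = s
        while j > 0 and s - j < max_back:
            j -= 1
            if x[j] > foot:
                below = 0
                s2 = j
            else:
                below += 1
                if below > tol:
                    break
        if refined and s2 < refined[-1][1]:
            s2 = refined[-1][1]
        refined.append((s2, e))

    records: list[BreathRecord] = []
    t0 = integrated.start
    for s, e in refined:
        seg = x[s:e]
        records.append(
            BreathRecord(
                onset=t0 + s / rate,
                offset=t0 + e / rate,
                peak=float(seg.max()),
                insp_duration=(e - s) / rate,
                area=float(np.trapezoid(seg, dx=1.0 / rate)),
            )
        )
    # fold decay-tail ripple fragments back into their parent burst
    folded: list[BreathRecord] = []
    for rec in records:
        if (
            folded
            and rec.onset - folded[-1].offset < tail_merge_gap_s
            and rec.peak < tail_merge_ratio * folded[-1].peak
        ):
            prev = folded[-1]
            prev.offset = rec.offset
            prev.insp_duration = prev.offset - prev.onset
            prev.area += rec.area
        else:
            folded.append(rec)
    for a, b in zip(folded, folded[1:]):
        a.period = b.onset - a.onset
        a.inst_freq = 1.0 / a.period
    return folded


def detect_ecg_peaks(
    raw_emg: TimeSeries,
    band_hz: tuple[float, float] = (180.0, 450.0),
    k_mad: float = 14.0,
    min_separation_s: float = 0.030,
) -> list[float]:
    """R-peak times of the cardiac signal contaminating the raw diaphragm EMG.

    ECG R-waves are much sharper than the inspiratory burst carrier, so a
    high-frequency band-pass concentrates spike energy while rejecting most
    burst energy; peaks are then threshold-crossings of the band envelope at
    ``k_mad`` x MAD above its median, with a cardiac refractory separation.
    Returns an empty list when no suprathreshold spikes exist (e.g. after
    asystole or with no cardiac contamination).
    """
    if raw_emg.n < 10:
        return []
    hi = min(band_hz[1], 0.45 * raw_emg.rate)
    lo = band_hz[0]
    if hi <= lo:
        return []
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=raw_emg.rate, output="sos")
    y = np.abs(sps.sosfiltfilt(sos, raw_emg.samples))
    med = np.median(y)
    mad = np.median(np.abs(y - med))
    if mad <= 0:
        return []
    thr = med + k_mad * mad
    dist = max(1, int(round(min_separation_s * raw_emg.rate)))
    peaks, _ = sps.find_peaks(y, height=thr, distance=dist)
    return [raw_emg.start + p / raw_emg.rate for p in peaks]
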