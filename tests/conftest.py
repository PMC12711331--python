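"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from epivent import BreathRecord, SimConfig, generate_recording


def make_breaths(periods, peaks=None, t0=0.0, burst_s=0.08):
    """Build a breath train from inter-onset periods (the last breath gets no
    period).  ``periods[i]`` is onset[i+1] - onset[i]."""
    onsets = t0 + np.concatenate(([0.0], np.cumsum(periods)))
    if peaks is None:
        peaks = np.ones(onsets.size)
    out = []
    for i, on in enumerate(onsets):
        per = float(periods[i]) if i < len(periods) else None
        out.append(
            BreathRecord(
                onset=float(on),
                offset=float(on) + burst_s,
                peak=float(peaks[i]),
                insp_duration=burst_s,
                area=float(peaks[i]) * burst_s / 2,
                period=per,
                inst_freq=None if per is None else 1.0 / per,
            )
        )
    return out


# ---------------------------------------------------------------------------
# brute-force oracles (intentionally naive, independent of the implementation)
# ---------------------------------------------------------------------------

def oracle_trailing_abs_mean(x, w):
    """O(n*w) trailing moving average of |x|."""
    out = np.empty(len(x))
    for i in range(len(x)):
        lo = max(0, i - w + 1)
        out[i] = np.mean(np.abs(x[lo: i + 1]))
    return out


def oracle_sighs(breaths, states, ratio=2.0, window=10, min_n=5, lookback=60.0):
    """Quadratic trailing-window sigh scan; returns sigh indices."""
    flags = []
    for i in range(len(breaths)):
        base = []
        for j in range(i - 1, -1, -1):
            # never scan back across a silent gap between consecutive breaths
            if breaths[j + 1].onset - breaths[j].offset > lookback:
                break
            if states[j] == states[i] and j not in flags:
                base.append(j)
            if len(base) == window:
                break
        if len(base) >= min_n:
            m = np.mean([breaths[j].peak for j in base])
            if breaths[i].peak >= ratio * m:
                flags.append(i)
    return flags


def oracle_apneas(breaths, states, sigh_idx, ratio=2.5, window=10, min_n=5,
                  lookback=60.0, postsigh_s=8.0):
    """Quadratic trailing-window apnea scan; returns (index, postsigh) pairs."""
    out = []
    sigh_ends = [breaths[j].offset for j in sigh_idx]
    for i in range(len(breaths)):
        if breaths[i].period is None:
            continue
        base = []
        for j in range(i - 1, -1, -1):
            if breaths[j + 1].onset - breaths[j].offset > lookback:
                break
            if states[j] == states[i] and j not in sigh_idx and breaths[j].period is not None:
                base.append(j)
            if len(base) == window:
                break
        if len(base) >= min_n:
            m = np.mean([breaths[j].period for j in base])
            if breaths[i].period >= ratio * m:
                ps = any(0.0 <= breaths[i].offset - se <= postsigh_s for se in sigh_ends)
                out.append((i, ps))
    return out


@pytest.fixture(scope="session")
def quiet_recording():
    """120 s event-free recording at the study conditions (shared, read-only)."""
    cfg = SimConfig(duration=120.0, seed=101)
    return cfg, generate_recording(cfg)


def oracle_pges(eeg, seizure, baseline_s=100.0, sustain_s=5.0, n_sd=3.0,
                window_s=2.0, floor_frac=0.25):
    """Independent PGES re-derivation: explicit per-position window means and
    an exhaustive scan over candidate endpoints."""
    from epivent.eeg import power_series

    p, dt = power_series(eeg)
    b0 = int((seizure.start - baseline_s) / dt)
    b1 = int(seizure.start / dt)
    w = int(sustain_s / dt)
    means = [p[k: k + w].mean() for k in range(b0, b1 - w + 1, w)]
    thr = max(np.mean(means) - n_sd * np.std(means, ddof=1),
              floor_frac * np.mean(means))
    k0 = int(seizure.end / dt)
    wb = int(window_s / dt)
    span = int((sustain_s - window_s) / dt) + 1
    m = p.size - k0
    exc = np.empty(m, dtype=bool)
    for i in range(m):
        lo = max(0, i - wb + 1)
        exc[i] = p[k0 + lo: k0 + i + 1].mean() > thr
    for t in range(m - span + 1):
        if all(exc[t: t + span]):
            if t == 0:
                return 0.0
            wf = int(0.5 / dt)
            for k in range(t, max(0, t - wb) - 1, -1):
                lo = max(0, k - wf)
                if lo == k:
                    break
                if p[k0 + lo: k0 + k].mean() <= thr:
                    return k * dt
            return t * dt
    return m * dt


def oracle_pea(seiz, end, max_gap=300.0, min_run=3, look=1800.0):
    """Independent PEA-onset scan."""
    for i in range(len(seiz)):
        horizon = min(end, seiz[i].start + look)
        gaps = []
        for k in range(i, len(seiz)):
            if k + 1 < len(seiz):
                if seiz[k].end <= horizon:
                    gaps.append(seiz[k + 1].start - seiz[k].end)
            elif seiz[k].end < horizon:
                gaps.append(horizon - seiz[k].end)
        if len(gaps) >= min_run and all(g < max_gap for g in gaps):
            return seiz[i].start
    return None
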