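"""Terminal-event ordering: last breath, last heartbeat, EEG collapse.

The defining observation in this disease model is that terminal apnea (no
further inspiratory bursts in the diaphragm EMG) precedes terminal asystole
(cessation of the cardiac signal contaminating the raw EMG), with EEG power
collapsing at or after the cessation of breathing.  :func:`analyze_terminal`
establishes that ordering for one recording and classifies the pre-terminal
breathing pattern.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .eeg import power_series
from .emg import BreathRecord
from .errors import ParameterError
from .io import TimeSeries
from .resp import RespEvent, detect_apneas, detect_sighs

__all__ = ["TerminalReport", "analyze_terminal"]


@dataclass
class TerminalReport:
    """Terminal-event times and ordering for one recording.

    ``apnea_before_asystole`` is ``None`` (absent, not false) when no cardiac
    signal was detectable.  ``pattern`` classifies the final 10 min of
    breathing: ``declining_rate``, ``irregular_with_apneas``, ``tonic_burst``
    or ``mixed``.
    """

    last_breath: float
    last_ecg: float | None
    eeg_collapse: float | None
    apnea_before_asystole: bool | None
    pattern: str

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def _eeg_collapse_time(
    eeg: TimeSeries,
    baseline_end: float,
    frac: float = 0.10,
    sustain_s: float = 60.0,
) -> float | None:
    """First time EEG power falls below ``frac`` x baseline for >= sustain_s.

    Baseline power is averaged over up to 6 h of recording ending at
    ``baseline_end`` (the pre-terminal portion).
    """
    p, dt = power_series(eeg, bin_s=0.1)
    b1 = max(1, min(p.size, int((baseline_end - eeg.start) / dt)))
    b0 = max(0, b1 - int(6 * 3600.0 / dt))
    mu = float(p[b0:b1].mean())
    if mu <= 0:
        return None
    thr = frac * mu
    need = int(round(sustain_s / dt))
    below = p < thr
    run = 0
    for i, v in enumerate(below):
        run = run + 1 if v else 0
        if run >= need:
            return eeg.start + (i - need + 1) * dt
    return None


def analyze_terminal(
    breaths: Sequence[BreathRecord],
    ecg_peaks: Sequence[float],
    eeg: TimeSeries,
    apneas: Sequence[RespEvent] | None = None,
    pattern_window_s: float = 600.0,
    decline_slope_bps_per_s: float = -0.002,
    tonic_duration_factor: float = 5.0,
) -> TerminalReport:
    """Determine terminal-event ordering for a recording ending in death.

    Precondition: no inspiratory bursts in the final 60 s of the recording.
    ``apneas`` may be supplied (e.g. state-aware events from the pipeline);
    otherwise they are recomputed state-free from the breath list.  The
    pre-terminal pattern is classified from the final ``pattern_window_s``:
    ``tonic_burst`` when a burst with inspiratory duration more than
    ``tonic_duration_factor`` x the median is present, else
    ``irregular_with_apneas`` when two or more apneas occurred, else
    ``declining_rate`` when the frequency trend slope is below
    ``decline_slope_bps_per_s``, else ``mixed``.
    """
    if not breaths:
        raise ParameterError("no breaths detected; cannot analyze terminal events")
    last_breath = max(b.onset for b in breaths)
    if eeg.end - last_breath < 60.0:
        raise ParameterError(
            "recording does not end with death: breaths present in the final 60 s"
        )
    last_ecg = float(max(ecg_peaks)) if len(ecg_peaks) else None
    flag = None if last_ecg is None else bool(last_breath < last_ecg)

    if apneas is None:
        one_state = lambda t: "ALL"
        sighs = detect_sighs(breaths, one_state)
        apneas = [
            e for e in detect_apneas(breaths, one_state, sighs) if e.kind == "apnea"
        ]

    w0 = eeg.end - pattern_window_s
    final = [b for b in breaths if b.onset >= w0]
    med_dur = float(np.median([b.insp_duration for b in breaths]))
    tonic = any(b.insp_duration > tonic_duration_factor * med_dur for b in final)
    n_ap = sum(1 for a in apneas if a.time >= w0)
    f = [(b.onset, b.inst_freq) for b in final if b.inst_freq is not None]
    slope = None
    if len(f) >= 5:
        t, y = np.array([x[0] for x in f]), np.array([x[1] for x in f])
        slope = float(np.polyfit(t - t[0], y, 1)[0])
    if tonic:
        pattern = "tonic_burst"
    elif n_ap >= 2:
        pattern = "irregular_with_apneas"
    elif slope is not None and slope < decline_slope_bps_per_s:
        pattern = "declining_rate"
    else:
        pattern = "mixed"

    return TerminalReport(
        last_breath=last_breath,
        last_ecg=last_ecg,
        eeg_collapse=_eeg_collapse_time(eeg, baseline_end=last_breath - 60.0),
        apnea_before_asystole=flag,
        pattern=pattern,
    )
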