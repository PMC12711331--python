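"""Sleep/wake scoring of 10 s epochs from EEG spectra, EMG and movement.

Epochs tile the recording without overlap.  Priority order: seizure > PGES >
movement > spectral scoring.  The spectral rule compares band power in the
delta (0.5-4 Hz) and theta (4.5-8 Hz) ranges per epoch (one-segment Welch
periodogram; 10 s at 500 Hz gives 0.1 Hz resolution):

* **NREM** — delta/theta >= ``r_nrem`` with high EEG amplitude (epoch RMS at
  least ``a_nrem`` x the recording median) and a quiescent EMG (tonic level
  at most ``m_max_factor`` x the recording median);
* **REM_IW** (REM merged with inactive wake, which cannot be separated
  without a nuchal EMG lead) — theta/delta >= ``r_rem``;
* otherwise **OTH**.

Sleep state is undefined during persistent epileptiform activity: every
epoch at or after ``pea_onset`` is scored OTH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .eeg import PGESEvent, SeizureEvent
from .errors import ParameterError
from .io import Interval, MovementMask, TimeSeries

__all__ = ["SleepEpoch", "score_epochs", "state_at"]

EPOCH_S = 10.0

MVM = "MVM"
NREM = "NREM"
REM_IW = "REM_IW"
SEIZ = "SEIZ"
PGES = "PGES"
OTH = "OTH"


@dataclass
class SleepEpoch:
    """One scored 10 s epoch."""

    start: float
    length: float
    state: str
    delta_power: float
    theta_power: float


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        return 0.0
    return float(np.trapezoid(psd[sel], freqs[sel]))


def score_epochs(
    eeg: TimeSeries,
    emg_integrated: TimeSeries,
    movement: MovementMask | None = None,
    seizures: Sequence[SeizureEvent] = (),
    pges: Sequence[PGESEvent] = (),
    pea_onset: float | None = None,
    epoch_s: float = EPOCH_S,
    delta_band: tuple[float, float] = (0.5, 4.0),
    theta_band: tuple[float, float] = (4.5, 8.0),
    r_nrem: float = 1.5,
    r_rem: float = 1.2,
    a_nrem: float = 0.5,
    m_max_factor: float = 3.0,
) -> list[SleepEpoch]:
    """Score the recording into 10 s epochs (see module docstring).

    ``emg_integrated`` is the rectified-integrated EMG; its per-epoch median
    is the tonic level used for the NREM EMG gate.  EEG and EMG must cover
    the same interval (tolerance one epoch).
    """
    if abs(eeg.duration - emg_integrated.duration) > epoch_s or abs(
        eeg.start - emg_integrated.start
    ) > 1e-6:
        raise ParameterError(
            "EEG and integrated EMG must cover the same interval"
        )
    n_ep = int(math.floor(eeg.duration / epoch_s + 1e-9))
    spe = int(round(epoch_s * eeg.rate))
    spe_m = int(round(epoch_s * emg_integrated.rate))

    rms = np.empty(n_ep)
    delta = np.empty(n_ep)
    theta = np.empty(n_ep)
    tonic = np.empty(n_ep)
    for i in range(n_ep):
        seg = eeg.samples[i * spe: (i + 1) * spe]
        freqs, psd = sps.welch(seg, fs=eeg.rate, nperseg=seg.size)
        delta[i] = _band_power(freqs, psd, delta_band)
        theta[i] = _band_power(freqs, psd, theta_band)
        rms[i] = float(np.sqrt(np.mean(seg**2)))
        mseg = emg_integrated.samples[i * spe_m: (i + 1) * spe_m]
        tonic[i] = float(np.median(mseg)) if mseg.size else 0.0

    rms_med = float(np.median(rms)) if n_ep else 0.0
    tonic_med = float(np.median(tonic)) if n_ep else 0.0

    seiz_iv = [Interval(s.start, s.end) for s in seizures]
    pges_iv = [Interval(g.seizure_end, g.seizure_end + g.duration) for g in pges if g.duration > 0]

    epochs: list[SleepEpoch] = []
    for i in range(n_ep):
        t0 = eeg.start + i * epoch_s
        ep = Interval(t0, t0 + epoch_s)
        if pea_onset is not None and ep.start >= pea_onset:
            state = OTH
        elif any(ep.overlaps(iv) for iv in seiz_iv):
            state = SEIZ
        elif any(ep.overlaps(iv) for iv in pges_iv):
            state = PGES
        elif movement is not None and movement.overlaps(ep):
            state = MVM
        else:
            d, th = delta[i], theta[i]
            if (
                th > 0
                and d / th >= r_nrem
                and rms[i] >= a_nrem * rms_med
                and tonic[i] <= m_max_factor * tonic_med
            ):
                state = NREM
            elif d > 0 and th / d >= r_rem:
                state = REM_IW
            else:
                state = OTH
        epochs.append(SleepEpoch(t0, epoch_s, state, delta[i], theta[i]))
    return epochs


def state_at(epochs: Sequence[SleepEpoch], t: float) -> str:
    """State of the epoch containing ``t`` (epochs are half-open, so a
    boundary time belongs to the later epoch)."""
    if not epochs:
        raise ParameterError("no epochs")
    t0 = epochs[0].start
    i = int(math.floor((t - t0) / epochs[0].length + 1e-9))
    if i < 0 or i >= len(epochs):
        raise ParameterError(
            f"time {t} s outside the scored range "
            f"[{t0}, {t0 + len(epochs) * epochs[0].length}) s"
        )
    return epochs[i].state
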