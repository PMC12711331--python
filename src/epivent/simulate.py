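"""Synthetic coupled EEG / diaphragm-EMG telemetry recordings.

The generator emulates chronic two-channel telemetry from an epileptic mouse:
baseline breathing near 4 breaths/s realized as inspiratory EMG bursts
(raised-cosine envelopes modulating band-limited noise), cardiac R-peak
contamination of the diaphragm lead, sighs (augmented-amplitude breaths),
apneas (stretched respiratory cycles), state-dependent cortical EEG
(high-amplitude 0.5-4 Hz activity in NREM sleep, moderate 4.5-8 Hz activity
in REM/inactive wake), generalized seizures (sinusoid-plus-harmonics surges
well above baseline amplitude), postictal EEG suppression, escalating seizure
rate culminating in persistent epileptiform activity (PEA), progressive
slowing/deepening of breathing, and a terminal apnea followed by asystole.

Every event is *programmed*: the returned :class:`GroundTruth` carries the
exact schedule and is the oracle against which all detectors are validated.
Output is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ScheduleError
from .io import Interval, MovementMask, TimeSeries, EEG_LABEL, EMG_LABEL

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ScheduledApnea",
    "generate_recording",
    "generate_disease_course",
    "random_event_config",
]

EPOCH_S = 10.0  # sleep-scoring epoch length, also used for ground-truth states


@dataclass
class ScheduledApnea:
    """One programmed apnea: the long respiratory cycle and its bookkeeping."""

    time: float          # onset of the breath that starts the long cycle
    pause_start: float   # end of that breath's burst (start of the silent gap)
    duration: float      # realized long period, s
    ratio: float         # programmed period multiple
    postsigh: bool = False


@dataclass
class SimConfig:
    """Study conditions for one synthetic recording.

    Defaults encode the recorded phenotype: ~4 breaths/s baseline breathing
    (≈240 breaths/min), ~80 ms inspiratory bursts, cardiac contamination at
    10 beats/s, NREM-dominant sleep architecture, and amplitude ratios that
    place sighs and seizures clearly beyond their detection thresholds
    (sighs 2.5x vs the 2x rule, seizures 3x vs the 2x rule, apneas 3x vs the
    2.5x rule) the way manually curated events in real traces are.
    """

    duration: float = 600.0
    seed: int = 0

    # breathing
    breath_rate: float = 4.0          # breaths/s baseline
    breath_burst_ms: float = 80.0     # inspiratory burst duration
    breath_amp: float = 1.0           # burst envelope peak, a.u.
    breath_jitter: float = 0.03       # fractional SD of the breath period
    amp_jitter: float = 0.08          # fractional SD of per-breath amplitude
    sigh_amp_ratio: float = 2.5       # sigh peak / local breath peak

    # cardiac contamination
    ecg_rate: float = 10.0            # beats/s
    ecg_amp_ratio: float = 0.3        # R-peak amplitude / breath envelope peak
    ecg_width_ms: float = 8.0         # biphasic spike width

    # noise floors
    noise_sd: float = 0.02            # EMG additive white noise, a.u.
    eeg_noise_sd: float = 0.05        # EEG broadband floor, a.u.

    # EEG state architecture
    eeg_rate: float = 500.0
    emg_rate: float = 1000.0
    eeg_nrem_rms: float = 1.0         # 0.5-4 Hz dominant, high amplitude
    eeg_rem_rms: float = 0.5          # 4.5-8 Hz dominant, moderate amplitude
    state_cycle: tuple = (("NREM", 300.0), ("REM_IW", 120.0), ("MVM", 60.0))

    # event schedules (times in recording seconds)
    sigh_times: tuple = ()
    apnea_schedule: tuple = ()        # (time, period_ratio)
    seizure_schedule: tuple = ()      # (start, duration, amp_ratio, freq_hz)
    pges_durations: tuple = ()        # seconds of suppression per seizure
    pea_onset: float | None = None
    slowing_profile: tuple | None = None  # (time, freq_scale, amp_scale) knots
    terminal: tuple | None = None     # (apnea_time, asystole_time)
    terminal_tonic_s: float | None = None  # prolonged final diaphragm burst

    # postictal suppression shape
    pges_amp_factor: float = 0.2
    pges_recovery_s: float = 0.25     # amplitude ramp back after suppression
    pges_rebound: float = 1.5         # brief rebound amplitude multiple
    pges_rebound_s: float = 4.0

    def validate(self) -> None:
        def _in_range(t: float, what: str) -> None:
            if not (0.0 <= t < self.duration):
                raise ScheduleError(f"{what} at {t} s outside [0, {self.duration}) s")

        for t in self.sigh_times:
            _in_range(t, "sigh")
        for t, ratio in self.apnea_schedule:
            _in_range(t, "apnea")
            if ratio <= 1.0:
                raise ScheduleError(f"apnea period_ratio must be > 1, got {ratio}")
        for s, d, amp, _f in self.seizure_schedule:
            _in_range(s, "seizure")
            if s + d > self.duration:
                raise ScheduleError(f"seizure at {s} s runs past recording end")
            if amp <= 1.0:
                raise ScheduleError(f"seizure amp_ratio must be > 1, got {amp}")
        if self.terminal is not None:
            t_a, t_s = self.terminal
            _in_range(t_a, "terminal apnea")
            _in_range(t_s, "terminal asystole")
            if t_s <= t_a:
                raise ScheduleError("terminal asystole must follow terminal apnea")


@dataclass
class GroundTruth:
    """The programmed event schedule — the universal test oracle."""

    duration: float
    breaths: np.ndarray                      # burst onsets, s
    breath_amps: np.ndarray                  # envelope peak per breath, a.u.
    breath_durs: np.ndarray                  # burst duration per breath, s
    sighs: list[float] = field(default_factory=list)
    apneas: list[ScheduledApnea] = field(default_factory=list)
    seizures: list[Interval] = field(default_factory=list)
    pges: list[tuple[float, float]] = field(default_factory=list)  # (seizure_end, dur)
    pea_onset: float | None = None
    state_blocks: list[tuple[Interval, str]] = field(default_factory=list)
    movement: MovementMask = field(default_factory=MovementMask)
    ecg_peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    terminal: tuple | None = None
    stages: list[tuple[str, Interval]] = field(default_factory=list)
    day_s: float = 86400.0  # seconds standing for one day (disease course)

    def epoch_states(self) -> list[str]:
        """Ground-truth label per 10 s epoch (priority SEIZ > PGES > MVM > block)."""
        n = int(math.floor(self.duration / EPOCH_S + 1e-9))
        out = []
        for i in range(n):
            ep = Interval(i * EPOCH_S, (i + 1) * EPOCH_S)
            if self.pea_onset is not None and ep.start >= self.pea_onset:
                out.append("OTH")
                continue
            if any(ep.overlaps(s) for s in self.seizures):
                out.append("SEIZ")
                continue
            if any(
                d > 0 and ep.overlaps(Interval(e, e + d)) for e, d in self.pges
            ):
                out.append("PGES")
                continue
            if self.movement.overlaps(ep):
                out.append("MVM")
                continue
            mid = ep.start + EPOCH_S / 2
            lab = "OTH"
            for iv, state in self.state_blocks:
                if iv.contains(mid):
                    lab = state
                    break
            out.append(lab)
        return out

    def state_at(self, t: float) -> str:
        for iv, state in self.state_blocks:
            if iv.contains(t):
                return state
        return "OTH"


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _profile_scales(config: SimConfig, t: float) -> tuple[float, float]:
    """(freq_scale, amp_scale) from the piecewise-linear slowing profile."""
    prof = config.slowing_profile
    if not prof:
        return 1.0, 1.0
    ts = [p[0] for p in prof]
    fs = [p[1] for p in prof]
    as_ = [p[2] for p in prof]
    return float(np.interp(t, ts, fs)), float(np.interp(t, ts, as_))


def _state_blocks(config: SimConfig) -> tuple[list[tuple[Interval, str]], MovementMask]:
    blocks: list[tuple[Interval, str]] = []
    mvm: list[Interval] = []
    t = 0.0
    i = 0
    cycle = config.state_cycle
    while t < config.duration:
        state, length = cycle[i % len(cycle)]
        end = min(t + length, config.duration)
        blocks.append((Interval(t, end), state))
        if state == "MVM":
            mvm.append(Interval(t, end))
        t = end
        i += 1
    return blocks, MovementMask(mvm)


def _bandnoise(rng: np.random.Generator, n: int, rate: float,
               lo: float, hi: float, rms: float) -> np.ndarray:
    """Band-passed white noise normalized to the requested RMS."""
    if n == 0:
        return np.empty(0)
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    s = y.std()
    return y * (rms / s) if s > 0 else y


def _schedule_breaths(config: SimConfig, rng: np.random.Generator):
    """Walk breath onsets through the recording, realizing sighs and apneas."""
    sighs_left = sorted(config.sigh_times)
    apneas_left = sorted(config.apnea_schedule)
    t_stop = config.duration
    tonic = None
    if config.terminal is not None:
        t_apnea = config.terminal[0]
        if config.terminal_tonic_s:
            tonic = (max(0.0, t_apnea - config.terminal_tonic_s), config.terminal_tonic_s)
            t_stop = tonic[0]
        else:
            t_stop = t_apnea

    onsets: list[float] = []
    amps: list[float] = []
    durs: list[float] = []
    sigh_onsets: list[float] = []
    apneas: list[ScheduledApnea] = []
    burst_s = config.breath_burst_ms * 1e-3

    t = 0.05
    while t < t_stop:
        fscale, ascale = _profile_scales(config, t)
        amp = config.breath_amp * ascale * float(
            np.clip(1.0 + config.amp_jitter * rng.standard_normal(), 0.7, 1.3)
        )
        is_sigh = False
        # a scheduled sigh lands on the breath whose onset first reaches it
        if sighs_left and t >= sighs_left[0] - 1e-9:
            sighs_left.pop(0)
            is_sigh = True
            amp *= config.sigh_amp_ratio
        onsets.append(t)
        amps.append(amp)
        durs.append(burst_s)
        if is_sigh:
            sigh_onsets.append(t)

        period = (1.0 / (config.breath_rate * fscale)) * float(
            np.clip(1.0 + config.breath_jitter * rng.standard_normal(), 0.8, 1.2)
        )
        if apneas_left and t <= apneas_left[0][0] < t + period:
            sched_t, ratio = apneas_left.pop(0)
            period *= ratio
            apneas.append(
                ScheduledApnea(
                    time=t, pause_start=t + burst_s, duration=period, ratio=ratio
                )
            )
        t += period

    if tonic is not None:
        onsets.append(tonic[0])
        fscale, ascale = _profile_scales(config, tonic[0])
        amps.append(config.breath_amp * ascale)
        durs.append(tonic[1])

    # post-sigh flag: pause starting within 8 s after a sigh burst's end
    for ap in apneas:
        for s in sigh_onsets:
            if 0.0 <= ap.pause_start - (s + burst_s) <= 8.0:
                ap.postsigh = True
                break
    return (
        np.asarray(onsets),
        np.asarray(amps),
        np.asarray(durs),
        sigh_onsets,
        apneas,
    )


def _ecg_times(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    stop = config.duration
    if config.terminal is not None:
        stop = min(stop, config.terminal[1])
    if config.ecg_amp_ratio <= 0 or config.ecg_rate <= 0:
        return np.empty(0)
    n = int(stop * config.ecg_rate) + 2
    periods = (1.0 / config.ecg_rate) * (1.0 + 0.02 * rng.standard_normal(n))
    times = 0.03 + np.cumsum(periods)
    return times[times < stop - 1e-3]


def _ecg_template(rate: float, width_ms: float) -> np.ndarray:
    """Sharp biphasic spike (derivative-of-Gaussian), unit peak amplitude."""
    sigma = width_ms * 1e-3 / 10.0
    half = int(round(width_ms * 1e-3 * rate)) // 2 + 2
    tau = np.arange(-half, half + 1) / rate
    w = -tau / sigma * np.exp(0.5 - 0.5 * (tau / sigma) ** 2)
    return w / np.abs(w).max()


def _burst_envelope(n: int, rate: float = 1000.0, attack_s: float = 0.016) -> np.ndarray:
    """Inspiratory burst envelope: fast sigmoidal attack (rapid motor-unit
    recruitment, ~16 ms regardless of burst length) followed by a
    raised-cosine decay; unit peak."""
    n_a = max(1, min(int(round(attack_s * rate)), n // 2))
    env = np.empty(n)
    env[:n_a] = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_a) / n_a))
    s = np.arange(n - n_a) / max(n - n_a - 1, 1)
    env[n_a:] = 0.5 * (1.0 + np.cos(np.pi * s))
    return env


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def generate_recording(
    config: SimConfig, seed: int | None = None
) -> tuple[TimeSeries, TimeSeries, MovementMask, GroundTruth]:
    """Generate one synthetic recording.

    Returns ``(eeg, emg, movement_mask, ground_truth)``.  ``seed`` overrides
    ``config.seed`` when given; identical ``(config, seed)`` yields
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_emg = int(round(config.duration * config.emg_rate))
    n_eeg = int(round(config.duration * config.eeg_rate))

    # ---- breathing schedule and EMG channel -------------------------------
    onsets, amps, durs, sigh_onsets, apneas = _schedule_breaths(config, rng)
    emg = config.noise_sd * rng.standard_normal(n_emg)
    carrier = _bandnoise(rng, n_emg, config.emg_rate, 60.0, 120.0, 1.0)
    for onset, amp, dur in zip(onsets, amps, durs):
        i0 = int(round(onset * config.emg_rate))
        nb = int(round(dur * config.emg_rate))
        i1 = min(i0 + nb, n_emg)
        if i1 <= i0:
            continue
        env = _burst_envelope(nb, config.emg_rate)[: i1 - i0]
        seg = carrier[i0:i1]
        # normalize the carrier's envelope-weighted rectified level so breath
        # peak amplitude tracks the schedule (breath-to-breath variability is
        # injected explicitly via amplitude jitter, not carrier luck)
        wsum = float(np.sum(np.abs(seg) * env))
        if wsum > 0:
            seg = seg * (0.798 * float(np.sum(env)) / wsum)
        emg[i0:i1] += amp * env * seg

    ecg_times = _ecg_times(config, rng)
    if ecg_times.size:
        tmpl = config.ecg_amp_ratio * config.breath_amp * _ecg_template(
            config.emg_rate, config.ecg_width_ms
        )
        half = tmpl.size // 2
        for t_peak in ecg_times:
            c = int(round(t_peak * config.emg_rate))
            i0, i1 = c - half, c + half + 1
            j0, j1 = max(0, i0), min(n_emg, i1)
            if j1 > j0:
                emg[j0:j1] += tmpl[j0 - i0: j1 - i0]

    # ---- EEG channel ------------------------------------------------------
    blocks, movement = _state_blocks(config)
    nrem = _bandnoise(rng, n_eeg, config.eeg_rate, 0.5, 4.0, config.eeg_nrem_rms)
    rem = _bandnoise(rng, n_eeg, config.eeg_rate, 4.5, 8.0, config.eeg_rem_rms)
    mvm = _bandnoise(rng, n_eeg, config.eeg_rate, 4.5, 30.0, 0.7 * config.eeg_nrem_rms)
    base = np.empty(n_eeg)
    for iv, state in blocks:
        i0 = int(round(iv.start * config.eeg_rate))
        i1 = int(round(iv.end * config.eeg_rate))
        src = {"NREM": nrem, "REM_IW": rem, "MVM": mvm}.get(state, rem)
        base[i0:i1] = src[i0:i1]

    gain = np.ones(n_eeg)  # multiplicative amplitude profile applied to base
    eeg_extra = np.zeros(n_eeg)

    seizures: list[Interval] = []
    pges: list[tuple[float, float]] = []
    t_axis_eeg = np.arange(n_eeg) / config.eeg_rate
    for k, (s, d, amp_ratio, freq) in enumerate(config.seizure_schedule):
        iv = Interval(s, s + d)
        seizures.append(iv)
        i0 = int(round(s * config.eeg_rate))
        i1 = int(round((s + d) * config.eeg_rate))
        # generalized seizures are large in absolute terms: scale against the
        # dominant (NREM) baseline so the >2x criterion holds in any state
        local_rms = max(config.eeg_nrem_rms, 1e-9)
        tt = t_axis_eeg[i0:i1]
        wave = (
            np.sin(2 * np.pi * freq * tt)
            + 0.5 * np.sin(2 * np.pi * 2 * freq * tt)
            + 0.25 * np.sin(2 * np.pi * 3 * freq * tt)
        )
        wave *= amp_ratio * local_rms / max(wave.std(), 1e-9)
        # short edge taper so the surge is abrupt but band-limited
        ntap = min(int(0.1 * config.eeg_rate), wave.size // 2)
        if ntap > 0:
            ramp = np.linspace(0.0, 1.0, ntap)
            wave[:ntap] *= ramp
            wave[-ntap:] *= ramp[::-1]
        gain[i0:i1] = 0.0
        eeg_extra[i0:i1] += wave

        pd_ = config.pges_durations[k] if k < len(config.pges_durations) else 0.0
        if pd_ > 0:
            pges.append((s + d, pd_))
            j0 = i1
            j1 = min(int(round((s + d + pd_) * config.eeg_rate)), n_eeg)
            gain[j0:j1] = np.minimum(gain[j0:j1], config.pges_amp_factor)
            # recovery: fast ramp to a brief rebound, then unity
            r0 = j1
            r1 = min(r0 + int(config.pges_recovery_s * config.eeg_rate), n_eeg)
            if r1 > r0:
                gain[r0:r1] = np.minimum(
                    gain[r0:r1],
                    np.linspace(config.pges_amp_factor, config.pges_rebound, r1 - r0),
                )
            b0, b1 = r1, min(r1 + int(config.pges_rebound_s * config.eeg_rate), n_eeg)
            gain[b0:b1] = config.pges_rebound
            # postictal recovery starts with mixed-frequency activity, not a
            # pure slow wave: a broadband burst makes the power re-entry as
            # abrupt as the underlying physiology, independent of the phase
            # of the ongoing delta oscillation
            bb0, bb1 = r0, b1
            if bb1 > bb0:
                env = np.ones(bb1 - bb0)
                nr = r1 - r0
                if nr > 0:
                    env[:nr] = np.linspace(0.0, 1.0, nr)
                eeg_extra[bb0:bb1] += (
                    config.pges_rebound / 0.7
                ) * env * mvm[bb0:bb1]

    if config.terminal is not None:
        t_a = config.terminal[0]
        i0 = int(round(t_a * config.eeg_rate))
        gain[i0:] = np.minimum(gain[i0:], 0.05)

    eeg = base * gain + eeg_extra + config.eeg_noise_sd * rng.standard_normal(n_eeg)

    gt = GroundTruth(
        duration=config.duration,
        breaths=onsets,
        breath_amps=amps,
        breath_durs=durs,
        sighs=sigh_onsets,
        apneas=apneas,
        seizures=seizures,
        pges=pges,
        pea_onset=config.pea_onset,
        state_blocks=blocks,
        movement=movement,
        ecg_peaks=ecg_times,
        terminal=config.terminal,
    )
    eeg_ts = TimeSeries(EEG_LABEL, config.eeg_rate, eeg)
    emg_ts = TimeSeries(EMG_LABEL, config.emg_rate, emg)
    return eeg_ts, emg_ts, movement, gt


# ---------------------------------------------------------------------------
# randomized study conditions and the disease course
# ---------------------------------------------------------------------------

def _place_times(
    rng: np.random.Generator,
    n: int,
    window: tuple[float, float],
    min_gap: float,
    forbidden: list[Interval],
) -> list[float]:
    """Draw ``n`` times in ``window``, pairwise >= min_gap apart, avoiding
    forbidden intervals; simple rejection sampling."""
    out: list[float] = []
    for _ in range(20000):
        if len(out) == n:
            break
        t = float(rng.uniform(*window))
        if any(iv.contains(t) for iv in forbidden):
            continue
        if any(abs(t - u) < min_gap for u in out):
            continue
        out.append(t)
    if len(out) < n:
        raise ScheduleError(f"could not place {n} events in {window}")
    return sorted(out)


def random_event_config(
    duration: float,
    seed: int,
    n_apneas: int = 20,
    n_sighs: int = 20,
    n_seizures: int = 3,
    apnea_ratio: float = 3.0,
    seizure_s: float = 25.0,
    pges_s: float = 20.0,
    **overrides,
) -> SimConfig:
    """A recording at the study conditions with a randomized event schedule.

    Events are kept clear of state-block transitions (>= 25 s inside a block,
    so a trailing same-state 10-breath baseline exists), >= 25 s apart, and
    respiratory events are kept off the seizure/PGES windows.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(duration=duration, seed=seed, **overrides)
    blocks, _ = _state_blocks(cfg)
    # forbid neighborhoods of block boundaries
    edges = sorted({iv.start for iv, _ in blocks} | {iv.end for iv, _ in blocks})
    forbidden = [Interval(max(0.0, e - 25.0), min(duration, e + 25.0)) for e in edges]

    seiz_starts = _place_times(
        rng, n_seizures, (120.0, duration - seizure_s - pges_s - 60.0),
        300.0, forbidden,
    ) if n_seizures else []
    seizure_schedule = tuple(
        (s, seizure_s, 3.0, 8.0) for s in seiz_starts
    )
    for s in seiz_starts:
        forbidden.append(Interval(s - 30.0, s + seizure_s + pges_s + 30.0))

    times = _place_times(
        rng, n_apneas + n_sighs, (60.0, duration - 30.0), 25.0, forbidden
    )
    order = rng.permutation(n_apneas + n_sighs)
    apnea_times = sorted(times[i] for i in order[:n_apneas])
    sigh_times = sorted(times[i] for i in order[n_apneas:])

    return replace(
        cfg,
        sigh_times=tuple(sigh_times),
        apnea_schedule=tuple((t, apnea_ratio) for t in apnea_times),
        seizure_schedule=seizure_schedule,
        pges_durations=tuple(pges_s for _ in seiz_starts),
    )


def generate_disease_course(
    seed: int,
    stages: list[tuple[float, float]],
    pea_hours: float = 0.5,
    terminal_lag_s: float = 30.0,
    stage_apnea_rate_per_h=lambda spd: 1.0 + 0.8 * spd,
    sigh_rate_per_h: float = 6.0,
    day_s: float = 7200.0,
) -> tuple[TimeSeries, TimeSeries, MovementMask, GroundTruth]:
    """Compressed multi-stage disease course ending in PEA and death.

    ``stages`` is an ordered list of ``(seizures_per_day, hours)``.  Time is
    compressed: every ``day_s`` seconds of recording stand for one day, so a
    stage of ``hours`` hours spans ``hours * 3600 / day_s`` virtual days and
    its seizure count is a Poisson draw at ``seizures_per_day`` x that
    (when the requested rates are nondecreasing, draws take a running
    maximum so realized counts escalate like the rates do).  Interictal
    apnea scheduling density escalates with the stage's seizure rate;
    breathing slows and deepens across stages via the slowing profile; a PEA
    phase (interictal gaps < 5 min) follows the last stage and ends in a
    terminal tonic burst, apnea, then asystole.  Re-analysis should bin
    stages with ``stage_recording(..., day_s=day_s)``.
    """
    if not stages:
        raise ScheduleError("stages must be nonempty")
    for spd, hours in stages:
        if hours <= 0:
            raise ScheduleError(f"zero-length stage ({spd}/day, {hours} h)")

    rng = np.random.default_rng(seed)
    stage_edges = np.concatenate(([0.0], np.cumsum([h * 3600.0 for _, h in stages])))
    pea_onset = float(stage_edges[-1])
    pea_len = pea_hours * 3600.0
    t_apnea = pea_onset + pea_len
    t_asys = t_apnea + terminal_lag_s
    duration = t_asys + 60.0

    seizure_s, pges_s = 25.0, 15.0
    seiz_schedule: list[tuple[float, float, float, float]] = []
    apnea_sched: list[tuple[float, float]] = []
    sigh_times: list[float] = []
    stage_windows: list[tuple[str, Interval]] = []

    def _bin_label(spd: float) -> str:
        if spd <= 0:
            return "0"
        if spd <= 1:
            return "1"
        if spd <= 3:
            return "2-3"
        if spd <= 5:
            return "4-5"
        if spd <= 10:
            return "6-10"
        return "11-20"

    spds = [spd for spd, _ in stages]
    escalating = all(b >= a for a, b in zip(spds, spds[1:]))
    counts: list[int] = []
    for spd, hours in stages:
        n_vdays = hours * 3600.0 / day_s
        c = int(rng.poisson(spd * n_vdays))
        if escalating and counts:
            c = max(c, counts[-1] if spds[len(counts)] >= spds[len(counts) - 1] else c)
        counts.append(c)

    for k, (spd, hours) in enumerate(stages):
        w = Interval(float(stage_edges[k]), float(stage_edges[k + 1]))
        stage_windows.append((_bin_label(spd), w))
        n_seiz = counts[k]
        lo, hi = w.start + 120.0, w.end - seizure_s - pges_s - 60.0
        if hi > lo:
            starts: list[float] = []
            for _ in range(20000):
                if len(starts) == n_seiz:
                    break
                t = float(rng.uniform(lo, hi))
                if all(abs(t - u) > seizure_s + pges_s + 60.0 for u in starts):
                    starts.append(t)
            for s in sorted(starts):
                seiz_schedule.append((s, seizure_s, 3.0, 8.0))
        n_ap = int(rng.poisson(stage_apnea_rate_per_h(spd) * hours))
        n_sg = int(rng.poisson(sigh_rate_per_h * hours))
        occupied = [Interval(s, s + seizure_s + pges_s + 20.0) for s, *_ in seiz_schedule]
        lo2, hi2 = w.start + 30.0, w.end - 10.0
        times = []
        for _ in range(20000):
            if len(times) == n_ap + n_sg:
                break
            t = float(rng.uniform(lo2, hi2))
            if any(iv.contains(t) for iv in occupied):
                continue
            if any(abs(t - u) < 20.0 for u in times):
                continue
            times.append(t)
        order = rng.permutation(len(times))
        apnea_sched.extend((times[i], 3.0) for i in order[:n_ap])
        sigh_times.extend(times[i] for i in order[n_ap: n_ap + n_sg])

    # PEA phase: seizure bursts with interictal gaps < 5 min
    t = pea_onset
    while t + seizure_s < t_apnea - 30.0:
        seiz_schedule.append((t, seizure_s, 3.0, 8.0))
        t += seizure_s + float(rng.uniform(120.0, 260.0))
    pea_win = max(7200.0 * day_s / 86400.0, 600.0)  # "2 h" in compressed time
    stage_windows.append(("early_PEA", Interval(pea_onset, min(pea_onset + pea_win, t_asys))))
    stage_windows.append(("late_PEA", Interval(max(t_asys - pea_win, pea_onset), t_asys)))

    n_stage = len(stages)
    slowing = tuple(
        (float(0.5 * (stage_edges[k] + stage_edges[k + 1])),
         1.0 - 0.25 * k / max(n_stage - 1, 1),
         1.0 + 0.5 * k / max(n_stage - 1, 1))
        for k in range(n_stage)
    ) + ((pea_onset + 0.5 * pea_len, 0.55, 1.8),)

    cfg = SimConfig(
        duration=duration,
        seed=seed,
        sigh_times=tuple(sorted(sigh_times)),
        apnea_schedule=tuple(sorted(apnea_sched)),
        seizure_schedule=tuple(sorted(seiz_schedule)),
        pges_durations=tuple(pges_s for _ in seiz_schedule),
        pea_onset=pea_onset,
        slowing_profile=slowing,
        terminal=(t_apnea, t_asys),
        terminal_tonic_s=1.5,
    )
    eeg, emg, movement, gt = generate_recording(cfg, seed=seed)
    gt.stages = stage_windows
    gt.day_s = day_s
    return eeg, emg, movement, gt
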