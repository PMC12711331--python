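"""Seizure detection, PGES measurement, PEA onset, disease staging."""

import numpy as np
import pytest

from epivent import (
    Interval,
    SeizureEvent,
    TimeSeries,
    detect_pea_onset,
    detect_seizures,
    generate_recording,
    measure_pges,
    SimConfig,
    stage_recording,
)
from epivent.eeg import power_series, stage_label_at
from epivent.errors import InsufficientDataError
from tests.conftest import oracle_pea, oracle_pges


class TestDetectSeizures:
    def test_stationary_noise_is_clean(self):
        rng = np.random.default_rng(0)
        eeg = TimeSeries("EEG", 250.0, rng.standard_normal(int(600 * 250)))
        assert detect_seizures(eeg) == []

    def test_programmed_burst_recovered_with_tight_edges(self):
        cfg = SimConfig(duration=600.0, seed=4,
                        seizure_schedule=((300.0, 20.0, 3.0, 8.0),),
                        pges_durations=(0.0,))
        eeg, _, mv, gt = generate_recording(cfg)
        ev = detect_seizures(eeg, mv)
        assert len(ev) == 1
        assert ev[0].start == pytest.approx(300.0, abs=1.0)
        assert ev[0].end == pytest.approx(320.0, abs=1.0)
        assert ev[0].peak_ratio > 2.0

    def test_duration_rule_keeps_only_longer_than_10s(self):
        cfg = SimConfig(duration=900.0, seed=6,
                        seizure_schedule=((200.0, 8.0, 3.0, 8.0),
                                          (500.0, 12.0, 3.0, 8.0)),
                        pges_durations=(0.0, 0.0))
        eeg, _, mv, _ = generate_recording(cfg)
        ev = detect_seizures(eeg, mv)
        assert len(ev) == 1
        assert abs(ev[0].start - 500.0) < 2.0

    def test_too_short_recording_rejected(self):
        eeg = TimeSeries("EEG", 250.0, np.zeros(250 * 30))
        with pytest.raises(InsufficientDataError):
            detect_seizures(eeg)


def _suppression_trace(
    seed=0, rate=250.0, dur=400.0, supp=(120.0, 320.0), exc=None, supp_gain=0.05
):
    """Broadband noise with a suppressed stretch; optional excursion back to
    baseline amplitude inside the suppression."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(int(dur * rate))
    t = np.arange(x.size) / rate
    mask = (t >= supp[0]) & (t < supp[1])
    x[mask] *= supp_gain
    if exc is not None:
        sel = (t >= exc[0]) & (t < exc[1])
        x[sel] /= supp_gain
    return TimeSeries("EEG", rate, x)


SEIZ = SeizureEvent(100.0, 120.0, 20.0, 3.0)


class TestMeasurePGES:
    def test_no_suppression_gives_zero(self):
        eeg = _suppression_trace(supp=(0.0, 0.0))
        assert measure_pges(eeg, SEIZ).duration == 0.0

    def test_clean_recovery_measured_to_programmed_duration(self):
        errs = []
        for seed in range(4):
            cfg = SimConfig(duration=600.0, seed=seed,
                            seizure_schedule=((200.0, 20.0, 3.0, 8.0),),
                            pges_durations=(30.0,))
            eeg, _, mv, _ = generate_recording(cfg)
            (s,) = detect_seizures(eeg, mv)
            g = measure_pges(eeg, s, exclude=[s.interval])
            errs.append(g.duration - 30.0)
        assert max(abs(e) for e in errs) <= 1.0

    def test_four_second_excursion_does_not_terminate(self):
        eeg = _suppression_trace(seed=1, exc=(150.0, 154.0))
        g = measure_pges(eeg, SEIZ)
        assert g.duration > 150.0  # runs to the real recovery at 320 s

    def test_five_second_excursion_terminates(self):
        eeg = _suppression_trace(seed=1, exc=(150.0, 155.0))
        g = measure_pges(eeg, SEIZ)
        assert 25.0 < g.duration < 40.0

    def test_deeper_suppression_never_shortens_duration(self):
        base = None
        for gain in (0.3, 0.15, 0.05):
            eeg = _suppression_trace(seed=2, supp=(120.0, 220.0), supp_gain=gain)
            d = measure_pges(eeg, SEIZ).duration
            if base is not None:
                assert d >= base - 1.0
            base = d

    def test_insufficient_preictal_rejected(self):
        eeg = _suppression_trace()
        with pytest.raises(InsufficientDataError):
            measure_pges(eeg, SeizureEvent(50.0, 70.0, 20.0, 3.0))

    def test_matches_bruteforce_endpoint_scan(self):
        """Naive scan over every candidate endpoint on short traces."""
        for seed in range(6):
            exc = (150.0, 150.0 + [0.0, 3.0, 6.0][seed % 3]) if seed % 2 else None
            eeg = _suppression_trace(seed=seed, dur=360.0, supp=(120.0, 300.0), exc=exc)
            g = measure_pges(eeg, SEIZ)
            expect = oracle_pges(eeg, SEIZ)
            assert g.duration == pytest.approx(expect, abs=0.06)


class TestPEAOnset:
    def test_empty_list_absent(self):
        assert detect_pea_onset([], 3600.0) is None

    def test_regular_three_minute_seizures_onset_at_first(self):
        seiz = [SeizureEvent(t, t + 20.0, 20.0, 3.0) for t in np.arange(100.0, 3500.0, 180.0)]
        assert detect_pea_onset(seiz, 3600.0) == 100.0

    def test_alternating_long_gaps_absent(self):
        times, t = [], 100.0
        for k in range(12):
            times.append(t)
            t += 20.0 + (180.0 if k % 2 == 0 else 1200.0)
        seiz = [SeizureEvent(t0, t0 + 20.0, 20.0, 3.0) for t0 in times]
        assert detect_pea_onset(seiz, t + 100.0) is None

    def test_run_scan_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t, times = 0.0, []
            for _ in range(rng.integers(3, 25)):
                times.append(t)
                t += 20.0 + float(rng.choice([120.0, 250.0, 400.0, 900.0]))
            end = t + float(rng.uniform(0, 600))
            seiz = [SeizureEvent(t0, t0 + 20.0, 20.0, 3.0) for t0 in times]
            got = detect_pea_onset(seiz, end)
            expect = oracle_pea(seiz, end)
            assert got == expect


class TestStaging:
    def test_quiet_recording_is_single_stage_zero(self):
        st = stage_recording([], None, None, end_time=3600.0)
        assert len(st) == 1 and st[0].label == "0"

    def test_daily_bins(self):
        day = 86400.0
        seiz = [SeizureEvent(1000.0 + k * 3600, 0, 20.0, 3.0) for k in range(7)]
        for s in seiz:
            s.end = s.start + 20.0
        st = stage_recording(seiz, pea_onset=2 * day, death_time=None)
        assert st[0].label == "6-10"
        assert st[1].label == "0"

    def test_death_one_hour_after_pea_truncates_early_window(self):
        st = stage_recording([], pea_onset=10 * 3600.0, death_time=11 * 3600.0)
        early = [s for s in st if s.label == "early_PEA"][0]
        late = [s for s in st if s.label == "late_PEA"][0]
        assert early.interval.end == 11 * 3600.0  # truncated at death
        # overlap resolved in favor of late_PEA
        assert stage_label_at(st, 10.5 * 3600.0) == "late_PEA"
        assert late.interval.start == 10 * 3600.0  # capped at PEA onset
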