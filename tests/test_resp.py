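"""Apnea/sigh classification rules and respiratory summary metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epivent import (
    Interval,
    MovementMask,
    detect_apneas,
    detect_sighs,
    frequency_zscore,
    segment_summary,
    select_stable_segment,
)
from epivent.errors import InsufficientDataError, ParameterError, SegmentError
from tests.conftest import make_breaths, oracle_apneas, oracle_sighs

ONE_STATE = lambda t: "NREM"


class TestSighRule:
    def test_constant_train_has_no_sighs(self):
        br = make_breaths([0.25] * 40)
        assert detect_sighs(br, ONE_STATE) == []

    def test_exactly_twice_trailing_mean_is_flagged(self):
        peaks = [1.0] * 12 + [2.0]
        br = make_breaths([0.25] * 12, peaks)
        ev = detect_sighs(br, ONE_STATE)
        assert len(ev) == 1 and ev[0].ratio == pytest.approx(2.0)
        # just below threshold: not a sigh
        peaks[-1] = 1.99
        assert detect_sighs(make_breaths([0.25] * 12, peaks), ONE_STATE) == []

    def test_sighs_excluded_from_later_baselines(self):
        # a sigh must not inflate the baseline and mask the next sigh
        peaks = [1.0] * 12 + [2.5] + [1.0] * 4 + [2.0]
        br = make_breaths([0.25] * 17, peaks)
        ev = detect_sighs(br, ONE_STATE)
        assert [round(e.ratio, 2) for e in ev] == [2.5, 2.0]

    def test_needs_five_same_state_breaths(self):
        br = make_breaths([0.25] * 4, [1.0, 1.0, 1.0, 1.0, 5.0])
        assert detect_sighs(br, ONE_STATE) == []


class TestApneaRule:
    def test_uniform_train_has_no_apneas(self):
        br = make_breaths([0.25] * 40)
        assert detect_apneas(br, ONE_STATE, []) == []

    def test_threshold_boundary_inclusive(self):
        periods = [0.25] * 11 + [0.625]  # exactly 2.5x the trailing mean
        br = make_breaths(periods + [0.25])
        ev = detect_apneas(br, ONE_STATE, [])
        assert len(ev) == 1 and ev[0].kind == "apnea"
        assert ev[0].ratio == pytest.approx(2.5)
        periods[-1] = 0.6225  # 2.49x
        assert detect_apneas(make_breaths(periods + [0.25]), ONE_STATE, []) == []

    def test_postsigh_window_boundary(self):
        # identical pauses, 5 s vs 9 s after a sigh
        def run(lag):
            periods = [0.25] * 12
            peaks = [1.0] * 12 + [2.5]
            # sigh breath, then normal breaths until the pause starts `lag`
            # seconds after the sigh's burst end
            n_fill = int(round(lag / 0.25)) - 1
            periods = periods + [0.25] * (n_fill + 1)
            peaks = peaks + [1.0] * (n_fill + 1)
            periods.append(0.75)  # 3x pause
            peaks.append(1.0)
            br = make_breaths(periods, peaks + [1.0])
            sighs = detect_sighs(br, ONE_STATE)
            assert len(sighs) == 1
            ev = detect_apneas(br, ONE_STATE, sighs)
            assert len(ev) == 1
            return ev[0].kind

        assert run(5.0) == "postsigh_apnea"
        assert run(9.0) == "apnea"

    def test_state_isolation(self):
        """Breaths of other states never influence classification."""
        periods = [0.25] * 30
        states = ["NREM"] * 15 + ["REM_IW"] * 16
        br = make_breaths(periods)
        br[20].period = 0.625  # 2.5x within REM breaths
        ev1 = detect_apneas(br, states, [])
        # perturb the NREM breaths wildly; REM classification must not move
        br2 = [b for b in br]
        for i in range(10):
            br2[i].period = 3.0
        ev2 = detect_apneas(br2, states, [])
        t1 = [e.time for e in ev1 if e.state == "REM_IW"]
        t2 = [e.time for e in ev2 if e.state == "REM_IW"]
        assert t1 == t2 and len(t1) == 1


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_detectors_match_bruteforce_oracle(seed):
    """Seeded irregular trains: implementation == quadratic trailing scan."""
    rng = np.random.default_rng(seed)
    n = 250
    periods = rng.uniform(0.2, 0.3, n - 1)
    # inject long pauses and large breaths at random spots
    for i in rng.integers(20, n - 2, 4):
        periods[i] *= rng.uniform(2.0, 4.0)
    peaks = rng.lognormal(0.0, 0.1, n)
    for i in rng.integers(20, n - 1, 3):
        peaks[i] *= rng.uniform(1.8, 3.0)
    states = ["NREM" if (i // 40) % 2 == 0 else "REM_IW" for i in range(n)]
    br = make_breaths(periods, peaks)

    sighs = detect_sighs(br, states)
    ap = detect_apneas(br, states, sighs)
    o_sighs = oracle_sighs(br, states)
    o_ap = oracle_apneas(br, states, o_sighs)

    assert [round(s.time, 6) for s in sighs] == [
        round(br[i].onset, 6) for i in o_sighs
    ]
    assert [(round(a.time, 6), a.kind == "postsigh_apnea") for a in ap] == [
        (round(br[i].onset, 6), ps) for i, ps in o_ap
    ]


class TestSegmentSummary:
    def test_self_normalization_identity(self):
        br = make_breaths([0.25] * 300, peaks=np.full(301, 2.0))
        s = segment_summary(br, Interval(0.0, 60.0), baseline_sigh_amp=2.0)
        assert s.norm_amp == pytest.approx(1.0)
        assert s.cv_freq == pytest.approx(0.0, abs=1e-12)
        assert s.mean_freq == pytest.approx(4.0)

    def test_irregular_train_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        periods = rng.uniform(0.2, 0.4, 299)
        br = make_breaths(periods)
        s = segment_summary(br, Interval(0.0, 60.0), 1.0)
        f = np.array([b.inst_freq for b in br if b.onset < 60.0 and b.inst_freq])
        assert s.mean_freq == pytest.approx(f.mean())
        assert s.cv_freq == pytest.approx(f.std(ddof=1) / f.mean())

    def test_too_few_breaths_flagged_not_silent(self):
        br = make_breaths([0.25] * 5)
        s = segment_summary(br, Interval(0.0, 60.0), 1.0)
        assert s.insufficient and np.isnan(s.mean_freq)

    def test_segment_length_bounds_enforced(self):
        br = make_breaths([0.25] * 100)
        with pytest.raises(ParameterError):
            segment_summary(br, Interval(0.0, 30.0), 1.0)
        segment_summary(br, Interval(0.0, 30.0), 1.0, allow_any_length=True)


class TestFrequencyZscore:
    def test_identities_and_flags(self):
        base = [(float(h * 3600), 4.0 + 0.1 * (h % 3 - 1)) for h in range(6)]
        mu = np.mean([f for _, f in base])
        sd = np.std([f for _, f in base], ddof=1)
        samples = base + [(7 * 3600.0, mu), (8 * 3600.0, mu - sd), (9 * 3600.0, mu - 2.5 * sd)]
        out = frequency_zscore(samples, Interval(0.0, 6 * 3600.0))
        assert out[6].z == pytest.approx(0.0, abs=1e-12)
        assert out[7].z == pytest.approx(-1.0)
        assert out[7].below_1sd and not out[7].below_2sd
        assert out[8].below_2sd
        # direct formula on the whole trajectory
        for t, f in samples:
            z = (f - mu) / sd
            match = [o for o in out if o.time == t]
            assert match[0].z == pytest.approx(z)

    def test_zero_sd_and_short_baseline_rejected(self):
        flat = [(float(h), 4.0) for h in range(6)]
        with pytest.raises(ParameterError):
            frequency_zscore(flat, Interval(0.0, 6.0))
        with pytest.raises(InsufficientDataError):
            frequency_zscore(flat[:2], Interval(0.0, 6.0))


class TestStableSegment:
    def test_uniform_hour_returns_earliest(self):
        br = make_breaths([0.25] * (4 * 3600))
        seg = select_stable_segment(br, Interval(0.0, 3600.0), 60.0)
        assert seg.start == 0.0

    def test_avoids_noisy_patch(self):
        rng = np.random.default_rng(3)
        periods = np.full(2400, 0.25)
        periods[:500] *= rng.uniform(0.6, 1.6, 500)  # irregular start
        br = make_breaths(periods)
        seg = select_stable_segment(br, Interval(0.0, 600.0), 60.0)
        assert seg.start >= 130.0  # clears the irregular patch

    def test_fully_masked_window_is_labeled_absence(self):
        br = make_breaths([0.25] * 2400)
        mask = MovementMask([Interval(0.0, 600.0)])
        with pytest.raises(SegmentError):
            select_stable_segment(br, Interval(0.0, 600.0), 60.0, movement=mask)
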