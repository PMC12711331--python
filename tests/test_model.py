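"""Pipeline orchestration: determinism, report bundle, configuration."""

import dataclasses
import json
import os

import numpy as np
import pandas as pd
import pytest

from epivent import RecordingAnalysis, RunConfig, SimConfig
from epivent.errors import EpiventError
from epivent.simulate import random_event_config


@pytest.fixture(scope="module")
def fitted():
    sim = random_event_config(
        900.0, seed=77, n_apneas=6, n_sighs=6, n_seizures=1,
        seizure_s=20.0, pges_s=15.0,
    )
    model = RecordingAnalysis.from_simulation(sim)
    return model, model.fit()


def test_identical_config_seed_gives_identical_tables(fitted):
    model, res = fitted
    sim = random_event_config(
        900.0, seed=77, n_apneas=6, n_sighs=6, n_seizures=1,
        seizure_s=20.0, pges_s=15.0,
    )
    res2 = RecordingAnalysis.from_simulation(sim).fit()
    pd.testing.assert_frame_equal(res.breaths_frame(), res2.breaths_frame())
    pd.testing.assert_frame_equal(res.events_frame(), res2.events_frame())
    pd.testing.assert_frame_equal(res.epochs_frame(), res2.epochs_frame())
    assert [dataclasses.asdict(s) for s in res.seizures] == [
        dataclasses.asdict(s) for s in res2.seizures
    ]


def test_event_free_simulation_gives_empty_tables_and_stage_zero(tmp_path):
    model = RecordingAnalysis.from_simulation(SimConfig(duration=600.0, seed=2))
    res = model.fit()
    assert res.sighs == [] and res.apneas == [] and res.seizures == []
    assert res.pea_onset is None and res.terminal is None
    assert [s.label for s in res.stages] == ["0"]
    out = tmp_path / "bundle"
    res.save(out)
    for f in ("breaths.csv", "events.csv", "seizures.csv", "pges.csv",
              "epochs.csv", "stages.csv", "summary.csv", "run.log"):
        assert (out / f).exists()
    assert len(pd.read_csv(out / "events.csv")) == 0
    assert pd.read_csv(out / "summary.csv")["stage"].astype(str).tolist() == ["0"]


def test_bundle_and_summary_report_detected_events(fitted, tmp_path):
    model, res = fitted
    assert len(res.seizures) == 1 and len(res.pges) == 1
    text = res.summary()
    assert "seizures: 1" in text
    res.save(tmp_path / "b")
    ev = pd.read_csv(tmp_path / "b" / "events.csv")
    assert set(ev["type"]) == {"resp"}
    assert (ev["start_s"].diff().dropna() >= 0).all()


def test_terminal_bundle_includes_report(tmp_path):
    cfg = SimConfig(duration=600.0, seed=41, terminal=(450.0, 500.0),
                    terminal_tonic_s=1.5)
    res = RecordingAnalysis.from_simulation(cfg).fit()
    assert res.terminal is not None
    assert res.terminal.apnea_before_asystole is True
    res.save(tmp_path / "t")
    data = json.loads((tmp_path / "t" / "terminal.json").read_text())
    assert data["apnea_before_asystole"] is True


def test_runconfig_yaml_round_trip(tmp_path):
    cfg = RunConfig(integrate_window_ms=44.0, r_nrem=1.8)
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(p)
    back = RunConfig.from_yaml(p)
    assert back == cfg


def test_runconfig_rejects_unknown_keys(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("not_a_parameter: 1\n")
    with pytest.raises(EpiventError):
        RunConfig.from_yaml(p)


def test_baseline_sigh_normalization_unit(fitted):
    model, res = fitted
    amp = res.baseline_sigh_amp()
    assert amp > 0
    # a segment of baseline breathing normalized by the sigh amplitude sits
    # well below 1 (sighs are ~2.5x ordinary breaths)
    df = res.stage_summaries()
    assert (df["norm_amp"].dropna() < 1.0).all()


def test_disease_course_escalation_and_terminal_ordering():
    """A compressed disease course shows the full phenotype end to end:
    escalating per-stage seizure counts, interictal apnea rate rising with
    seizure burden, breathing slowing and deepening, PEA detected at its
    scheduled onset, and terminal apnea before asystole."""
    from epivent import generate_disease_course

    stages = [(0, 1.0), (3, 1.0), (8, 1.0), (15, 1.0)]
    eeg, emg, mv, gt = generate_disease_course(
        seed=3, stages=stages, pea_hours=0.4, day_s=7200.0
    )
    cfg = RunConfig(stage_day_s=7200.0, pea_window_s=600.0)
    model = RecordingAnalysis(eeg, emg, mv, cfg)
    res = model.fit()

    assert res.pea_onset == pytest.approx(gt.pea_onset, abs=30.0)

    def apnea_rate(window):
        hours = sum(e.length for e in res.epochs
                    if e.state in ("NREM", "REM_IW")
                    and window.start <= e.start < window.end) / 3600.0
        n = sum(1 for a in res.spontaneous_apneas
                if window.start <= a.time < window.end)
        return n / hours if hours else 0.0

    quiet = gt.stages[0][1]     # 0 seizures/day
    severe = gt.stages[3][1]    # 15 seizures/day
    assert apnea_rate(severe) > 2.0 * apnea_rate(quiet)
    assert apnea_rate(severe) > 6.0

    # breathing slows and deepens across the course
    df = res.stage_summaries()
    first = df.iloc[0]
    late = df[df["stage"] == "late_PEA"].iloc[0]
    assert late["mean_freq_bps"] < 0.85 * first["mean_freq_bps"]
    assert late["norm_amp"] > first["norm_amp"]
    assert late["mean_insp_dur_s"] > first["mean_insp_dur_s"]

    assert res.terminal is not None
    assert res.terminal.apnea_before_asystole is True
    assert res.terminal.pattern == "tonic_burst"
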