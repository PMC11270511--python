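"""Cohort model interface, screening, pipeline determinism and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest

from perisacc.model import SubjectEpochs, screen_subjects
from perisacc.pipeline import RunConfig, process_subject
from perisacc.epochs import EpochSet


def test_screening_threshold():
    acc = np.array([0.60, 0.50, 0.52, 0.519])
    included = screen_subjects(acc, threshold=0.52)
    assert included.tolist() == [0, 2]
    assert screen_subjects(acc, threshold=0.0).tolist() == [0, 1, 2, 3]


def test_subject_epochs_split():
    md = pd.DataFrame(
        {
            "condition": [
                "fixation",
                "control",
                "saccade_peripheral",
                "saccade_central",
                "fixation",
            ],
            "is_catch": [False, False, False, False, True],
            "location_id": [1, 5, 6, 2, 3],
            "fixation_side": ["left"] * 5,
        }
    )
    eps = EpochSet(np.zeros((5, 4, 10)), np.arange(10) / 256.0, 256.0, "stimulus_onset", md)
    sub = SubjectEpochs.from_epochset(eps)
    assert sub.fixation.n_trials == 1  # the catch trial is excluded
    assert sub.control.n_trials == 1
    assert sub.peripheral.n_trials == 1
    assert sub.central.n_trials == 1


def test_config_json_roundtrip(tmp_path):
    cfg = RunConfig(seed=3, n_subjects=4, forward={"remap_gain_uv": 0.0})
    path = tmp_path / "cfg.json"
    cfg.to_json(path)
    back = RunConfig.from_json(path)
    assert back == cfg


def test_forward_model_per_subject_topographies():
    cfg = RunConfig(seed=0)
    fm0 = cfg.forward_model(0)
    fm1 = cfg.forward_model(1)
    assert fm0.topography_seed != fm1.topography_seed
    assert not np.allclose(fm0.topographies(), fm1.topographies())
    cfg2 = RunConfig(seed=0, subject_topographies=False)
    assert np.allclose(
        cfg2.forward_model(0).topographies(), cfg2.forward_model(1).topographies()
    )


def test_subject_processing_is_deterministic():
    """Same config and subject index: identical epochs and gating."""
    cfg = RunConfig(seed=5, n_subjects=1)
    a = process_subject(cfg, 0)
    b = process_subject(cfg, 0)
    np.testing.assert_array_equal(a.epochs.fixation.data, b.epochs.fixation.data)
    pd.testing.assert_frame_equal(a.schedule, b.schedule)
    pd.testing.assert_frame_equal(a.rejection.table, b.rejection.table)
    # different subject index gives different data
    c = process_subject(cfg, 1)
    assert not np.array_equal(
        a.epochs.fixation.data[: c.epochs.fixation.n_trials],
        c.epochs.fixation.data[: a.epochs.fixation.n_trials],
    )


def test_effect_run_outputs_complete(effect_run):
    """The full run yields every result table/series the report needs."""
    results, manifest = effect_run
    n_sub = manifest["n_subjects"]
    assert results.fixation_cv.accuracy.shape[0] == n_sub
    assert results.sliding_accuracy.shape == (n_sub, 26, len(results.times))
    assert results.bf_control is not None
    assert set(results.bf_bins) == {"short", "medium", "long"}
    assert results.sliding_mask.shape == (26, len(results.times))
    frames = results.to_frames()
    assert {"fixation_cv", "control", "central", "ssoa_bins"} <= set(frames)
    bf = results.bf_frame()
    assert {"fixation_cv", "control", "bin_short", "central"} <= set(bf["series"])
    assert (bf["bf"].dropna() > 0).all()
    summary = results.summary()
    assert "fixation CV peak" in summary and "Short-Bin" in summary


def test_effect_run_keeps_most_trials(effect_run):
    results, manifest = effect_run
    kept = np.array(manifest["trials_kept_per_subject"])
    assert (kept >= 0.9 * 480).all()
    assert manifest["subjects_included_after_screening"] == list(range(len(kept)))
    assert np.array(manifest["components_rejected_per_subject"]).min() >= 1


def test_cli_stagewise_flow(tmp_path):
    """simulate -> preprocess -> decode -> infer -> report through the
    output directory (single subject)."""
    from click.testing import CliRunner

    from perisacc.cli import main

    out = tmp_path / "stages"
    cfg = RunConfig(seed=3, n_subjects=1, out_dir=str(out))
    cfg_path = tmp_path / "cfg.json"
    cfg.to_json(cfg_path)
    runner = CliRunner()
    for cmd in ("simulate", "preprocess", "decode", "infer", "report"):
        res = runner.invoke(main, [cmd, "--config", str(cfg_path)])
        assert res.exit_code == 0, f"{cmd}: {res.output}"
    assert (out / "subject_00" / "trials.csv").exists()
    assert (out / "subject_00" / "epochs_fixation" / "data.npy").exists()
    assert (out / "decode_results.npz").exists()
    assert (out / "bayes_factors.csv").exists()
    assert (out / "report.json").exists()


def test_cli_run_all_writes_outputs(tmp_path):
    """End-to-end CLI smoke run (single subject, inference included)."""
    from click.testing import CliRunner

    from perisacc.cli import main

    out = tmp_path / "run"
    cfg = RunConfig(seed=2, n_subjects=1, out_dir=str(out))
    cfg_path = tmp_path / "cfg.json"
    cfg.to_json(cfg_path)
    runner = CliRunner()
    res = runner.invoke(main, ["run-all", "--config", str(cfg_path)])
    assert res.exit_code == 0, res.output
    for fname in (
        "manifest.json",
        "summary.txt",
        "fixation_cv.csv",
        "bayes_factors.csv",
        "rejection_report.csv",
        "config.json",
    ):
        assert (out / fname).exists()
    man = json.loads((out / "manifest.json").read_text())
    assert man["seed"] == 2
    frame = pd.read_csv(out / "fixation_cv.csv")
    assert set(frame.columns) >= {
        "subject",
        "comparison",
        "comparison_class",
        "time_s",
        "accuracy",
    }
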