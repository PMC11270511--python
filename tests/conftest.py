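"""Shared fixtures.

The two cohort fixtures run the full pipeline (simulation through
inference) once per session at the study's desk-scale conditions: 10
synthetic subjects, one 480-trial block each, fixed seed — once with the
remapping effect at its default strength and once with it disabled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from perisacc.forward import ForwardModel
from perisacc.geometry import build_stimulus_layout
from perisacc.pipeline import RunConfig, run_pipeline
from perisacc.schedule import build_trial_schedule

COHORT_SEED = 7


@pytest.fixture(scope="session")
def layout():
    return build_stimulus_layout()


@pytest.fixture(scope="session")
def small_schedule():
    """One desk-scale session block (480 trials)."""
    return build_trial_schedule(1, seed=11, blocks_per_session=1)


@pytest.fixture(scope="session")
def effect_run():
    """Full pipeline on 10 subjects with the remapping effect injected."""
    cfg = RunConfig(seed=COHORT_SEED, n_subjects=10)
    results, manifest = run_pipeline(cfg, write=False)
    return results, manifest


@pytest.fixture(scope="session")
def null_run():
    """Full pipeline on 10 subjects with the remapping effect disabled."""
    cfg = RunConfig(
        seed=COHORT_SEED, n_subjects=10, forward={"remap_gain_uv": 0.0}
    )
    results, manifest = run_pipeline(cfg, write=False)
    return results, manifest


def make_gaussian_epochs(
    n_per_loc: int,
    locations,
    topographies: np.ndarray,
    kernel,
    times: np.ndarray,
    noise_sd: float,
    seed: int,
    fixation_side: str = "left",
):
    """Small synthetic EpochSet: kernel x topography + white noise."""
    from perisacc.epochs import EpochSet

    rng = np.random.default_rng(seed)
    n_ch = topographies.shape[1]
    rows, data = [], []
    k = kernel(times)
    for loc in locations:
        for _ in range(n_per_loc):
            x = np.outer(topographies[loc], k)
            x = x + rng.normal(0, noise_sd, (n_ch, len(times)))
            data.append(x)
            rows.append(
                {
                    "location_id": loc,
                    "fixation_side": fixation_side,
                    "condition": "fixation",
                    "is_catch": False,
                }
            )
    return EpochSet(
        np.stack(data),
        times,
        256.0,
        "stimulus_onset",
        pd.DataFrame(rows),
    )
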