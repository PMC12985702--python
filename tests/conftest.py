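"""Shared fixtures.

The expensive session fixture ``seed_runs`` executes the full two-stage
pipeline (synthetic study, base training, fine-tuning) for three seeds;
tests that probe end-to-end behavior share it instead of re-training.
"""

from __future__ import annotations

import numpy as np
import pytest

from endobleed import pipeline as pl
from endobleed import scene_synth as ss
from endobleed.config import test_profile


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_scene():
    """One 128 px mixed scene (plume + vessel + bone)."""
    return ss.make_scene(
        ss.SceneParams(
            image_size=128, plume_area_frac=0.25, vessel_on=True, bone_on=True,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def seed_runs():
    """Three full two-stage pipeline runs on the desk-scale profile."""
    runs = []
    for seed in (11, 12, 13):
        cfg = test_profile(seed)
        study = pl.generate_study(cfg)
        base, ft = pl.run_two_stage(cfg, study)
        runs.append({"cfg": cfg, "study": study, "base": base, "ft": ft})
    return runs


@pytest.fixture(scope="session")
def eval_report(seed_runs):
    """Evaluation protocol applied to the first seed's fine-tuned model."""
    run = seed_runs[0]
    return pl.evaluate_checkpoint(run["ft"].checkpoint, run["study"], run["cfg"])
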