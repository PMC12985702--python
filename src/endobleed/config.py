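"""Run configuration and the paper/test execution profiles.

The ``paper`` profile pins the published pipeline constants (512 px
inputs, 2 fps extraction, 1% red-area filter, HSV thresholds, lr 1e-4,
batch 4, patience 20/10, 120 red-mask + 230 zero-mask curated images).
The ``test`` profile only shrinks scale — image size and dataset counts
— so the full workflow runs on a desktop CPU in minutes; thresholds,
loss, optimizer and early-stopping rules are identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model_core import ModelSpec, TrainConfig


@dataclass
class RunConfig:
    profile: str = "test"
    seed: int = 0
    image_size: int = 128
    frame_rate: float = 2.0
    min_red_ratio: float = 0.01
    # synthetic study sizes
    n_train_scenes: int = 50
    val_frac: float = 0.1
    n_curated_bleeding: int = 120
    n_curated_zero: int = 230
    n_monitor_mixed: int = 12
    n_monitor_distractor: int = 3
    n_eval_images: int = 30
    n_distractor_eval: int = 20
    n_raters: int = 5
    panel_k: int = 3
    video_frames: int = 20
    video_growth: float = 0.02
    train: TrainConfig = field(default_factory=TrainConfig)
    model: ModelSpec = field(default_factory=ModelSpec)

    def __post_init__(self) -> None:
        if self.profile not in ("paper", "test"):
            raise ValueError("profile must be 'paper' or 'test'")


def paper_profile(seed: int = 0) -> RunConfig:
    """Published constants at full scale."""
    return RunConfig(
        profile="paper",
        seed=seed,
        image_size=512,
        n_train_scenes=2000,
        n_curated_bleeding=120,
        n_curated_zero=230,
        n_monitor_mixed=40,
        n_monitor_distractor=10,
        n_eval_images=60,
        n_distractor_eval=40,
        train=TrainConfig(input_size=512, seed=seed),
        model=ModelSpec(input_size=512),
    )


def test_profile(seed: int = 0) -> RunConfig:
    """Desk-scale profile: same formulas and constants, smaller everything."""
    return RunConfig(
        profile="test",
        seed=seed,
        image_size=128,
        train=TrainConfig(
            input_size=128, max_epochs=250, pixels_per_image=2000, seed=seed
        ),
        model=ModelSpec(input_size=128),
    )


def make_config(profile: str = "test", seed: int = 0) -> RunConfig:
    return paper_profile(seed) if profile == "paper" else test_profile(seed)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    train = raw.pop("train", {})
    model = raw.pop("model", {})
    for key in ("feature_scales", "texture_scales", "hidden"):
        if key in model:
            model[key] = tuple(model[key])
    return RunConfig(train=TrainConfig(**train), model=ModelSpec(**model), **raw)
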