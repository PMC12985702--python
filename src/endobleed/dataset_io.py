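"""Frame extraction, preprocessing, augmentation and leakage-safe splits.

Videos are handled as numbered-frame directories (frame_000000.png, ...)
with a small JSON sidecar carrying the native frame rate; the
:class:`FrameVideo` container is the in-memory equivalent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .weak_labels import rgb_to_hsv, hsv_to_rgb

IMAGENET_MEANS = (0.485, 0.456, 0.406)
IMAGENET_SDS = (0.229, 0.224, 0.225)


class LeakageError(ValueError):
    """Raised when a source id would appear on both sides of a split."""


@dataclass
class FrameVideo:
    """An in-memory video: a list of RGB frames plus the native fps."""

    frames: list[np.ndarray]
    fps: float

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("video must contain at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Seconds spanned by the frame timestamps, (n-1)/fps."""
        return (len(self.frames) - 1) / self.fps

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(self.frames):
            Image.fromarray(frame).save(directory / f"frame_{i:06d}.png")
        (directory / "video.json").write_text(
            json.dumps({"fps": self.fps, "n_frames": len(self.frames)})
        )

    @classmethod
    def load(cls, directory: str | Path) -> "FrameVideo":
        directory = Path(directory)
        meta_path = directory / "video.json"
        if not meta_path.exists():
            raise IOError(f"{directory}: not a frame-directory video (video.json missing)")
        meta = json.loads(meta_path.read_text())
        paths = sorted(directory.glob("frame_*.png"))
        if len(paths) != meta["n_frames"]:
            raise IOError(
                f"{directory}: expected {meta['n_frames']} frames, found {len(paths)}"
            )
        frames = [np.asarray(Image.open(p).convert("RGB")) for p in paths]
        return cls(frames=frames, fps=float(meta["fps"]))


@dataclass(frozen=True)
class NormalizationSpec:
    """Scale 8-bit RGB to [0,1] then standardize per channel."""

    channel_means: tuple[float, float, float] = IMAGENET_MEANS
    channel_sds: tuple[float, float, float] = IMAGENET_SDS


@dataclass(frozen=True)
class AugmentSpec:
    """Joint geometric / image-only photometric augmentation parameters."""

    hflip_prob: float = 0.5
    brightness_delta_frac: float = 0.2
    saturation_delta_frac: float = 0.2
    seed: int = 0


@dataclass
class CuratedSample:
    """One fine-tuning example: a definite-bleeding red mask or a zero mask.

    Zero masks attach an all-negative target to an image whose red
    structures (vessels, cancellous bone) are *not* bleeding, teaching
    the model to suppress them.
    """

    image: np.ndarray
    mask: np.ndarray
    label_class: str  # "bleeding_red_mask" | "zero_mask"
    annotator_id: str
    source_id: str

    def __post_init__(self) -> None:
        if self.label_class not in ("bleeding_red_mask", "zero_mask"):
            raise ValueError(f"unknown label_class {self.label_class!r}")
        any_pos = bool(np.asarray(self.mask).any())
        if self.label_class == "zero_mask" and any_pos:
            raise ValueError("zero_mask sample must have an all-negative mask")
        if self.label_class == "bleeding_red_mask" and not any_pos:
            raise ValueError("bleeding_red_mask sample must have a non-empty mask")


def extract_frames(video: FrameVideo, rate: float = 2.0) -> list[np.ndarray]:
    """Sample frames at target timestamps k/rate, k = 0, 1, ...

    The number of samples is floor(duration * rate) + 1, capped at the
    frame count; each timestamp maps to the nearest native frame.  When
    ``rate`` equals the native fps every frame is returned exactly once.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    n = len(video)
    n_out = min(math.floor(video.duration * rate + 1e-9) + 1, n)
    out = []
    for k in range(n_out):
        idx = int(round(k / rate * video.fps))
        out.append(video.frames[min(idx, n - 1)])
    return out


def resize_pair(
    image: np.ndarray, mask: np.ndarray, size: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Resize an image (bilinear) and its mask (nearest, stays binary)."""
    image = np.asarray(image)
    mask = np.asarray(mask).astype(bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes disagree")
    if image.shape[:2] == (size, size):
        return image, mask
    out_img = _sk_resize(
        image, (size, size), order=1, preserve_range=True, anti_aliasing=True
    )
    out_mask = _sk_resize(
        mask.astype(np.uint8), (size, size), order=0, preserve_range=True,
        anti_aliasing=False,
    )
    return np.clip(np.round(out_img), 0, 255).astype(np.uint8), out_mask.astype(bool)


def normalize(image: np.ndarray, spec: NormalizationSpec | None = None) -> np.ndarray:
    """(pixel/255 - mean_c) / sd_c per channel, float64 output."""
    spec = spec or NormalizationSpec()
    x = np.asarray(image, dtype=np.float64) / 255.0
    return (x - np.array(spec.channel_means)) / np.array(spec.channel_sds)


def denormalize(array: np.ndarray, spec: NormalizationSpec | None = None) -> np.ndarray:
    """Inverse of :func:`normalize`, back to 8-bit RGB."""
    spec = spec or NormalizationSpec()
    x = np.asarray(array) * np.array(spec.channel_sds) + np.array(spec.channel_means)
    return np.clip(np.round(x * 255.0), 0, 255).astype(np.uint8)


def augment(
    image: np.ndarray, mask: np.ndarray, spec: AugmentSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded horizontal flip (joint) plus brightness/saturation jitter
    (image only).  The mask is never photometrically altered."""
    rng = np.random.default_rng(spec.seed)
    image = np.asarray(image)
    mask = np.asarray(mask).astype(bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes disagree")

    if rng.random() < spec.hflip_prob:
        image = image[:, ::-1]
        mask = mask[:, ::-1]

    if spec.brightness_delta_frac > 0:
        factor = 1.0 + rng.uniform(-spec.brightness_delta_frac, spec.brightness_delta_frac)
        image = np.clip(np.round(image.astype(np.float64) * factor), 0, 255).astype(
            np.uint8
        )
    if spec.saturation_delta_frac > 0:
        factor = 1.0 + rng.uniform(-spec.saturation_delta_frac, spec.saturation_delta_frac)
        hsv = rgb_to_hsv(image)
        sat = np.clip(hsv.saturation.astype(np.float64) * factor, 0, 255)
        image = hsv_to_rgb(hsv.hue, sat, hsv.value)
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def split_by_source(
    pairs: Sequence, val_frac: float, seed: int = 0
) -> tuple[list, list]:
    """Split at the source-video level so no source leaks across partitions.

    Each element must expose a ``source_id`` attribute.  Both partitions
    receive at least one source.
    """
    sources = sorted({p.source_id for p in pairs})
    if len(sources) < 2:
        raise LeakageError("need at least 2 distinct source_ids to split")
    rng = np.random.default_rng(seed)
    order = [sources[i] for i in rng.permutation(len(sources))]
    n_val = int(np.clip(round(val_frac * len(sources)), 1, len(sources) - 1))
    val_sources = set(order[:n_val])
    train = [p for p in pairs if p.source_id not in val_sources]
    val = [p for p in pairs if p.source_id in val_sources]
    return train, val


def write_manifest(path: str | Path, rows: Sequence[dict]) -> None:
    """Write a CSV manifest (paths, source_id, label_class, ratio, ...)."""
    pd.DataFrame(list(rows)).to_csv(Path(path), index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
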