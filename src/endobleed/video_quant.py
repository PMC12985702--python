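"""Frame-by-frame bleeding quantification of endoscopic video.

Runs the segmentation model over every frame, records the bleeding-area
ratio as a time series, renders a three-panel composite (original
footage | segmentation overlay | ratio plot) and measures inference
throughput.  The ratio denominator defaults to the full frame (every
pixel); a field-of-view denominator is available because the clinically
relevant fraction is the share of the *visible* field that is obscured.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as _draw_line

from .dataset_io import FrameVideo, resize_pair
from .weak_labels import rgb_to_hsv, fov_mask, DegenerateFrameError
from . import model_core

logger = logging.getLogger(__name__)

DENOMINATOR_MODES = ("full_frame", "fov")


@dataclass(frozen=True)
class ThroughputReport:
    """Mean inference speed over processed frames (warmup excluded)."""

    fps: float
    latency_ms: float
    resolution: tuple[int, int]
    n_frames: int


def _as_predictor(model_or_ckpt) -> Callable[[np.ndarray], np.ndarray]:
    """Accept a model, checkpoint, or a mask-valued callable."""
    if callable(model_or_ckpt) and not isinstance(
        model_or_ckpt, (model_core.PixelSegmenter, model_core.Checkpoint)
    ):
        return model_or_ckpt
    model = model_core._as_model(model_or_ckpt)
    return lambda frame: model_core._sigmoid(model.predict_logits(frame)) > 0.5


def infer_video(
    model_or_ckpt,
    video: FrameVideo,
    denominator_mode: str = "full_frame",
    input_size: int | None = None,
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Per-frame bleeding-area ratio timeline plus the predicted masks.

    Each frame is resized to the model input size, segmented, and the
    ratio |mask| / denominator recorded.  The returned DataFrame has
    columns frame, time_s, ratio_full and ratio_fov; ``ratio`` of the
    selected mode drives the ``ratio`` column.  In ``fov`` mode a frame
    with an empty field of view raises
    :class:`~endobleed.weak_labels.DegenerateFrameError`; in
    ``full_frame`` mode its FOV ratio is recorded as NaN.  Unreadable
    (None) frames are skipped with a logged gap, never silently.
    """
    if denominator_mode not in DENOMINATOR_MODES:
        raise ValueError(f"denominator_mode must be one of {DENOMINATOR_MODES}")
    predict = _as_predictor(model_or_ckpt)
    rows, masks = [], []
    for idx, frame in enumerate(video.frames):
        if frame is None:
            logger.warning("frame %d unreadable; skipping", idx)
            continue
        if input_size is not None and frame.shape[:2] != (input_size, input_size):
            frame, _ = resize_pair(frame, np.zeros(frame.shape[:2], bool), input_size)
        mask = np.asarray(predict(frame)).astype(bool)
        n_px = mask.size
        fov = fov_mask(rgb_to_hsv(frame))
        n_fov = int(fov.sum())
        ratio_full = float(mask.sum()) / n_px
        if n_fov == 0:
            if denominator_mode == "fov":
                raise DegenerateFrameError(f"frame {idx}: empty field of view")
            ratio_fov = np.nan
        else:
            ratio_fov = float((mask & fov).sum()) / n_fov
        rows.append(
            {
                "frame": idx,
                "time_s": idx / video.fps,
                "ratio_full": ratio_full,
                "ratio_fov": ratio_fov,
                "ratio": ratio_full if denominator_mode == "full_frame" else ratio_fov,
            }
        )
        masks.append(mask)
    return pd.DataFrame(rows), masks


def _plot_panel(ratios: Sequence[float], upto: int, size: tuple[int, int]) -> np.ndarray:
    """Ratio-vs-frame polyline up to the current frame, drawn on white."""
    h, w = size
    panel = np.full((h, w, 3), 255, dtype=np.uint8)
    m = 8  # margin
    panel[m, m : w - m] = panel[h - m - 1, m : w - m] = 0
    panel[m : h - m, m] = panel[m : h - m, w - m - 1] = 0
    n = len(ratios)
    if n < 1 or upto < 0:
        return panel

    def to_px(i: int, r: float) -> tuple[int, int]:
        x = m + int(round(i / max(n - 1, 1) * (w - 2 * m - 1)))
        y = (h - m - 1) - int(round(np.clip(r, 0, 1) * (h - 2 * m - 1)))
        return y, x

    pts = [to_px(i, ratios[i]) for i in range(min(upto + 1, n))]
    for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
        rr, cc = _draw_line(y0, x0, y1, x1)
        panel[rr, cc] = (200, 0, 0)
    y, x = pts[-1]
    panel[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2] = (200, 0, 0)
    return panel


def render_composite(
    video: FrameVideo,
    masks: Sequence[np.ndarray],
    timeline: pd.DataFrame,
    out_dir: str | Path,
    alpha: float = 0.45,
) -> FrameVideo:
    """Three-panel composite: footage | overlay | cumulative ratio plot.

    The overlay panel alters only pixels inside the predicted mask
    (semi-transparent red fill plus a solid contour); the frame count
    of the output equals the input's.
    """
    if not (len(video.frames) == len(masks) == len(timeline)):
        raise ValueError("video, masks and timeline lengths disagree")
    ratios = timeline["ratio"].to_numpy()
    out_frames = []
    for idx, (frame, mask) in enumerate(zip(video.frames, masks)):
        overlay = frame.copy()
        fill = np.asarray(mask, dtype=bool)
        if fill.any():
            red = np.array([255, 0, 0], dtype=np.float64)
            overlay[fill] = np.clip(
                np.round((1 - alpha) * frame[fill] + alpha * red), 0, 255
            ).astype(np.uint8)
            contour = fill & ~ndimage.binary_erosion(fill)
            overlay[contour] = (255, 0, 0)
        plot = _plot_panel(ratios, idx, frame.shape[:2])
        out_frames.append(np.concatenate([frame, overlay, plot], axis=1))
    out = FrameVideo(out_frames, video.fps)
    out.save(out_dir)
    return out


def measure_throughput(
    model_or_ckpt, frames: Sequence[np.ndarray], warmup: int = 2
) -> ThroughputReport:
    """Wall-clock mean inference speed; warmup frames are excluded."""
    if warmup >= len(frames):
        raise ValueError("warmup leaves no frames to measure")
    predict = _as_predictor(model_or_ckpt)
    for frame in frames[:warmup]:
        predict(frame)
    t0 = time.perf_counter()
    for frame in frames[warmup:]:
        predict(frame)
    elapsed = time.perf_counter() - t0
    n = len(frames) - warmup
    latency_ms = elapsed / n * 1000.0
    return ThroughputReport(
        fps=n / elapsed,
        latency_ms=latency_ms,
        resolution=tuple(frames[0].shape[:2]),
        n_frames=n,
    )
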