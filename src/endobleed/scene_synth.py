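"""Seeded synthetic endoscopic scenes with per-component truth masks.

Real spinal-endoscopy frames show a bright circular surgical field on a
black lens margin; under continuous irrigation, bleeding appears as
diffuse saturated-red plumes, while two classes of red *distractors* —
thin curvilinear vessels and speckled cancellous-bone patches — share
the same hue band without representing bleeding.  This module renders
that geometry with exact truth masks so that every downstream stage
(weak labelling, training, rater-panel evaluation, video quantification)
can be exercised end to end with known answers.

Colors are drawn strictly inside the red HSV bands for the three red
component classes, and strictly outside them for tissue and background,
so the HSV weak label recovers bleeding ∪ vessel ∪ bone by construction
on these hard-edged scenes.

All randomness flows through one `numpy.random.Generator` per call;
identical parameters and seed give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .weak_labels import hsv_to_rgb, write_mask, read_mask


@dataclass(frozen=True)
class SceneParams:
    """Generation parameters for one synthetic scene.

    plume_area_frac is the target bleeding fraction of the FOV; the
    plume field threshold is found by bisection so the rendered area
    matches it closely.  color_jitter_sd is the per-pixel jitter of
    saturation/value in 8-bit intensity units.
    """

    image_size: int = 512
    fov_radius_frac: float = 0.92
    n_plumes: int = 3
    plume_area_frac: float = 0.15
    vessel_on: bool = False
    bone_on: bool = False
    color_jitter_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if not 0.0 < self.fov_radius_frac <= 1.0:
            raise ValueError("fov_radius_frac must lie in (0,1]")
        if not 0.0 <= self.plume_area_frac <= 1.0:
            raise ValueError("plume_area_frac must lie in [0,1]")
        if self.n_plumes < 0:
            raise ValueError("n_plumes must be >= 0")
        if self.color_jitter_sd < 0:
            raise ValueError("color_jitter_sd must be >= 0")


@dataclass(frozen=True)
class RaterNoise:
    """Annotator-variability model applied to a truth mask.

    dilate_erode_px: systematic over/under-segmentation (signed);
    boundary_jitter_sd: pixel scale of a smooth random boundary warp;
    miss_prob: probability that a connected component smaller than
    miss_area_px pixels is dropped entirely.
    """

    dilate_erode_px: int = 0
    boundary_jitter_sd: float = 0.0
    miss_prob: float = 0.0
    miss_area_px: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_sd < 0:
            raise ValueError("boundary_jitter_sd must be >= 0")
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must lie in [0,1]")


@dataclass
class SyntheticScene:
    """Rendered RGB frame with disjoint per-component truth masks."""

    image: np.ndarray
    bleeding_mask: np.ndarray
    vessel_mask: np.ndarray
    bone_mask: np.ndarray
    fov_truth: np.ndarray
    params: SceneParams

    def validate(self) -> None:
        masks = (self.bleeding_mask, self.vessel_mask, self.bone_mask)
        for m in masks:
            if m.shape != self.fov_truth.shape:
                raise AssertionError("mask shape mismatch")
            if (m & ~self.fov_truth).any():
                raise AssertionError("component mask escapes the FOV")
        if (self.bleeding_mask & self.vessel_mask).any() or (
            (self.bleeding_mask | self.vessel_mask) & self.bone_mask
        ).any():
            raise AssertionError("component masks overlap")
        outside = self.image[~self.fov_truth]
        if outside.size and outside.max() >= 50:
            raise AssertionError("pixels outside the FOV are not near-black")

    @property
    def red_union(self) -> np.ndarray:
        return self.bleeding_mask | self.vessel_mask | self.bone_mask


@dataclass
class SyntheticVideo:
    """Frame sequence with exact per-frame truth bleeding ratios."""

    frames: list[np.ndarray]
    truth_ratios: list[float]
    fps: float
    params: SceneParams


# -- color sampling --------------------------------------------------------
# Red components live strictly inside hue [0,8]∪[172,180) with S>=90,
# V>=50 and also inside the FOV bands (S>60, V>70); margins of 1-2 units
# absorb the +-1 quantization of the HSV->RGB->HSV round trip.
_RED_HUE_LOW = (1, 7)
_RED_HUE_HIGH = (173, 179)
_TISSUE_SAT = (64, 78)  # chromatic but well below the red sat bound of 90


def _fill_component(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    sat_range: tuple[int, int],
    val_range: tuple[int, int],
    jitter_sd: float,
) -> None:
    n = int(mask.sum())
    if n == 0:
        return
    band = _RED_HUE_LOW if rng.random() < 0.5 else _RED_HUE_HIGH
    hue0 = rng.integers(band[0], band[1] + 1)
    sat0 = rng.integers(sat_range[0] + 10, sat_range[1] - 9)
    val0 = rng.integers(val_range[0] + 10, val_range[1] - 9)
    hue = np.clip(hue0 + rng.normal(0, jitter_sd / 4, n), band[0], band[1])
    sat = np.clip(sat0 + rng.normal(0, jitter_sd, n), *sat_range)
    val = np.clip(val0 + rng.normal(0, jitter_sd, n), *val_range)
    image[mask] = hsv_to_rgb(np.round(hue), sat, val)


def _plume_field(
    shape: tuple[int, int],
    fov: np.ndarray,
    n_plumes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sum of anisotropic Gaussian blobs; strictly positive inside FOV."""
    n_px = shape[0]
    yy, xx = np.mgrid[0:n_px, 0:n_px].astype(np.float64)
    c = (n_px - 1) / 2.0
    r_fov = np.sqrt(fov.sum() / np.pi)
    field = np.full(shape, 1e-9)
    for _ in range(max(n_plumes, 0)):
        ang = rng.uniform(0, np.pi)
        cy = c + rng.uniform(-0.55, 0.55) * r_fov
        cx = c + rng.uniform(-0.55, 0.55) * r_fov
        s1 = rng.uniform(0.10, 0.30) * r_fov
        s2 = rng.uniform(0.10, 0.30) * r_fov
        amp = rng.uniform(0.8, 1.2)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(ang) + dx * np.sin(ang)
        v = -dy * np.sin(ang) + dx * np.cos(ang)
        field += amp * np.exp(-0.5 * ((u / s1) ** 2 + (v / s2) ** 2))
    return field


def _threshold_to_area(
    field: np.ndarray, fov: np.ndarray, target_px: int
) -> np.ndarray:
    """Bisection on the field threshold to hit a pixel-count target in FOV."""
    if target_px <= 0:
        return np.zeros(field.shape, dtype=bool)
    vals = field[fov]
    if target_px >= vals.size:
        return fov.copy()
    # kth largest value inside the FOV is the exact threshold
    t = np.partition(vals, vals.size - target_px)[vals.size - target_px]
    return (field >= t) & fov


def _vessel_mask(
    fov: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """2-4 px wide curvilinear tracks from random quadratic Bezier curves."""
    n_px = fov.shape[0]
    c = (n_px - 1) / 2.0
    r_fov = np.sqrt(fov.sum() / np.pi)
    mask = np.zeros(fov.shape, dtype=bool)
    for _ in range(rng.integers(2, 5)):
        pts = c + rng.uniform(-0.8, 0.8, size=(3, 2)) * r_fov
        t = np.linspace(0.0, 1.0, 6 * n_px)[:, None]
        curve = ((1 - t) ** 2) * pts[0] + 2 * t * (1 - t) * pts[1] + t**2 * pts[2]
        iy = np.clip(np.round(curve[:, 0]).astype(int), 0, n_px - 1)
        ix = np.clip(np.round(curve[:, 1]).astype(int), 0, n_px - 1)
        track = np.zeros(fov.shape, dtype=bool)
        track[iy, ix] = True
        width_iter = int(rng.integers(1, 3))  # dilation radius 1-2 -> 2-4 px wide
        track = ndimage.binary_dilation(track, iterations=width_iter)
        mask |= track
    return mask & fov


def _bone_mask(fov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Speckled cancellous-bone patch: random speckle inside an ellipse."""
    n_px = fov.shape[0]
    c = (n_px - 1) / 2.0
    r_fov = np.sqrt(fov.sum() / np.pi)
    yy, xx = np.mgrid[0:n_px, 0:n_px].astype(np.float64)
    cy = c + rng.uniform(-0.5, 0.5) * r_fov
    cx = c + rng.uniform(-0.5, 0.5) * r_fov
    ay = rng.uniform(0.15, 0.30) * r_fov
    ax = rng.uniform(0.15, 0.30) * r_fov
    ellipse = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    speckle = rng.random(fov.shape) < 0.45
    return ellipse & speckle & fov


def _scene_layout(params: SceneParams, rng: np.random.Generator):
    """Static geometry shared by all frames of a video: FOV, field, distractors."""
    n_px = params.image_size
    yy, xx = np.mgrid[0:n_px, 0:n_px].astype(np.float64)
    c = (n_px - 1) / 2.0
    radius = params.fov_radius_frac * n_px / 2.0
    fov = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    field = _plume_field((n_px, n_px), fov, params.n_plumes, rng)
    vessel = _vessel_mask(fov, rng) if params.vessel_on else np.zeros_like(fov)
    bone = _bone_mask(fov, rng) if params.bone_on else np.zeros_like(fov)
    return fov, field, vessel, bone


def _compose(
    params: SceneParams,
    fov: np.ndarray,
    bleeding: np.ndarray,
    vessel: np.ndarray,
    bone: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render the RGB frame from the component masks."""
    n_px = params.image_size
    image = np.zeros((n_px, n_px, 3), dtype=np.uint8)

    # black lens margin: all channels < 30 so V < 50 (never red, never FOV)
    outside = ~fov
    image[outside] = rng.integers(0, 26, size=(int(outside.sum()), 3))

    # tan tissue: chromatic enough for the FOV bands, far from the red sat bound
    tissue = fov & ~(bleeding | vessel | bone)
    n_t = int(tissue.sum())
    if n_t:
        hue = np.clip(15 + rng.normal(0, 3, n_t), 10, 25)
        sat = np.clip(71 + rng.normal(0, params.color_jitter_sd / 2, n_t), *_TISSUE_SAT)
        val = np.clip(150 + rng.normal(0, params.color_jitter_sd * 2, n_t), 100, 210)
        image[tissue] = hsv_to_rgb(np.round(hue), sat, val)

    jit = params.color_jitter_sd
    _fill_component(image, bleeding, rng, (130, 250), (100, 250), jit)
    _fill_component(image, vessel, rng, (150, 250), (80, 170), jit)
    _fill_component(image, bone, rng, (120, 200), (140, 250), jit)
    return image


def make_scene(params: SceneParams) -> SyntheticScene:
    """Render one seeded scene satisfying all component invariants."""
    rng = np.random.default_rng(params.seed)
    fov, field, vessel, bone = _scene_layout(params, rng)
    target = int(round(params.plume_area_frac * fov.sum()))
    if params.n_plumes == 0:
        target = 0
    bleeding = _threshold_to_area(field, fov, target)
    vessel = vessel & ~bleeding
    bone = bone & ~(bleeding | vessel)
    image = _compose(params, fov, bleeding, vessel, bone, rng)
    scene = SyntheticScene(image, bleeding, vessel, bone, fov, params)
    scene.validate()
    return scene


def make_video(
    params: SceneParams,
    n_frames: int,
    growth: float = 0.0,
    fps: float = 2.0,
) -> SyntheticVideo:
    """A frame sequence whose bleeding area follows a growth schedule.

    Frame t targets a bleeding fraction clamp(plume_area_frac + t*growth,
    0, 1); the scene layout (FOV, plume potential field, distractors) is
    fixed across frames so only the plume extent and the photometric
    jitter evolve.  truth_ratios holds the exact pixel-count fraction of
    each frame's bleeding mask within the FOV.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    layout_rng = np.random.default_rng(params.seed)
    fov, field, vessel, bone = _scene_layout(params, layout_rng)
    n_fov = int(fov.sum())

    frames: list[np.ndarray] = []
    ratios: list[float] = []
    for t in range(n_frames):
        frac = float(np.clip(params.plume_area_frac + t * growth, 0.0, 1.0))
        target = int(round(frac * n_fov)) if params.n_plumes else 0
        bleeding = _threshold_to_area(field, fov, target)
        v = vessel & ~bleeding
        b = bone & ~(bleeding | v)
        frame_rng = np.random.default_rng([params.seed, t])
        frames.append(_compose(params, fov, bleeding, v, b, frame_rng))
        ratios.append(float(bleeding.sum()) / n_fov)
    return SyntheticVideo(frames, ratios, fps, params)


def make_rater_mask(truth: np.ndarray, noise: RaterNoise) -> np.ndarray:
    """Simulate one annotator's mask from the truth mask.

    With all noise parameters at zero the truth is returned unchanged.
    Expected Dice against the truth decreases as boundary_jitter_sd
    grows (verified empirically in the test suite).
    """
    truth = np.asarray(truth)
    if truth.dtype != bool and not np.isin(truth, (0, 1)).all():
        raise ValueError("truth mask must be binary")
    truth = truth.astype(bool)
    rng = np.random.default_rng(noise.seed)
    mask = truth.copy()

    if noise.dilate_erode_px > 0:
        mask = ndimage.binary_dilation(mask, iterations=noise.dilate_erode_px)
    elif noise.dilate_erode_px < 0:
        mask = ndimage.binary_erosion(mask, iterations=-noise.dilate_erode_px)

    if noise.boundary_jitter_sd > 0:
        yy, xx = np.mgrid[0 : truth.shape[0], 0 : truth.shape[1]].astype(np.float64)
        warps = []
        for _ in range(2):
            w = ndimage.gaussian_filter(rng.standard_normal(truth.shape), sigma=6)
            sd = w.std()
            warps.append(w / sd * noise.boundary_jitter_sd if sd > 0 else w)
        mask = (
            ndimage.map_coordinates(
                mask.astype(np.float64),
                [yy + warps[0], xx + warps[1]],
                order=1,
                mode="constant",
            )
            > 0.5
        )

    if noise.miss_prob > 0:
        labels, n_comp = ndimage.label(mask)
        if n_comp:
            areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
            drop = (areas < noise.miss_area_px) & (
                rng.random(n_comp) < noise.miss_prob
            )
            if drop.any():
                mask &= ~np.isin(labels, np.flatnonzero(drop) + 1)
    return mask


# -- on-disk layout --------------------------------------------------------


def save_scene(scene: SyntheticScene, directory: str | Path) -> None:
    """Write image.png, the four mask PNGs, and a params.json sidecar."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    Image.fromarray(scene.image).save(directory / "image.png")
    for name in ("bleeding_mask", "vessel_mask", "bone_mask", "fov_truth"):
        write_mask(directory / f"{name}.png", getattr(scene, name))
    (directory / "params.json").write_text(json.dumps(asdict(scene.params), indent=1))


def load_scene(directory: str | Path) -> SyntheticScene:
    from PIL import Image

    directory = Path(directory)
    params = SceneParams(**json.loads((directory / "params.json").read_text()))
    return SyntheticScene(
        image=np.asarray(Image.open(directory / "image.png").convert("RGB")),
        bleeding_mask=read_mask(directory / "bleeding_mask.png"),
        vessel_mask=read_mask(directory / "vessel_mask.png"),
        bone_mask=read_mask(directory / "bone_mask.png"),
        fov_truth=read_mask(directory / "fov_truth.png"),
        params=params,
    )


def scene_variants(base: SceneParams, n: int, seed0: int = 0) -> list[SceneParams]:
    """n copies of ``base`` with consecutive seeds — a convenience for batches."""
    return [replace(base, seed=seed0 + i) for i in range(n)]
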