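"""Trainable bleeding-segmentation model: training, fine-tuning, prediction.

The model is a compact convolutional pixel classifier authored here in
numpy/scipy.  A fixed multiscale feature bank turns each frame into a
stack of per-pixel descriptors — normalized RGB, saturation/value, a
chromatic red score, Gaussian-smoothed red context at several scales,
local red variance (speckle texture), and structure-tensor coherence
(curvilinear texture) — and a small trainable multilayer perceptron
maps every pixel's descriptor to one logit.  The output is a logit map
at input resolution, trained with binary cross-entropy on logits and
the Adam optimizer.

The two training stages mirror the weak-label → fine-tune workflow:
``train_base`` fits the model to HSV weak labels (all red structures
positive) with early stopping on validation loss; ``finetune`` resumes
from the base checkpoint on a curated set of definite-bleeding red
masks and all-negative zero masks, with early stopping on the mean
Dice against a held-out monitoring set.  The smoothed-context and
texture features are what let fine-tuning separate diffuse bleeding
plumes from thin vessels and speckled cancellous bone, which are
indistinguishable by color alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .dataset_io import NormalizationSpec, normalize, denormalize, CuratedSample
from .weak_labels import rgb_to_hsv


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class LeakageError(ValueError):
    """Raised when fine-tuning and monitoring share source ids."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of the pixel classifier.

    feature_scales are the sigmas (pixels) of the Gaussian red-context
    pyramid; texture_scales the sigmas of the local-variance channels;
    hidden the widths of the MLP layers.  The output is always a
    single-channel logit map at input resolution.
    """

    input_size: int = 512
    feature_scales: tuple[float, ...] = (2.0, 4.0, 8.0)
    texture_scales: tuple[float, ...] = (2.0, 4.0)
    hidden: tuple[int, ...] = (16, 16)

    @property
    def n_features(self) -> int:
        return 6 + len(self.feature_scales) + len(self.texture_scales) + 1


@dataclass(frozen=True)
class TrainConfig:
    """Optimization constants shared by base training and fine-tuning."""

    input_size: int = 512
    learning_rate: float = 1e-4
    batch_size: int = 4
    patience_base: int = 20
    patience_finetune: int = 10
    max_epochs: int = 500
    improvement_epsilon: float = 1e-4
    pixels_per_image: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience_base < 0 or self.patience_finetune < 0:
            raise ValueError("patience must be >= 0")


@dataclass
class Checkpoint:
    """Model weights with training provenance.

    Reloading a checkpoint reproduces bit-identical predictions on a
    fixed input (weights are stored as exact float64 arrays).
    """

    weights: dict
    spec: ModelSpec
    epoch: int
    monitored: float
    config_hash: str

    def save(self, path: str | Path) -> None:
        meta = json.dumps(
            {
                "spec": asdict(self.spec),
                "epoch": self.epoch,
                "monitored": self.monitored,
                "config_hash": self.config_hash,
            }
        )
        np.savez(Path(path), __meta__=np.array(meta), **self.weights)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(Path(path)) as data:
            meta = json.loads(str(data["__meta__"]))
            weights = {k: data[k] for k in data.files if k != "__meta__"}
        spec_d = meta["spec"]
        spec_d["feature_scales"] = tuple(spec_d["feature_scales"])
        spec_d["texture_scales"] = tuple(spec_d["texture_scales"])
        spec_d["hidden"] = tuple(spec_d["hidden"])
        return cls(
            weights=weights,
            spec=ModelSpec(**spec_d),
            epoch=meta["epoch"],
            monitored=meta["monitored"],
            config_hash=meta["config_hash"],
        )


@dataclass
class EvalImage:
    """A monitoring/evaluation frame with one or more reference masks."""

    image: np.ndarray
    rater_masks: list
    source_id: str


def config_hash(cfg: TrainConfig, spec: ModelSpec) -> str:
    blob = json.dumps({"cfg": asdict(cfg), "spec": asdict(spec)}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# -- feature bank ----------------------------------------------------------


def extract_features(image_u8: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Per-pixel descriptor stack (H x W x n_features, float32).

    Channels: normalized R,G,B; S/255; V/255; red score; Gaussian red
    context at each feature scale; local red std at each texture scale;
    structure-tensor coherence of the red score.
    """
    norm = normalize(image_u8)
    hsv = rgb_to_hsv(image_u8)
    h = hsv.hue.astype(np.float64)
    s = hsv.saturation.astype(np.float64) / 255.0
    v = hsv.value.astype(np.float64) / 255.0
    dmin = np.minimum(h, 180.0 - h)  # half-degree distance to pure red
    red = np.clip(1.0 - dmin / 12.0, 0.0, 1.0) * s * v

    chans = [norm[..., 0], norm[..., 1], norm[..., 2], s, v, red]
    for sig in spec.feature_scales:
        chans.append(ndimage.gaussian_filter(red, sig))
    for sig in spec.texture_scales:
        m1 = ndimage.gaussian_filter(red, sig)
        m2 = ndimage.gaussian_filter(red * red, sig)
        chans.append(np.sqrt(np.clip(m2 - m1 * m1, 0.0, None)))
    gy = ndimage.gaussian_filter(red, 1.5, order=(1, 0))
    gx = ndimage.gaussian_filter(red, 1.5, order=(0, 1))
    jyy = ndimage.gaussian_filter(gy * gy, 2.5)
    jxx = ndimage.gaussian_filter(gx * gx, 2.5)
    jxy = ndimage.gaussian_filter(gx * gy, 2.5)
    disc = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)
    chans.append(disc / (jxx + jyy + 1e-9))  # coherence in [0,1]
    return np.stack(chans, axis=-1).astype(np.float32)


# -- MLP head --------------------------------------------------------------


class PixelSegmenter:
    """Fixed feature bank + trainable per-pixel MLP producing a logit map."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        sizes = [spec.n_features, *spec.hidden, 1]
        self.weights: dict[str, np.ndarray] = {}
        for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            self.weights[f"W{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)
            )
            self.weights[f"b{i}"] = np.zeros(fan_out)
        self.n_layers = len(sizes) - 1
        # per-channel input standardization, fitted once during base training
        self.feat_mean = np.zeros(spec.n_features)
        self.feat_scale = np.ones(spec.n_features)

    def fit_scaler(self, X: np.ndarray) -> None:
        """Fit the per-channel feature standardization on training pixels.

        The texture and smoothed-context channels are an order of
        magnitude smaller than the color channels; equalizing their
        scales lets the optimizer weight them on equal footing.
        """
        self.feat_mean = X.mean(axis=0)
        self.feat_scale = np.maximum(X.std(axis=0), 1e-3)

    @classmethod
    def from_checkpoint(cls, ckpt: Checkpoint) -> "PixelSegmenter":
        model = cls(ckpt.spec, seed=0)
        weights = {k: v.copy() for k, v in ckpt.weights.items()}
        model.feat_mean = weights.pop("feat_mean")
        model.feat_scale = weights.pop("feat_scale")
        model.weights = weights
        return model

    def forward(self, X: np.ndarray, cache: bool = False):
        a = (X - self.feat_mean) / self.feat_scale
        acts = [a]
        for i in range(self.n_layers):
            z = a @ self.weights[f"W{i}"] + self.weights[f"b{i}"]
            a = z if i == self.n_layers - 1 else np.maximum(z, 0.0)
            acts.append(a)
        logits = acts[-1][:, 0]
        return (logits, acts) if cache else logits

    def backward(self, acts: list, dlogit: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        delta = dlogit[:, None]
        for i in range(self.n_layers - 1, -1, -1):
            grads[f"W{i}"] = acts[i].T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[f"W{i}"].T) * (acts[i] > 0)
        return grads

    def predict_logits(self, image: np.ndarray) -> np.ndarray:
        """Logit map at input resolution for one frame (8-bit or normalized)."""
        u8 = image if image.dtype == np.uint8 else denormalize(image)
        feats = extract_features(u8, self.spec).astype(np.float64)
        h, w, f = feats.shape
        return self.forward(feats.reshape(-1, f)).reshape(h, w)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        return _sigmoid(self.predict_logits(image))

    def checkpoint(
        self, epoch: int, monitored: float, cfg_hash: str
    ) -> Checkpoint:
        return Checkpoint(
            weights={
                **{k: v.copy() for k, v in self.weights.items()},
                "feat_mean": self.feat_mean.copy(),
                "feat_scale": self.feat_scale.copy(),
            },
            spec=self.spec,
            epoch=epoch,
            monitored=monitored,
            config_hash=cfg_hash,
        )


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> PixelSegmenter:
    """Seeded model construction; identical seed gives identical weights."""
    return PixelSegmenter(spec or ModelSpec(), seed=seed)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_logit_loss(logits: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy evaluated in the stable logit form.

    loss = mean( max(z,0) - z*t + log(1 + exp(-|z|)) ).
    """
    z = np.asarray(logits, dtype=np.float64)
    t = np.asarray(targets)
    if t.dtype != bool and not np.isin(t, (0, 1)).all():
        raise ValueError("targets must be binary")
    t = t.astype(np.float64)
    if z.shape != t.shape:
        raise ValueError("logits and targets shapes disagree")
    return float(np.mean(np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))))


class _Adam:
    def __init__(self, weights: dict, lr: float) -> None:
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}

    def step(self, weights: dict, grads: dict) -> None:
        self.t += 1
        for k in weights:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            weights[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# -- training --------------------------------------------------------------


@dataclass
class TrainResult:
    checkpoint: Checkpoint
    history: pd.DataFrame


def _pair_arrays(pair) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pair, tuple):
        return pair
    return np.asarray(pair.image), np.asarray(pair.mask)


_RED_FEATURE = 5  # index of the red-score channel in the feature stack


def _sample_pixels(
    feats: np.ndarray, mask: np.ndarray, n_max: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified pixel subsample emphasizing the decision region.

    Up to half the budget goes to positives; the negative half is drawn
    preferentially from *red* negatives (red score > 0.2), the hard
    examples — non-bleeding vessels and cancellous bone under a zero
    mask — that the fine-tuning stage exists to suppress.  Uniform
    negative sampling would dilute their gradient to near nothing.
    """
    flat_f = feats.reshape(-1, feats.shape[-1]).astype(np.float64)
    flat_y = mask.reshape(-1).astype(np.float64)
    if flat_y.size <= n_max:
        return flat_f, flat_y
    red = flat_f[:, _RED_FEATURE] > 0.2
    pos = np.flatnonzero(flat_y > 0)
    neg_red = np.flatnonzero((flat_y == 0) & red)
    neg_other = np.flatnonzero((flat_y == 0) & ~red)

    n_pos = min(pos.size, n_max // 2)
    budget = n_max - n_pos
    n_red = min(neg_red.size, budget // 3)
    n_other = min(neg_other.size, budget - n_red)
    n_red = min(neg_red.size, budget - n_other)  # backfill if few plain negatives

    def pick(idx: np.ndarray, n: int) -> np.ndarray:
        return rng.choice(idx, n, replace=False) if n else np.empty(0, int)

    take = np.concatenate([pick(pos, n_pos), pick(neg_red, n_red), pick(neg_other, n_other)])
    return flat_f[take], flat_y[take]


def _build_cache(pairs, cfg: TrainConfig, spec: ModelSpec, salt: int):
    cache = []
    for i, pair in enumerate(pairs):
        image, mask = _pair_arrays(pair)
        feats = extract_features(image, spec)
        rng = np.random.default_rng([cfg.seed, salt, i])
        cache.append(_sample_pixels(feats, mask, cfg.pixels_per_image, rng))
    return cache

def _epoch_pass(model, cache, order, opt, batch_size):
    """One optimization pass; returns the mean minibatch loss."""
    losses = []
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        X = np.vstack([cache[i][0] for i in idx])
        y = np.concatenate([cache[i][1] for i in idx])
        logits, acts = model.forward(X, cache=True)
        loss = bce_logit_loss(logits, y)
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite training loss {loss}")
        dlogit = (_sigmoid(logits) - y) / y.size
        opt.step(model.weights, model.backward(acts, dlogit))
        losses.append(loss)
    return float(np.mean(losses))


def train_base(
    model: PixelSegmenter,
    train_pairs: Sequence,
    val_pairs: Sequence,
    cfg: TrainConfig,
) -> TrainResult:
    """First-stage training on weak labels with patience on validation loss.

    Stops once the best validation loss has not improved by more than
    ``improvement_epsilon`` for ``patience_base`` consecutive epochs
    (patience 0 stops at the first non-improving epoch) and returns the
    checkpoint of the best epoch plus a per-epoch loss history.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation partitions must be non-empty")
    train_cache = _build_cache(train_pairs, cfg, model.spec, salt=0)
    val_cache = _build_cache(val_pairs, cfg, model.spec, salt=1)
    model.fit_scaler(np.vstack([X for X, _ in train_cache]))
    opt = _Adam(model.weights, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    cfg_hash = config_hash(cfg, model.spec)

    best = np.inf
    best_ckpt = model.checkpoint(0, np.inf, cfg_hash)
    n_bad = 0
    rows = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_cache))
        train_loss = _epoch_pass(model, cache=train_cache, order=order, opt=opt,
                                 batch_size=cfg.batch_size)
        val_logits = [model.forward(X) for X, _ in val_cache]
        val_loss = float(
            np.mean(
                [bce_logit_loss(z, y) for z, (_, y) in zip(val_logits, val_cache)]
            )
        )
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        if best - val_loss > cfg.improvement_epsilon:
            best = val_loss
            best_ckpt = model.checkpoint(epoch, val_loss, cfg_hash)
            n_bad = 0
        else:
            n_bad += 1
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
             "best_val": best}
        )
        if n_bad >= max(cfg.patience_base, 1):
            break
    model.weights = {
        k: v.copy() for k, v in best_ckpt.weights.items() if not k.startswith("feat_")
    }
    return TrainResult(best_ckpt, pd.DataFrame(rows))


def finetune(
    base_ckpt: Checkpoint,
    curated: Sequence[CuratedSample],
    gt_eval: Sequence[EvalImage],
    cfg: TrainConfig,
) -> TrainResult:
    """Second-stage training on curated red masks and zero masks.

    Training resumes from the base-model weights.  Early stopping
    monitors the mean Dice of predicted masks against every reference
    mask in ``gt_eval`` (IoU is logged alongside); the best-Dice
    checkpoint is returned.  Sources shared between the curated set and
    the monitoring set are refused as leakage.
    """
    from .eval_suite import dice_iou  # local import avoids a cycle

    shared = {s.source_id for s in curated} & {e.source_id for e in gt_eval}
    if shared:
        raise LeakageError(f"curated and monitoring sets share sources: {sorted(shared)}")
    if not curated or not gt_eval:
        raise ValueError("curated and monitoring sets must be non-empty")

    model = PixelSegmenter.from_checkpoint(base_ckpt)
    cache = _build_cache(curated, cfg, model.spec, salt=2)
    opt = _Adam(model.weights, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    cfg_hash = config_hash(cfg, model.spec)

    # features of the monitoring frames are fixed; extract them once
    eval_feats = [
        extract_features(np.asarray(ev.image), model.spec).astype(np.float64)
        for ev in gt_eval
    ]

    def monitor() -> tuple[float, float]:
        dices, ious = [], []
        for ev, feats in zip(gt_eval, eval_feats):
            h, w, f = feats.shape
            pred = _sigmoid(model.forward(feats.reshape(-1, f)).reshape(h, w)) > 0.5
            for ref in ev.rater_masks:
                sc = dice_iou(pred, np.asarray(ref).astype(bool))
                dices.append(sc.dice)
                ious.append(sc.iou)
        return float(np.mean(dices)), float(np.mean(ious))

    best = -np.inf
    best_ckpt = model.checkpoint(0, -np.inf, cfg_hash)
    n_bad = 0
    rows = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(cache))
        train_loss = _epoch_pass(model, cache=cache, order=order, opt=opt,
                                 batch_size=cfg.batch_size)
        dice, iou = monitor()
        if dice - best > cfg.improvement_epsilon:
            best = dice
            best_ckpt = model.checkpoint(epoch, dice, cfg_hash)
            n_bad = 0
        else:
            n_bad += 1
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "monitor_dice": dice,
             "monitor_iou": iou, "best_dice": best}
        )
        if n_bad >= max(cfg.patience_finetune, 1):
            break
    model.weights = {
        k: v.copy() for k, v in best_ckpt.weights.items() if not k.startswith("feat_")
    }
    return TrainResult(best_ckpt, pd.DataFrame(rows))


def _as_model(model_or_ckpt) -> PixelSegmenter:
    if isinstance(model_or_ckpt, Checkpoint):
        return PixelSegmenter.from_checkpoint(model_or_ckpt)
    return model_or_ckpt


def predict_mask(
    model_or_ckpt, image: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Binary mask: sigmoid(logit) strictly greater than ``threshold``.

    8-bit input is auto-normalized with a warning; pass an array
    preprocessed per :class:`~endobleed.dataset_io.NormalizationSpec`
    to silence it.
    """
    model = _as_model(model_or_ckpt)
    if image.dtype == np.uint8:
        warnings.warn("8-bit input auto-normalized before prediction", stacklevel=2)
    return _sigmoid(model.predict_logits(image)) > threshold


def predict_proba(model_or_ckpt, image: np.ndarray) -> np.ndarray:
    """Per-pixel bleeding probability map."""
    return _as_model(model_or_ckpt).predict_proba(image)
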