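"""End-to-end workflow orchestration: synth → label → filter → split →
curate → train → finetune → evaluate → video.

Two layers live here.  The in-memory layer (:func:`generate_study`,
:func:`run_two_stage`, :func:`evaluate_checkpoint`, ...) builds the full
synthetic study and runs the pipeline on it; it is what the test suite
and the acceptance script drive.  The disk layer (:func:`run_stage`)
wraps the same computations as CLI stages with per-stage JSON manifests
recording the config hash, seed and SHA-256 of every input and output
file, so a rerun can detect tampered or stale inputs.

The simulated annotator panel follows the study design: five raters,
three with low boundary noise and two with high noise (one systematic
over-segmenter, one under-segmenter), so that panel selection has a
correct answer and the ground-truth agreement spans a useful range.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import eval_suite as es
from . import model_core as mc
from . import scene_synth as ss
from . import weak_labels as wl
from .config import RunConfig
from .dataset_io import CuratedSample, FrameVideo, split_by_source

logger = logging.getLogger(__name__)

# Annotator noise profiles: (dilate_erode_px, boundary_jitter_sd, miss_prob)
RATER_PROFILES = {
    "r1": ss.RaterNoise(0, 1.5, 0.0),
    "r2": ss.RaterNoise(0, 2.0, 0.0),
    "r3": ss.RaterNoise(1, 2.5, 0.0),
    "r4": ss.RaterNoise(3, 6.0, 0.1),
    "r5": ss.RaterNoise(-2, 7.0, 0.2),
}
LOW_NOISE_RATERS = ("r1", "r2", "r3")


class ManifestError(RuntimeError):
    """An input file does not match the hash its producing stage recorded."""


class MissingInputError(FileNotFoundError):
    """A stage's declared input is absent; the message names the stage to run."""


@dataclass
class EvalCase:
    """One evaluation frame with its per-rater masks and FOV."""

    image: np.ndarray
    rater_masks: dict
    fov: np.ndarray
    source_id: str
    truth_ratio: float


@dataclass
class StudyData:
    """The complete synthetic study: every dataset the pipeline consumes."""

    train_pairs: list
    curated: list
    monitor: list
    eval_cases: list
    distractor_scenes: list
    bleeding_scenes: list
    video: ss.SyntheticVideo


def _scene_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def generate_study(cfg: RunConfig) -> StudyData:
    """Generate all synthetic datasets for one pipeline run, seeded by cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size

    def scene(frac: float, vessel: bool, bone: bool) -> ss.SyntheticScene:
        return ss.make_scene(
            ss.SceneParams(
                image_size=size,
                plume_area_frac=frac,
                n_plumes=3 if frac > 0 else 0,
                vessel_on=vessel,
                bone_on=bone,
                seed=_scene_seed(rng),
            )
        )

    # base-training pool: mixed frames, weak-labelled
    train_pairs = []
    for i in range(cfg.n_train_scenes):
        sc = scene(float(rng.uniform(0.05, 0.40)), True, True)
        mask, ratio = wl.weak_label(sc.image)
        train_pairs.append(
            wl.LabeledPair(sc.image, mask, ratio, source_id=f"train{i:04d}")
        )

    # curated fine-tuning set: definite bleeding vs zero-mask distractors
    curated = []
    for i in range(cfg.n_curated_bleeding):
        sc = scene(float(rng.uniform(0.08, 0.35)), False, False)
        curated.append(
            CuratedSample(sc.image, sc.bleeding_mask, "bleeding_red_mask",
                          "expert", f"cur{i:04d}")
        )
    for i in range(cfg.n_curated_zero):
        sc = scene(0.0, True, True)
        curated.append(
            CuratedSample(sc.image, np.zeros((size, size), bool), "zero_mask",
                          "expert", f"zero{i:04d}")
        )

    # fine-tune monitoring set (sources disjoint from curated)
    monitor = []
    for i in range(cfg.n_monitor_mixed):
        sc = scene(float(rng.uniform(0.10, 0.35)), True, True)
        masks = [
            ss.make_rater_mask(
                sc.bleeding_mask,
                ss.RaterNoise(0, 1.0, 0.0, seed=_scene_seed(rng)),
            )
            for _ in range(3)
        ]
        monitor.append(mc.EvalImage(sc.image, masks, f"mon{i:04d}"))
    for i in range(cfg.n_monitor_distractor):
        sc = scene(0.0, True, True)
        monitor.append(
            mc.EvalImage(sc.image, [np.zeros((size, size), bool)] * 3,
                         f"mond{i:04d}")
        )

    # evaluation set: balanced bleeding-area ratios plus GT-negative frames
    eval_cases = []
    n_neg = max(cfg.n_eval_images // 4, 1)
    n_pos = cfg.n_eval_images - n_neg
    fracs = np.linspace(0.015, 0.50, n_pos)
    for i in range(cfg.n_eval_images):
        frac = float(fracs[i]) if i < n_pos else 0.0
        sc = scene(frac, True, True)
        raters = {
            rid: ss.make_rater_mask(
                sc.bleeding_mask,
                ss.RaterNoise(
                    prof.dilate_erode_px, prof.boundary_jitter_sd,
                    prof.miss_prob, prof.miss_area_px, seed=_scene_seed(rng),
                ),
            )
            for rid, prof in RATER_PROFILES.items()
        }
        eval_cases.append(
            EvalCase(sc.image, raters, sc.fov_truth, f"eval{i:04d}",
                     float(sc.bleeding_mask.sum()) / float(sc.fov_truth.sum()))
        )

    # held-out scenes for the before/after distractor comparison
    distractor_scenes = [scene(0.0, True, True) for _ in range(cfg.n_distractor_eval)]
    bleeding_scenes = [
        scene(float(rng.uniform(0.10, 0.40)), False, False)
        for _ in range(cfg.n_distractor_eval)
    ]

    video = ss.make_video(
        ss.SceneParams(
            image_size=size, plume_area_frac=0.05, vessel_on=True,
            bone_on=True, seed=_scene_seed(rng),
        ),
        n_frames=cfg.video_frames,
        growth=cfg.video_growth,
    )
    return StudyData(
        train_pairs, curated, monitor, eval_cases, distractor_scenes,
        bleeding_scenes, video,
    )


def run_two_stage(
    cfg: RunConfig, study: StudyData
) -> tuple[mc.TrainResult, mc.TrainResult]:
    """Base training on weak labels followed by curated fine-tuning."""
    pairs = [p for p in study.train_pairs]
    kept = wl.filter_pairs(pairs, cfg.min_red_ratio)
    train, val = split_by_source(kept, cfg.val_frac, seed=cfg.seed)
    model = mc.build_model(cfg.model, seed=cfg.seed)
    base = mc.train_base(
        model, [(p.image, p.mask) for p in train], [(p.image, p.mask) for p in val],
        cfg.train,
    )
    ft = mc.finetune(base.checkpoint, study.curated, study.monitor, cfg.train)
    return base, ft


@dataclass
class EvaluationReport:
    """Everything the evaluation protocol produces for one checkpoint."""

    panel: es.RaterPanel
    records: list
    confusion: es.ConfusionCounts
    detection: es.DetectionMetrics
    agreement_strata: list
    area_strata: list
    dice_correlation: es.CorrelationResult
    iou_correlation: es.CorrelationResult
    average_precision: float
    overall: es.StratumSummary

    def metrics_dict(self) -> dict:
        d = self.detection
        out = {
            "tp": self.confusion.tp, "tn": self.confusion.tn,
            "fp": self.confusion.fp, "fn": self.confusion.fn,
        }
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            m = getattr(d, name)
            if m is not None:
                out[name] = m.value
                out[f"{name}_ci"] = [m.lo, m.hi]
        out["dice_median"] = self.overall.dice_median
        out["dice_mean"] = self.overall.dice_mean
        out["iou_median"] = self.overall.iou_median
        out["iou_mean"] = self.overall.iou_mean
        out["spearman_rho_dice"] = self.dice_correlation.rho
        out["spearman_rho_iou"] = self.iou_correlation.rho
        out["average_precision"] = self.average_precision
        out["panel"] = self.panel.selected
        out["panel_mean_dice"] = self.panel.selection_score
        return out


def evaluate_checkpoint(
    ckpt: mc.Checkpoint, study: StudyData, cfg: RunConfig
) -> EvaluationReport:
    """The full multi-rater evaluation protocol against one checkpoint.

    Selects the most consistent rater panel, scores the model against
    each selected rater's mask on every evaluation frame within a
    circular FOV, tallies image-wise detection, stratifies Dice/IoU by
    ground-truth agreement and bleeding area, and computes the pooled
    pixel-level average precision and the Spearman correlation between
    overlap scores and panel agreement.
    """
    model = mc.PixelSegmenter.from_checkpoint(ckpt)
    cases = study.eval_cases

    panel = es.pairwise_agreement(
        {rid: [c.rater_masks[rid] for c in cases] for rid in RATER_PROFILES}
    )
    panel = es.select_panel(panel, k=cfg.panel_k)

    records, preds, gts, fovs, probs = [], [], [], [], []
    dice_vals, agree_vals, iou_vals = [], [], []
    for case in cases:
        prob = model.predict_proba(case.image)
        pred = prob > 0.5
        fov = es.circular_fov(case.fov)
        n_fov = int(fov.sum())
        agree_d, _ = es.gt_agreement([case.rater_masks[r] for r in panel.selected])
        for rid in panel.selected:
            gt = case.rater_masks[rid] & fov
            sc = es.dice_iou(pred & fov, gt)
            area = float(gt.sum()) / n_fov
            records.append(
                es.EvalRecord(case.source_id, rid, sc.dice, sc.iou, agree_d, area)
            )
            preds.append(pred)
            gts.append(case.rater_masks[rid])
            fovs.append(fov)
            probs.append(prob)
            if area > 0:
                dice_vals.append(sc.dice)
                iou_vals.append(sc.iou)
                agree_vals.append(agree_d)

    counts = es.confusion(preds, gts, fovs)
    detection = es.detection_metrics(counts, ci_method="wilson")
    positive = [r for r in records if r.gt_positive]
    report = EvaluationReport(
        panel=panel,
        records=records,
        confusion=counts,
        detection=detection,
        agreement_strata=es.stratify_by_agreement(positive),
        area_strata=es.stratify_by_area(records),
        dice_correlation=es.spearman(dice_vals, agree_vals),
        iou_correlation=es.spearman(iou_vals, agree_vals),
        average_precision=es.pixel_pr(probs, gts, fovs).average_precision,
        overall=es._summary("overall", positive),
    )
    return report


def distractor_fp_area(ckpt: mc.Checkpoint, scenes) -> float:
    """Mean predicted-positive pixel count on distractor-only scenes."""
    model = mc.PixelSegmenter.from_checkpoint(ckpt)
    areas = [
        int((mc._sigmoid(model.predict_logits(sc.image)) > 0.5).sum())
        for sc in scenes
    ]
    return float(np.mean(areas))


def bleeding_dice(ckpt: mc.Checkpoint, scenes) -> float:
    """Mean Dice against truth bleeding masks on bleeding-only scenes."""
    model = mc.PixelSegmenter.from_checkpoint(ckpt)
    vals = [
        es.dice_iou(
            mc._sigmoid(model.predict_logits(sc.image)) > 0.5, sc.bleeding_mask
        ).dice
        for sc in scenes
    ]
    return float(np.mean(vals))


# -- disk stages with manifests ---------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    from .config import _to_plain

    return hashlib.sha256(
        json.dumps(_to_plain(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]


def _write_manifest(
    root: Path, stage: str, cfg: RunConfig, inputs: list[Path], outputs: list[Path]
) -> None:
    manifest = {
        "stage": stage,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "inputs": {str(p.relative_to(root)): _sha256(p) for p in inputs},
        "outputs": {str(p.relative_to(root)): _sha256(p) for p in outputs},
    }
    (root / f"{stage}.manifest.json").write_text(json.dumps(manifest, indent=1))


def _recorded_hashes(root: Path) -> dict[str, str]:
    recorded: dict[str, str] = {}
    for mpath in root.glob("*.manifest.json"):
        recorded.update(json.loads(mpath.read_text()).get("outputs", {}))
    return recorded


def _check_inputs(root: Path, stage: str, upstream: str, paths: list[Path]) -> None:
    recorded = _recorded_hashes(root)
    for p in paths:
        if not p.exists():
            raise MissingInputError(
                f"stage '{stage}' needs {p}; run stage '{upstream}' first"
            )
        rel = str(p.relative_to(root))
        if rel in recorded:
            actual = _sha256(p)
            if actual != recorded[rel]:
                raise ManifestError(
                    f"stage '{stage}': input {rel} was modified after being "
                    f"produced (recorded {recorded[rel][:12]}, found {actual[:12]})"
                )


_STAGE_ORDER = [
    "synth", "label", "filter", "split", "curate", "train", "finetune",
    "evaluate", "video",
]


def run_stage(name: str, cfg: RunConfig, root: str | Path) -> dict:
    """Run one named pipeline stage under ``root`` with manifest bookkeeping.

    Returns a small dict of headline results for logging.  ``all`` runs
    every stage in order.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    if name == "all":
        out = {}
        for stage in _STAGE_ORDER:
            out[stage] = run_stage(stage, cfg, root)
        return out
    fn = _STAGE_FNS.get(name)
    if fn is None:
        raise ValueError(f"unknown stage {name!r}; expected one of {_STAGE_ORDER}")
    logger.info("running stage %s", name)
    return fn(cfg, root)


def _study_path(root: Path) -> Path:
    return root / "study.npz"


def _stage_synth(cfg: RunConfig, root: Path) -> dict:
    study = generate_study(cfg)
    # persist the video and eval scenes as inspectable artifacts
    video_dir = root / "video_in"
    FrameVideo(study.video.frames, study.video.fps).save(video_dir)
    (root / "video_truth.json").write_text(json.dumps(study.video.truth_ratios))
    n_imgs = (
        len(study.train_pairs) + len(study.curated) + len(study.monitor)
        + len(study.eval_cases)
    )
    outputs = sorted(video_dir.glob("*")) + [root / "video_truth.json"]
    _write_manifest(root, "synth", cfg, [], outputs)
    return {"n_images": n_imgs, "video_frames": len(study.video.frames)}


def _stage_label(cfg: RunConfig, root: Path) -> dict:
    study = generate_study(cfg)
    rows = [
        {"source_id": p.source_id, "red_area_ratio": p.red_area_ratio}
        for p in study.train_pairs
    ]
    out = root / "labels.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    _write_manifest(root, "label", cfg, [], [out])
    return {"n_labelled": len(rows)}


def _stage_filter(cfg: RunConfig, root: Path) -> dict:
    src = root / "labels.csv"
    _check_inputs(root, "filter", "label", [src])
    df = pd.read_csv(src)
    kept = df[df.red_area_ratio > cfg.min_red_ratio]
    out = root / "filtered.csv"
    kept.to_csv(out, index=False)
    _write_manifest(root, "filter", cfg, [src], [out])
    return {"n_in": len(df), "n_kept": len(kept)}


def _stage_split(cfg: RunConfig, root: Path) -> dict:
    src = root / "filtered.csv"
    _check_inputs(root, "split", "filter", [src])
    df = pd.read_csv(src)
    rng = np.random.default_rng(cfg.seed)
    sources = sorted(df.source_id.unique())
    order = [sources[i] for i in rng.permutation(len(sources))]
    n_val = int(np.clip(round(cfg.val_frac * len(sources)), 1, len(sources) - 1))
    val = set(order[:n_val])
    df["partition"] = ["val" if s in val else "train" for s in df.source_id]
    out = root / "split.csv"
    df.to_csv(out, index=False)
    _write_manifest(root, "split", cfg, [src], [out])
    return {"n_train": int((df.partition == "train").sum()),
            "n_val": int((df.partition == "val").sum())}


def _stage_curate(cfg: RunConfig, root: Path) -> dict:
    study = generate_study(cfg)
    rows = [
        {"source_id": s.source_id, "label_class": s.label_class,
         "annotator_id": s.annotator_id, "mask_area": int(s.mask.sum())}
        for s in study.curated
    ]
    out = root / "curated.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    _write_manifest(root, "curate", cfg, [], [out])
    return {"n_red_mask": sum(r["label_class"] == "bleeding_red_mask" for r in rows),
            "n_zero_mask": sum(r["label_class"] == "zero_mask" for r in rows)}


def _stage_train(cfg: RunConfig, root: Path) -> dict:
    split_csv = root / "split.csv"
    _check_inputs(root, "train", "split", [split_csv])
    study = generate_study(cfg)
    split = pd.read_csv(split_csv)
    val_ids = set(split.loc[split.partition == "val", "source_id"])
    kept_ids = set(split.source_id)
    train = [(p.image, p.mask) for p in study.train_pairs
             if p.source_id in kept_ids and p.source_id not in val_ids]
    val = [(p.image, p.mask) for p in study.train_pairs if p.source_id in val_ids]
    model = mc.build_model(cfg.model, seed=cfg.seed)
    result = mc.train_base(model, train, val, cfg.train)
    ckpt_path = root / "base.npz"
    result.checkpoint.save(ckpt_path)
    hist = root / "base_history.csv"
    result.history.to_csv(hist, index=False)
    _write_manifest(root, "train", cfg, [split_csv], [ckpt_path, hist])
    return {"epochs": len(result.history), "best_epoch": result.checkpoint.epoch,
            "best_val_loss": result.checkpoint.monitored}


def _stage_finetune(cfg: RunConfig, root: Path) -> dict:
    base_path = root / "base.npz"
    _check_inputs(root, "finetune", "train", [base_path])
    study = generate_study(cfg)
    base_ckpt = mc.Checkpoint.load(base_path)
    result = mc.finetune(base_ckpt, study.curated, study.monitor, cfg.train)
    ckpt_path = root / "finetuned.npz"
    result.checkpoint.save(ckpt_path)
    hist = root / "finetune_history.csv"
    result.history.to_csv(hist, index=False)
    _write_manifest(root, "finetune", cfg, [base_path], [ckpt_path, hist])
    return {"epochs": len(result.history), "best_epoch": result.checkpoint.epoch,
            "best_dice": result.checkpoint.monitored}


def _stage_evaluate(cfg: RunConfig, root: Path) -> dict:
    ckpt_path = root / "finetuned.npz"
    _check_inputs(root, "evaluate", "finetune", [ckpt_path])
    study = generate_study(cfg)
    report = evaluate_checkpoint(mc.Checkpoint.load(ckpt_path), study, cfg)
    metrics = report.metrics_dict()
    out = root / "metrics.json"
    out.write_text(json.dumps(metrics, indent=1))
    strata_rows = []
    for s in report.agreement_strata + report.area_strata + [report.overall]:
        strata_rows.append(
            {"group": s.group, "n": s.n,
             "dice_median": s.dice_median, "dice_iqr_lo": s.dice_iqr[0],
             "dice_iqr_hi": s.dice_iqr[1], "dice_mean": s.dice_mean,
             "dice_sd": s.dice_sd, "iou_median": s.iou_median,
             "iou_mean": s.iou_mean, "iou_sd": s.iou_sd}
        )
    strata_csv = root / "strata.csv"
    pd.DataFrame(strata_rows).to_csv(strata_csv, index=False)
    _write_manifest(root, "evaluate", cfg, [ckpt_path], [out, strata_csv])
    return metrics


def _stage_video(cfg: RunConfig, root: Path) -> dict:
    from .video_quant import infer_video, render_composite

    ckpt_path = root / "finetuned.npz"
    video_dir = root / "video_in"
    _check_inputs(root, "video", "finetune/synth",
                  [ckpt_path, video_dir / "video.json"])
    video = FrameVideo.load(video_dir)
    ckpt = mc.Checkpoint.load(ckpt_path)
    timeline, masks = infer_video(ckpt, video, denominator_mode="full_frame")
    tl_path = root / "timeline.csv"
    timeline.to_csv(tl_path, index=False)
    render_composite(video, masks, timeline, root / "video_out")
    outputs = [tl_path] + sorted((root / "video_out").glob("*"))
    _write_manifest(root, "video", cfg, [ckpt_path], outputs)
    return {"n_frames": len(timeline), "final_ratio": float(timeline.ratio.iloc[-1])}


_STAGE_FNS = {
    "synth": _stage_synth,
    "label": _stage_label,
    "filter": _stage_filter,
    "split": _stage_split,
    "curate": _stage_curate,
    "train": _stage_train,
    "finetune": _stage_finetune,
    "evaluate": _stage_evaluate,
    "video": _stage_video,
}
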