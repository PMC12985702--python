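"""Evaluation statistics for bleeding segmentation against expert panels.

Covers the full multi-rater protocol: per-image/per-rater Dice and IoU,
image-wise bleeding detection (confusion matrix, accuracy/sensitivity/
specificity/PPV/NPV with Wilson or Clopper–Pearson 95% CIs), selection
of the most mutually consistent annotator panel, per-image ground-truth
agreement, stratified Dice/IoU summaries by agreement and bleeding
area, Spearman correlation with a Shapiro–Wilk normality gate, and
pooled pixel-level precision–recall with average precision.

Conventions, fixed here once and used throughout:

* Dice and IoU of two empty masks are defined as 1.0 for bookkeeping,
  but such records are excluded from area-based summaries, which run
  on ground-truth-positive images only (GT area > 0 within the FOV).
* Image-wise positivity means at least one positive pixel inside the
  circular field of view (a configurable minimum area defaults to 0).
* The area stratification places a ratio of exactly 0.20 in the
  low-bleeding group (the high group is strictly > 20%).
* Reported numbers round half-up to two decimals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats
from sklearn.metrics import average_precision_score, precision_recall_curve
from statsmodels.stats.proportion import proportion_confint

_CI_METHODS = {"wilson": "wilson", "clopper_pearson": "beta"}


@dataclass(frozen=True)
class OverlapScores:
    """Dice/IoU of one (image, rater) mask pair.

    The identity dice = 2*iou/(1+iou) holds exactly for every record.
    gt_positive marks whether the reference mask had any positive pixel.
    """

    dice: float
    iou: float
    gt_positive: bool


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricCI:
    value: float
    lo: float
    hi: float
    method: str


@dataclass(frozen=True)
class DetectionMetrics:
    """Image-wise diagnostic performance with 95% CIs (None if undefined)."""

    accuracy: MetricCI
    sensitivity: MetricCI | None
    specificity: MetricCI | None
    ppv: MetricCI | None
    npv: MetricCI | None
    counts: ConfusionCounts


@dataclass
class RaterPanel:
    """Pairwise mean Dice/IoU agreement across annotators.

    ``selected`` holds the most mutually consistent subset after
    :func:`select_panel`; ``selection_score`` its mean within-subset
    pairwise Dice.
    """

    rater_ids: list
    dice_matrix: np.ndarray
    iou_matrix: np.ndarray
    selected: list | None = None
    selection_score: float | None = None


@dataclass(frozen=True)
class StratumSummary:
    group: str
    n: int
    dice_median: float
    dice_iqr: tuple[float, float]
    dice_mean: float
    dice_sd: float
    iou_median: float
    iou_iqr: tuple[float, float]
    iou_mean: float
    iou_sd: float


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    undefined: bool = False


@dataclass(frozen=True)
class NormalityVerdict:
    statistic: float
    p_value: float
    normal: bool  # at the conventional 0.05 level


@dataclass(frozen=True)
class PRResult:
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    average_precision: float


@dataclass(frozen=True)
class EvalRecord:
    """One (image, rater) evaluation row feeding the stratified summaries."""

    image_id: str
    rater_id: str
    dice: float
    iou: float
    gt_agreement: float
    gt_area_ratio: float

    @property
    def gt_positive(self) -> bool:
        return self.gt_area_ratio > 0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding as used in the reported tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    return mask.astype(bool)


def dice_iou(a: np.ndarray, b: np.ndarray) -> OverlapScores:
    """Dice = 2|A∩B|/(|A|+|B|), IoU = |A∩B|/|A∪B|.

    Two empty masks score (1.0, 1.0) by convention; such records are
    excluded from area-based summaries by the GT-positive rule.
    """
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes disagree: {a.shape} vs {b.shape}")
    inter = int((a & b).sum())
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return OverlapScores(1.0, 1.0, gt_positive=False)
    dice = 2.0 * inter / (sa + sb)
    iou = inter / (sa + sb - inter)
    return OverlapScores(dice, iou, gt_positive=sb > 0)


def image_class(mask: np.ndarray, fov: np.ndarray, min_area: int = 0) -> bool:
    """Image-wise positivity: more than ``min_area`` positive pixels in FOV."""
    mask, fov = _as_bool(mask), _as_bool(fov)
    if mask.shape != fov.shape:
        raise ValueError("mask and fov shapes disagree")
    if not fov.any():
        raise ValueError("empty FOV")
    return int((mask & fov).sum()) > min_area


def confusion(
    preds: Sequence[np.ndarray],
    gts: Sequence[np.ndarray],
    fovs: Sequence[np.ndarray] | np.ndarray,
    min_area: int = 0,
) -> ConfusionCounts:
    """2x2 tally of image-wise outcomes over aligned (image, rater) pairs.

    ``fovs`` may be a single mask shared by all evaluations or one per
    evaluation.
    """
    if len(preds) != len(gts):
        raise ValueError("preds and gts are misaligned")
    if isinstance(fovs, np.ndarray):
        fovs = [fovs] * len(preds)
    if len(fovs) != len(preds):
        raise ValueError("fovs misaligned with preds")
    tp = tn = fp = fn = 0
    for pred, gt, fov in zip(preds, gts, fovs):
        p = image_class(pred, fov, min_area)
        g = image_class(gt, fov, min_area)
        if p and g:
            tp += 1
        elif not p and not g:
            tn += 1
        elif p and not g:
            fp += 1
        else:
            fn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def score_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Two-sided binomial CI for k successes in n trials."""
    if method not in _CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}")
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"invalid counts k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method=_CI_METHODS[method])
    return float(lo), float(hi)


def detection_metrics(
    c: ConfusionCounts, ci_method: str = "wilson", level: float = 0.95
) -> DetectionMetrics:
    """Accuracy, sensitivity, specificity, PPV, NPV with binomial CIs.

    A metric whose denominator is zero is reported as None.
    """
    if c.total == 0:
        raise ValueError("all confusion counts are zero")

    def metric(k: int, n: int) -> MetricCI | None:
        if n == 0:
            return None
        lo, hi = score_ci(k, n, level, ci_method)
        return MetricCI(k / n, lo, hi, ci_method)

    return DetectionMetrics(
        accuracy=metric(c.tp + c.tn, c.total),
        sensitivity=metric(c.tp, c.tp + c.fn),
        specificity=metric(c.tn, c.tn + c.fp),
        ppv=metric(c.tp, c.tp + c.fp),
        npv=metric(c.tn, c.tn + c.fn),
        counts=c,
    )


# -- rater panel -----------------------------------------------------------


def pairwise_agreement(rater_masks: Mapping[str, Sequence[np.ndarray]]) -> RaterPanel:
    """Mean-over-images pairwise Dice/IoU matrices across annotators.

    ``rater_masks`` maps rater id -> masks in a shared image order; all
    raters must annotate every image.
    """
    ids = sorted(rater_masks)
    if len(ids) < 2:
        raise ValueError("need at least 2 raters")
    n_imgs = {r: len(rater_masks[r]) for r in ids}
    if len(set(n_imgs.values())) != 1 or next(iter(n_imgs.values())) == 0:
        raise ValueError(f"missing annotations: per-rater image counts {n_imgs}")
    k = len(ids)
    dmat = np.eye(k)
    jmat = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        scores = [
            dice_iou(a, b)
            for a, b in zip(rater_masks[ids[i]], rater_masks[ids[j]])
        ]
        dmat[i, j] = dmat[j, i] = np.mean([s.dice for s in scores])
        jmat[i, j] = jmat[j, i] = np.mean([s.iou for s in scores])
    return RaterPanel(ids, dmat, jmat)


def select_panel(panel: RaterPanel, k: int = 3) -> RaterPanel:
    """Subset of k raters maximizing mean within-subset pairwise Dice.

    Exhaustive search over all C(n, k) subsets; ties break toward the
    lexicographically first subset of rater ids.
    """
    n = len(panel.rater_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds number of raters {n}")
    best_subset, best_score = None, -np.inf
    for subset in itertools.combinations(range(n), k):  # lexicographic order
        pair_vals = [
            panel.dice_matrix[i, j] for i, j in itertools.combinations(subset, 2)
        ]
        score = float(np.mean(pair_vals)) if pair_vals else 1.0
        if score > best_score:
            best_subset, best_score = subset, score
    selected = [panel.rater_ids[i] for i in best_subset]
    return replace(panel, selected=selected, selection_score=best_score)


def gt_agreement(panel_masks: Sequence[np.ndarray]) -> tuple[float, float]:
    """Per-image GT agreement: mean pairwise Dice (and IoU) of the panel."""
    if any(m is None for m in panel_masks):
        raise ValueError("missing panel mask")
    if len(panel_masks) < 2:
        raise ValueError("need at least 2 panel masks")
    scores = [
        dice_iou(a, b) for a, b in itertools.combinations(panel_masks, 2)
    ]
    return (
        float(np.mean([s.dice for s in scores])),
        float(np.mean([s.iou for s in scores])),
    )


def consensus_mask(panel_masks: Sequence[np.ndarray]) -> np.ndarray:
    """Majority vote across the panel's masks."""
    stack = np.stack([_as_bool(m) for m in panel_masks])
    return stack.sum(axis=0) * 2 > len(panel_masks)


def rater_vs_consensus(
    rater_masks: Mapping[str, Sequence[np.ndarray]],
    panel: Sequence[str],
    fovs: Sequence[np.ndarray] | np.ndarray,
    leave_one_out: bool = True,
) -> dict:
    """Per-rater image-wise detection against the panel consensus.

    Each rater's masks are classified against the majority vote of the
    selected panel.  With ``leave_one_out`` (default) a panel member is
    excluded from the consensus that judges their own masks, avoiding
    self-agreement inflation; with False the full fixed panel is used.
    Returns rater id -> :class:`ConfusionCounts`.
    """
    n_images = len(next(iter(rater_masks.values())))
    if isinstance(fovs, np.ndarray):
        fovs = [fovs] * n_images
    out = {}
    for rid, masks in rater_masks.items():
        jury = [p for p in panel if not (leave_one_out and p == rid)]
        preds, gts = [], []
        for i in range(n_images):
            preds.append(masks[i])
            gts.append(consensus_mask([rater_masks[p][i] for p in jury]))
        out[rid] = confusion(preds, gts, list(fovs))
    return out


# -- stratified summaries --------------------------------------------------


def _summary(group: str, records: Sequence[EvalRecord]) -> StratumSummary:
    dice = np.array([r.dice for r in records], dtype=float)
    iou = np.array([r.iou for r in records], dtype=float)

    def stats5(x):
        if x.size == 0:
            return (np.nan,) * 5
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        return med, q1, q3, float(np.mean(x)), sd

    dm, dq1, dq3, dmean, dsd = stats5(dice)
    jm, jq1, jq3, jmean, jsd = stats5(iou)
    return StratumSummary(
        group, len(records), dm, (dq1, dq3), dmean, dsd, jm, (jq1, jq3), jmean, jsd
    )


def stratify_by_agreement(
    records: Sequence[EvalRecord],
    thresholds: Sequence[float] = (0.70, 0.80, 0.90),
) -> list[StratumSummary]:
    """Cumulative GT-agreement strata (each higher threshold nests in the lower)."""
    return [
        _summary(f">={thr:.2f}", [r for r in records if r.gt_agreement >= thr])
        for thr in sorted(thresholds)
    ]


def stratify_by_area(
    records: Sequence[EvalRecord], boundary: float = 0.20
) -> list[StratumSummary]:
    """Low (>0 to boundary, inclusive) vs high (> boundary) bleeding strata.

    GT-negative records (area ratio 0) are excluded entirely.
    """
    positive = [r for r in records if r.gt_positive]
    low = [r for r in positive if r.gt_area_ratio <= boundary]
    high = [r for r in positive if r.gt_area_ratio > boundary]
    return [
        _summary(f"low (>0-{boundary:.0%})", low),
        _summary(f"high (>{boundary:.0%})", high),
    ]


# -- correlation and normality --------------------------------------------


def spearman(scores: Sequence[float], agreements: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (average-rank ties, two-tailed t p-value).

    A constant input vector makes the coefficient undefined; the result
    is flagged rather than raised.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(agreements, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors required")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, x.size, undefined=True)
    res = stats.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), x.size)


def shapiro_gate(values: Sequence[float]) -> NormalityVerdict:
    """Shapiro–Wilk normality check gating parametric vs rank methods."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = stats.shapiro(x)
    return NormalityVerdict(float(res.statistic), float(res.pvalue),
                            normal=res.pvalue >= 0.05)


# -- pixel-level precision-recall ------------------------------------------


def pixel_pr(
    prob_maps: Sequence[np.ndarray],
    gt_masks: Sequence[np.ndarray],
    fovs: Sequence[np.ndarray] | np.ndarray,
) -> PRResult:
    """Pooled pixel-level PR curve and step-interpolated average precision."""
    if isinstance(fovs, np.ndarray):
        fovs = [fovs] * len(prob_maps)
    if not (len(prob_maps) == len(gt_masks) == len(fovs)):
        raise ValueError("misaligned inputs")
    probs, labels = [], []
    for p, g, f in zip(prob_maps, gt_masks, fovs):
        f = _as_bool(f)
        probs.append(np.asarray(p, dtype=float)[f])
        labels.append(_as_bool(g)[f])
    y_score = np.concatenate(probs)
    y_true = np.concatenate(labels)
    if not y_true.any():
        raise ValueError("no positive ground-truth pixels in the pooled set")
    precision, recall, thresholds = precision_recall_curve(y_true, y_score)
    ap = float(average_precision_score(y_true, y_score))
    return PRResult(precision, recall, thresholds, ap)


# -- evaluation FOV geometry -----------------------------------------------


def circular_fov(fov_mask: np.ndarray) -> np.ndarray:
    """Largest inscribed circle of a thresholded FOV mask.

    The center is the maximum of the Euclidean distance transform and
    the radius that maximum distance, reproducing the circular
    evaluation field from an arbitrary thresholded FOV.
    """
    fov_mask = _as_bool(fov_mask)
    if not fov_mask.any():
        raise ValueError("empty FOV mask")
    dist = ndimage.distance_transform_edt(fov_mask)
    cy, cx = np.unravel_index(np.argmax(dist), dist.shape)
    return fixed_circle(fov_mask.shape, (int(cy), int(cx)), float(dist[cy, cx]))


def fixed_circle(
    shape: tuple[int, int], center: tuple[int, int], radius: float
) -> np.ndarray:
    """Fixed-geometry circular FOV override (center in pixels)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
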