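"""Object-level detection evaluation: matching, error taxonomy, reports.

The protocol counts three error types against ground truth: a detection
matching a true nucleus is a TP; splitting one nucleus into several
detections yields 1 TP and k-1 FP (one-to-one matching); a missed
nucleus is an FN.  Mask-vs-mask matching uses IoU >= 0.5 with an optimal
one-to-one assignment; point-vs-mask matching (expert dot annotations)
uses containment with nearest-centroid tie-breaks.

Percentages follow the printed-report convention: per-image recall,
precision and F1 are rounded half-up to 1 decimal; report means are the
banker's-rounded (2 decimal) means of the rounded per-image values and
the std is the sample standard deviation (1 decimal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import MetricsError, ParameterError, SchemaError
from .starconvex import DetectionSet

DEFAULT_MATCH_IOU = 0.5


@dataclass
class MatchResult:
    """TP/FP/FN counts plus the matched (prediction, ground-truth) pairs."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ParameterError("counts must be non-negative")
        if len(self.pairs) not in (0, self.tp):
            raise ParameterError("tp must equal the number of matched pairs")

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            tp=self.tp + other.tp, fp=self.fp + other.fp, fn=self.fn + other.fn
        )


@dataclass
class MetricsRow:
    """One evaluated image: counts plus percentage metrics (1 decimal)."""

    image_id: str
    gt: int
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f1: float


@dataclass
class EvaluationReport:
    """Per-image rows plus mean/std summary of each percentage metric."""

    rows: list[MetricsRow]
    mean_recall: float
    mean_precision: float
    mean_f1: float
    std_recall: float
    std_precision: float
    std_f1: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        summary = pd.DataFrame(
            [
                {"image_id": "mean", "recall": self.mean_recall,
                 "precision": self.mean_precision, "f1": self.mean_f1},
                {"image_id": "std", "recall": self.std_recall,
                 "precision": self.std_precision, "f1": self.std_f1},
            ]
        )
        return pd.concat([df, summary], ignore_index=True)


def _iou_matrix(pred: np.ndarray, gt: np.ndarray):
    """Pairwise IoU between all prediction and ground-truth labels."""
    pred_ids = np.unique(pred[pred > 0])
    gt_ids = np.unique(gt[gt > 0])
    if len(pred_ids) == 0 or len(gt_ids) == 0:
        return pred_ids, gt_ids, np.zeros((len(pred_ids), len(gt_ids)))
    p_index = {lab: i for i, lab in enumerate(pred_ids)}
    g_index = {lab: i for i, lab in enumerate(gt_ids)}
    both = (pred > 0) & (gt > 0)
    inter = np.zeros((len(pred_ids), len(gt_ids)))
    pv, gv = pred[both], gt[both]
    combo = pv.astype(np.int64) * (gt.max() + 1) + gv
    uniq, counts = np.unique(combo, return_counts=True)
    for u, c in zip(uniq, counts):
        pl, gl = divmod(int(u), int(gt.max() + 1))
        inter[p_index[pl], g_index[gl]] = c
    p_areas = np.array([(pred == lab).sum() for lab in pred_ids])
    g_areas = np.array([(gt == lab).sum() for lab in gt_ids])
    union = p_areas[:, None] + g_areas[None, :] - inter
    return pred_ids, gt_ids, inter / union


def match_instances(
    pred: np.ndarray, gt: np.ndarray, iou_thresh: float = DEFAULT_MATCH_IOU
) -> MatchResult:
    """One-to-one instance matching maximizing total IoU.

    Candidate pairs are those with IoU >= ``iou_thresh``; the assignment
    maximizes summed IoU over the candidate graph.  Unmatched predictions
    count as FP (this is where over-segmentation lands: k detections on
    one nucleus give 1 TP and k-1 FP) and unmatched ground-truth
    instances as FN.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ParameterError("prediction and ground-truth shapes disagree")
    pred_ids, gt_ids, iou = _iou_matrix(pred, gt)
    pairs: list[tuple[int, int]] = []
    if iou.size:
        gain = np.where(iou >= iou_thresh, iou, 0.0)
        rows, cols = linear_sum_assignment(-gain)
        for r, c in zip(rows, cols):
            if iou[r, c] >= iou_thresh:
                pairs.append((int(pred_ids[r]), int(gt_ids[c])))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(pred_ids) - tp, fn=len(gt_ids) - tp, pairs=pairs)


def match_points(
    pred: DetectionSet,
    gt_points: list[tuple[float, float]],
    region: np.ndarray | None = None,
) -> MatchResult:
    """Match expert point annotations against detected instances.

    A point matches the instance whose painted polygon contains it; when
    several points fall inside one instance the nearest centroid wins and
    the rest are FN.  Instances containing no point are FP when they
    overlap the evaluated ``region`` (whole image if None).
    """
    mask = pred.instance_mask
    h, w = mask.shape
    claimed: dict[int, tuple[int, float]] = {}  # instance -> (point idx, dist)
    fn = 0
    for idx, (r, c) in enumerate(gt_points):
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < h and 0 <= ci < w):
            raise ParameterError(f"point {(r, c)} outside image bounds")
        inst = int(mask[ri, ci])
        if inst == 0:
            fn += 1
            continue
        d = float(np.hypot(
            pred.centroids[inst - 1][0] - r, pred.centroids[inst - 1][1] - c
        ))
        if inst not in claimed:
            claimed[inst] = (idx, d)
        elif d < claimed[inst][1]:
            claimed[inst] = (idx, d)  # closer point takes over; old one is FN
            fn += 1
        else:
            fn += 1
    pairs = [(inst, idx) for inst, (idx, _) in claimed.items()]
    tp = len(pairs)
    fp = 0
    for inst in range(1, int(mask.max()) + 1):
        if inst in claimed:
            continue
        sel = mask == inst
        if region is None or np.any(sel & np.asarray(region, dtype=bool)):
            fp += 1
    return MatchResult(tp=tp, fp=fp, fn=fn, pairs=pairs)


def expert_filter(nuclei: pd.DataFrame) -> pd.DataFrame:
    """Keep nuclei meeting the expert scoring criteria.

    A nucleus qualifies for HER2 quantification when it shows at least
    two red (CEN17) signals and is neither overlapping a neighbour nor
    touching the image border.
    """
    required = {"red_signals", "overlaps_neighbor", "touches_border"}
    missing = required - set(nuclei.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    keep = (
        (nuclei["red_signals"] >= 2)
        & ~nuclei["overlaps_neighbor"].astype(bool)
        & ~nuclei["touches_border"].astype(bool)
    )
    return nuclei[keep].copy()


def _round_pct(num: int, den: int) -> float:
    """Exact percentage num/den, half-up to 1 decimal."""
    frac = Fraction(100 * num, den)
    d = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def metrics(counts: MatchResult, image_id: str = "", gt: int | None = None) -> MetricsRow:
    """Recall, precision and F1 percentages from TP/FP/FN counts.

    recall = 100 TP/(TP+FN), precision = 100 TP/(TP+FP),
    F1 = 100 * 2TP/(2TP+FN+FP); each rounded half-up to 1 decimal.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp + fn == 0:
        raise MetricsError("metrics undefined for tp=fp=fn=0")
    recall = _round_pct(tp, tp + fn) if tp + fn else 100.0
    precision = _round_pct(tp, tp + fp) if tp + fp else 100.0
    f1 = _round_pct(2 * tp, 2 * tp + fn + fp)
    return MetricsRow(
        image_id=image_id,
        gt=gt if gt is not None else tp + fn,
        tp=tp, fp=fp, fn=fn,
        recall=recall, precision=precision, f1=f1,
    )


def aggregate_report(rows: list[MetricsRow]) -> EvaluationReport:
    """Mean (2 decimals, banker's) and population std (1 decimal) per metric.

    Aggregation runs on the already-rounded per-row percentages, matching
    how printed per-image tables are summarized.
    """
    if not rows:
        raise ParameterError("need at least one row")

    def agg(vals: list[float]) -> tuple[float, float]:
        dec = [Decimal(str(v)) for v in vals]
        mean = (sum(dec) / len(dec)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN)
        # sample std (ddof=1) matches how printed report tables summarize
        sd = float(np.std(np.array(vals, dtype=float), ddof=1)) if len(vals) > 1 else 0.0
        sd = Decimal(repr(sd)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
        return float(mean), float(sd)

    mr, sr = agg([r.recall for r in rows])
    mp, sp = agg([r.precision for r in rows])
    mf, sf = agg([r.f1 for r in rows])
    return EvaluationReport(
        rows=rows,
        mean_recall=mr, mean_precision=mp, mean_f1=mf,
        std_recall=sr, std_precision=sp, std_f1=sf,
    )


def compare_methods(
    methods: dict[str, "callable"],
    scenes: list,
    iou_thresh: float = DEFAULT_MATCH_IOU,
) -> pd.DataFrame:
    """Pooled precision/recall/F1 per named segmenter over an evaluation set.

    Counts are pooled over all scenes first, then converted to the three
    percentage metrics — the method-comparison table layout.
    """
    if len(methods) < 2:
        raise ParameterError("need at least two methods to compare")
    records = []
    for name, segmenter in methods.items():
        total = MatchResult(0, 0, 0)
        for scene in scenes:
            pred = segmenter(scene.image)
            total = total + match_instances(pred, scene.mask, iou_thresh)
        row = metrics(total, image_id=name)
        records.append(
            {"method": name, "precision": row.precision,
             "recall": row.recall, "f1": row.f1}
        )
    return pd.DataFrame(records)


def load_benchmark_counts() -> pd.DataFrame:
    """Published per-image detection counts for the HER2-SISH benchmark.

    Twenty test ROIs evaluated under two protocols: ``visual`` (every
    object resembling a nucleus is ground truth) and ``expert``
    (expert-marked nuclei only).  Columns carry the reported TP/FP/FN
    triples together with the reported percentage metrics; the package
    recomputes the latter from the former.
    """
    from importlib import resources

    with resources.files("sishdetect.data").joinpath("benchmark_counts.csv").open() as fh:
        return pd.read_csv(fh, dtype={"image_id": str})
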