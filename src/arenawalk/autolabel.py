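"""Fully automatic head/back labelling by progressive erosion.

Each frame is converted to grey, Gaussian-blurred and binarised with a
fixed dark threshold to isolate the insect. The single foreground blob is
then eroded iteratively until it falls apart into two regions; the smaller
is the head, the larger the back. Bounding boxes and centroids are
computed on the full (pre-erosion) blob pixels, assigned to the nearer
eroded-core centroid, so each part box covers the whole lobe rather than
its eroded remnant. The labelled frames can be exported as a
detection-format dataset (normalised ``class cx cy w h`` text annotations)
with a seeded train/val/test split, and predicted boxes can be scored
against ground truth with precision/recall/F1/accuracy, IoU and mAP.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.ndimage as ndi

from .errors import InvalidParameterError, NoInsectError, NoSplitError

__all__ = [
    "LabelParams",
    "PartDetection",
    "ClassMetrics",
    "DetectionMetrics",
    "SplitCounts",
    "preprocess",
    "split_body",
    "label_frame",
    "export_dataset",
    "load_annotation",
    "evaluate_detection",
    "f1_score",
    "bbox_iou",
]

_STRUCTURE = np.ones((3, 3), dtype=bool)  # 8-connected erosion/labelling
CLASS_IDS = {"head": 0, "back": 1}


@dataclass(frozen=True)
class LabelParams:
    """Tunable parameters of the classical labeller."""

    blur_kernel: int = 5
    threshold: float = 60.0
    max_iters: int = 10
    min_area: int = 5
    crop: bool = True               # erode on the insect-bbox crop
    axis_split_fallback: bool = False


@dataclass(frozen=True)
class PartDetection:
    """One labelled body part in one frame.

    ``bbox`` is (x_min, y_min, x_max, y_max), half-open, px.
    """

    part: str
    bbox: tuple[float, float, float, float]
    centroid: tuple[float, float]
    area: float
    confidence: float = 1.0

    def __post_init__(self):
        x0, y0, x1, y1 = self.bbox
        cx, cy = self.centroid
        if not (x0 <= cx <= x1 and y0 <= cy <= y1):
            raise InvalidParameterError("centroid must lie inside bbox")
        if self.area <= 0:
            raise InvalidParameterError("area must be > 0")


def _to_grey(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.size == 0:
        raise InvalidParameterError("empty image")
    if frame.ndim == 3:
        # ITU-R BT.601 luma
        return frame[..., 0] * 0.299 + frame[..., 1] * 0.587 + frame[..., 2] * 0.114
    if frame.ndim != 2:
        raise InvalidParameterError("frame must be 2-D grey or 3-D colour")
    return frame.astype(float)


def preprocess(frame: np.ndarray, blur_kernel: int = 5,
               threshold: float = 60.0) -> np.ndarray:
    """Blur and binarise one frame; foreground = pixels darker than threshold."""
    if not 0 < threshold < 255:
        raise InvalidParameterError("threshold must be in (0, 255)")
    if blur_kernel < 1 or blur_kernel % 2 == 0:
        raise InvalidParameterError("blur kernel must be odd and >= 1")
    grey = _to_grey(frame)
    if blur_kernel > 1:
        # sigma from kernel size by the common default rule
        sigma = 0.3 * ((blur_kernel - 1) * 0.5 - 1) + 0.8
        grey = ndi.gaussian_filter(grey, sigma, radius=blur_kernel // 2)
    return grey < threshold


def split_body(mask: np.ndarray, max_iters: int = 10, min_area: int = 5):
    """Erode a blob until it separates into head and back regions.

    Applies 0, 1, ... ``max_iters`` erosions (3x3 square element); at the
    first iteration where the foreground contains >= 2 components above
    ``min_area`` px^2, the two largest are returned as
    ``(head_mask, back_mask, n_erosions)`` with head = smaller area.

    Raises
    ------
    NoSplitError
        If no split occurs within ``max_iters`` erosions.
    """
    current = np.asarray(mask, dtype=bool)
    if not current.any():
        raise InvalidParameterError("mask has no foreground")
    for n_er in range(max_iters + 1):
        lbl, n = ndi.label(current, structure=_STRUCTURE)
        if n >= 2:
            areas = np.bincount(lbl.ravel())[1:]
            keep = np.flatnonzero(areas >= min_area) + 1
            if len(keep) >= 2:
                # two largest; ties broken by lower label index (scan order)
                order = sorted(keep, key=lambda l: (-areas[l - 1], l))
                big2 = order[:2]
                a, b = big2
                if areas[a - 1] <= areas[b - 1]:
                    head_lbl, back_lbl = a, b
                else:
                    head_lbl, back_lbl = b, a
                return lbl == head_lbl, lbl == back_lbl, n_er
        if n_er < max_iters:
            current = ndi.binary_erosion(current, structure=_STRUCTURE)
            if not current.any():
                break
    raise NoSplitError(f"no two-region split within {max_iters} erosions")


def _pixels_stats(xs: np.ndarray, ys: np.ndarray):
    centroid = (float(xs.mean()), float(ys.mean()))
    bbox = (float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))
    return centroid, bbox, float(len(xs))


def _principal_axis_split(xs, ys):
    """Fallback: split blob pixels by the line through the centroid
    perpendicular to the principal axis."""
    pts = np.stack([xs - xs.mean(), ys - ys.mean()], axis=1)
    cov = pts.T @ pts
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    proj = pts @ axis
    side = proj >= 0
    if side.all() or (~side).all():
        raise NoSplitError("principal-axis fallback produced one region")
    return side


def label_frame(frame: np.ndarray, params: LabelParams = LabelParams(),
                motion_dir: tuple[float, float] | None = None):
    """Label head and back in one frame; returns ``(head, back)`` detections.

    The insect is the largest dark component; its blob is split by
    progressive erosion and every blob pixel is then assigned to the
    nearer eroded-core centroid (a two-site Voronoi partition), so the
    reported centroids, areas and boxes describe the full lobes. The
    smaller lobe is the head. On equal areas the tie is broken by the
    component leading along ``motion_dir`` if given, else by scan order.

    Raises
    ------
    NoInsectError
        If no foreground component reaches ``min_area``.
    NoSplitError
        Propagated from :func:`split_body` when the fallback is off.
    """
    mask = preprocess(frame, params.blur_kernel, params.threshold)
    lbl, n = ndi.label(mask, structure=_STRUCTURE)
    if n == 0:
        raise NoInsectError("no foreground found")
    areas = np.bincount(lbl.ravel())[1:]
    main = int(np.argmax(areas)) + 1
    if areas[main - 1] < params.min_area:
        raise NoInsectError("largest component below minimum area")
    blob = lbl == main

    if params.crop:
        sl = ndi.find_objects(blob.astype(np.int8))[0]
        work = blob[sl]
        off_x, off_y = sl[1].start, sl[0].start
    else:
        work, off_x, off_y = blob, 0, 0

    ys_all, xs_all = np.nonzero(work)
    try:
        head_m, back_m, _ = split_body(work, params.max_iters, params.min_area)
        cy_h, cx_h = ndi.center_of_mass(head_m)
        cy_b, cx_b = ndi.center_of_mass(back_m)
        d_h = (xs_all - cx_h) ** 2 + (ys_all - cy_h) ** 2
        d_b = (xs_all - cx_b) ** 2 + (ys_all - cy_b) ** 2
        to_head = d_h <= d_b
    except NoSplitError:
        if not params.axis_split_fallback:
            raise
        to_head = _principal_axis_split(xs_all.astype(float), ys_all.astype(float))

    groups = []
    for sel in (to_head, ~to_head):
        centroid, bbox, area = _pixels_stats(xs_all[sel] + off_x, ys_all[sel] + off_y)
        groups.append((centroid, bbox, area))
    a0, a1 = groups[0][2], groups[1][2]
    if a0 != a1:
        head_i = 0 if a0 < a1 else 1
    elif motion_dir is not None:
        proj = [g[0][0] * motion_dir[0] + g[0][1] * motion_dir[1] for g in groups]
        head_i = int(np.argmax(proj))
    else:
        head_i = 0
    back_i = 1 - head_i
    head = PartDetection("head", groups[head_i][1], groups[head_i][0], groups[head_i][2])
    back = PartDetection("back", groups[back_i][1], groups[back_i][0], groups[back_i][2])
    return head, back


@dataclass(frozen=True)
class SplitCounts:
    train: int
    val: int
    test: int


def export_dataset(detections: Sequence[Sequence[PartDetection]],
                   image_shape: tuple[int, int], out_dir,
                   ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
                   seed: int = 0,
                   images: Sequence[np.ndarray] | None = None) -> SplitCounts:
    """Write a detection dataset with a seeded 70:20:10-style split.

    One annotation file per frame, one line per part:
    ``class_id cx cy w h`` normalised to [0, 1] by the image dimensions.
    Counts follow floor allocation of the val and test ratios with the
    remainder going to train (1200 frames at 70:20:10 -> 840/240/120).
    """
    ratios = tuple(float(r) for r in ratios)
    if any(r < 0 for r in ratios):
        raise InvalidParameterError("ratios must be non-negative")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise InvalidParameterError("ratios must sum to 1")
    n = len(detections)
    if n == 0:
        raise InvalidParameterError("no frames to export")
    h, w = image_shape
    n_val = math.floor(n * ratios[1])
    n_test = math.floor(n * ratios[2])
    n_train = n - n_val - n_test
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = {}
    for pos, idx in enumerate(order):
        split = "train" if pos < n_train else ("val" if pos < n_train + n_val else "test")
        assignment[int(idx)] = split

    out = Path(out_dir)
    for split in ("train", "val", "test"):
        (out / split / "labels").mkdir(parents=True, exist_ok=True)
        if images is not None:
            (out / split / "images").mkdir(parents=True, exist_ok=True)
    for idx, dets in enumerate(detections):
        split = assignment[idx]
        lines = []
        for det in dets:
            x0, y0, x1, y1 = det.bbox
            cx, cy = (x0 + x1) / 2.0 / w, (y0 + y1) / 2.0 / h
            bw, bh = (x1 - x0) / w, (y1 - y0) / h
            lines.append(f"{CLASS_IDS[det.part]} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
        (out / split / "labels" / f"frame_{idx:06d}.txt").write_text("\n".join(lines) + "\n")
        if images is not None:
            import imageio.v3 as iio
            iio.imwrite(out / split / "images" / f"frame_{idx:06d}.png", images[idx])
    (out / "classes.txt").write_text("\n".join(
        name for name, _ in sorted(CLASS_IDS.items(), key=lambda kv: kv[1])) + "\n")
    counts = SplitCounts(n_train, n_val, n_test)
    (out / "manifest.json").write_text(json.dumps({
        "counts": {"train": n_train, "val": n_val, "test": n_test},
        "ratios": list(ratios), "seed": seed, "n_frames": n,
        "image_shape": [h, w],
        "assignment": {str(k): v for k, v in sorted(assignment.items())},
    }, indent=2))
    return counts


def load_annotation(path, image_shape: tuple[int, int]):
    """Read one annotation file back to px boxes: [(part, bbox), ...]."""
    h, w = image_shape
    names = {v: k for k, v in CLASS_IDS.items()}
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        cid, cx, cy, bw, bh = line.split()
        cx, cy, bw, bh = float(cx) * w, float(cy) * h, float(bw) * w, float(bh) * h
        out.append((names[int(cid)],
                    (cx - bw / 2.0, cy - bh / 2.0, cx + bw / 2.0, cy + bh / 2.0)))
    return out


def bbox_iou(a, b) -> float:
    """Intersection over union of two half-open boxes."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    ap: float
    mean_iou: float


@dataclass
class DetectionMetrics:
    """Detection scores per class plus macro averages."""

    per_class: dict[str, ClassMetrics]
    precision: float
    recall: float
    f1: float
    accuracy: float
    iou: float
    map50: float
    iou_threshold: float


def _average_precision(tp_flags: np.ndarray, confs: np.ndarray, n_truth: int) -> float:
    """AP as area under the PR curve with all-point interpolation."""
    if n_truth == 0:
        return 1.0 if len(tp_flags) == 0 else 0.0
    if len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-confs, kind="stable")
    tp = tp_flags[order].astype(float)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_truth
    precision = cum_tp / (cum_tp + cum_fp)
    # monotone precision envelope from the right
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


def evaluate_detection(predicted: Sequence[Sequence[PartDetection]],
                       truth: Sequence[Sequence[PartDetection]],
                       iou_threshold: float = 0.5) -> DetectionMetrics:
    """Score predicted boxes against ground-truth boxes.

    Within each frame and class, predictions are matched to unmatched
    truth boxes greedily by descending IoU; a match with IoU >= threshold
    is a TP, unmatched predictions are FP and unmatched truths FN.
    Accuracy is (TP+TN)/total with TN = 0 (no negative boxes exist in
    detection). AP uses all-point interpolation of the PR curve ranked by
    confidence; ``map50`` is the mean AP over classes at the configured
    threshold. If there are neither truths nor predictions anywhere, all
    metrics are 1 by convention.
    """
    if len(predicted) != len(truth):
        raise InvalidParameterError("predicted and truth frame counts differ")
    if not 0 <= iou_threshold <= 1:
        raise InvalidParameterError("iou_threshold must be in [0, 1]")
    classes = sorted(CLASS_IDS, key=CLASS_IDS.get)
    per_class: dict[str, ClassMetrics] = {}
    any_boxes = any(len(f) for f in predicted) or any(len(f) for f in truth)
    for cls in classes:
        tp = fp = fn = 0
        tp_flags: list[bool] = []
        confs: list[float] = []
        ious: list[float] = []
        n_truth = 0
        for pf, tf in zip(predicted, truth):
            preds = [d for d in pf if d.part == cls]
            truths = [d for d in tf if d.part == cls]
            n_truth += len(truths)
            if preds and truths:
                iou_mat = np.array([[bbox_iou(p.bbox, t.bbox) for t in truths]
                                    for p in preds])
            else:
                iou_mat = np.zeros((len(preds), len(truths)))
            matched_p, matched_t = set(), set()
            while True:
                best = -1.0
                bi = bj = -1
                for i in range(len(preds)):
                    if i in matched_p:
                        continue
                    for j in range(len(truths)):
                        if j in matched_t:
                            continue
                        if iou_mat[i, j] > best:
                            best, bi, bj = iou_mat[i, j], i, j
                if best < iou_threshold or bi < 0:
                    break
                matched_p.add(bi)
                matched_t.add(bj)
                ious.append(best)
            for i, p in enumerate(preds):
                hit = i in matched_p
                tp_flags.append(hit)
                confs.append(p.confidence)
                tp += hit
                fp += not hit
            fn += len(truths) - len(matched_t)
        if tp + fp + fn == 0:
            prec = rec = acc = ap = 1.0
        else:
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            acc = tp / (tp + fp + fn)
            ap = _average_precision(np.array(tp_flags, dtype=bool),
                                    np.array(confs), n_truth)
        per_class[cls] = ClassMetrics(tp=tp, fp=fp, fn=fn, precision=prec,
                                      recall=rec, f1=f1_score(prec, rec),
                                      accuracy=acc, ap=ap,
                                      mean_iou=float(np.mean(ious)) if ious else
                                      (1.0 if tp + fp + fn == 0 else 0.0))
    if not any_boxes:
        return DetectionMetrics(per_class=per_class, precision=1.0, recall=1.0,
                                f1=1.0, accuracy=1.0, iou=1.0, map50=1.0,
                                iou_threshold=iou_threshold)
    ms = list(per_class.values())
    mp = float(np.mean([m.precision for m in ms]))
    mr = float(np.mean([m.recall for m in ms]))
    return DetectionMetrics(
        per_class=per_class, precision=mp, recall=mr, f1=f1_score(mp, mr),
        accuracy=float(np.mean([m.accuracy for m in ms])),
        iou=float(np.mean([m.mean_iou for m in ms])),
        map50=float(np.mean([m.ap for m in ms])),
        iou_threshold=iou_threshold)
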