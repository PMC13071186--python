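import itertools

import numpy as np
import pytest
import scipy.ndimage as ndi

import arenawalk as aw
from arenawalk.autolabel import LabelParams, bbox_iou
from arenawalk.errors import InvalidParameterError, NoInsectError, NoSplitError


def disc_mask(shape, centre, radius):
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    return (xs - centre[0]) ** 2 + (ys - centre[1]) ** 2 <= radius ** 2


class TestPreprocess:
    def test_uniform_white_gives_empty_mask(self):
        assert not aw.preprocess(np.full((20, 20), 255, np.uint8)).any()

    def test_uniform_black_gives_full_mask(self):
        assert aw.preprocess(np.zeros((20, 20), np.uint8)).all()

    def test_mask_matches_true_silhouette(self, control_truth):
        """Blur + fixed threshold recovers the body silhouette (IoU >= 0.9)."""
        for i in (0, 77, 200, 399):
            img, truth_mask = aw.render_frame(control_truth, i, noise_sd=5.0,
                                              seed=i)
            mask = aw.preprocess(img)
            iou = (mask & truth_mask).sum() / (mask | truth_mask).sum()
            assert iou >= 0.9

    def test_parameter_validation(self):
        img = np.zeros((5, 5), np.uint8)
        with pytest.raises(InvalidParameterError):
            aw.preprocess(img, blur_kernel=4)
        with pytest.raises(InvalidParameterError):
            aw.preprocess(img, threshold=0)
        with pytest.raises(InvalidParameterError):
            aw.preprocess(np.empty((0, 0)))


class TestSplitBody:
    def test_presplit_blobs_need_no_erosion(self):
        mask = np.zeros((40, 80), bool)
        mask |= disc_mask(mask.shape, (15, 20), 4)    # ~50 px
        mask |= disc_mask(mask.shape, (60, 20), 8)    # ~200 px
        head, back, n_er = aw.split_body(mask)
        assert n_er == 0
        assert head.sum() < back.sum()
        assert head.sum() == disc_mask(mask.shape, (15, 20), 4).sum()

    def test_dumbbell_splits_when_bridge_erodes(self):
        """The split happens at exactly the erosion count at which the
        bridge vanishes, per an explicit step-by-step oracle."""
        mask = np.zeros((36, 80), bool)
        mask |= disc_mask(mask.shape, (18, 18), 5)
        mask |= disc_mask(mask.shape, (55, 18), 9)
        mask[17:20, 18:55] = True                      # 3-px-wide bridge
        # oracle: erode step by step, note first iteration with two
        # components above the area floor
        cur, expected_iter = mask.copy(), None
        for it in range(11):
            lbl, n = ndi.label(cur, structure=np.ones((3, 3)))
            areas = np.bincount(lbl.ravel())[1:]
            if (areas >= 5).sum() >= 2:
                expected_iter = it
                expected_areas = sorted(areas[areas >= 5], reverse=True)[:2]
                break
            cur = ndi.binary_erosion(cur, structure=np.ones((3, 3)))
        assert expected_iter is not None and expected_iter > 0
        head, back, n_er = aw.split_body(mask)
        assert n_er == expected_iter
        assert (back.sum(), head.sum()) == tuple(expected_areas)

    def test_solid_disc_never_splits(self):
        """A disc of radius 30 px survives 10 square-element erosions
        connected (oracle: erosion shrinks the radius ~1 px per step)."""
        mask = disc_mask((80, 80), (40, 40), 30)
        cur = mask.copy()
        for _ in range(10):
            cur = ndi.binary_erosion(cur, structure=np.ones((3, 3)))
            _, n = ndi.label(cur, structure=np.ones((3, 3)))
            assert n == 1
        with pytest.raises(NoSplitError):
            aw.split_body(mask)

    def test_equal_area_tie_is_deterministic(self):
        mask = np.zeros((30, 60), bool)
        mask[10:20, 5:15] = True
        mask[10:20, 40:50] = True
        h1, b1, _ = aw.split_body(mask)
        h2, b2, _ = aw.split_body(mask)
        assert np.array_equal(h1, h2) and np.array_equal(b1, b2)
        assert h1.sum() == b1.sum() == 100


class TestLabelFrame:
    def test_head_centroid_close_to_truth(self, control_truth):
        for i in (0, 150, 300):
            img, _ = aw.render_frame(control_truth, i, noise_sd=5.0, seed=i)
            head, back = aw.label_frame(img)
            assert np.hypot(*(np.array(head.centroid) - control_truth.head[i])) <= 3.0
            assert np.hypot(*(np.array(back.centroid) - control_truth.back[i])) <= 3.0
            assert head.area <= back.area

    def test_rotating_the_frame_keeps_the_assignment(self, control_truth):
        """Head/back are assigned by area, so a 180-degree rotation maps
        the head onto the rotated head position."""
        img, _ = aw.render_frame(control_truth, 40, noise_sd=0.0)
        h, w = img.shape
        head0, _ = aw.label_frame(img)
        head1, _ = aw.label_frame(np.rot90(img, 2).copy())
        mapped = (w - head0.centroid[0], h - head0.centroid[1])
        assert np.hypot(head1.centroid[0] - mapped[0],
                        head1.centroid[1] - mapped[1]) <= 2.0

    def test_part_boxes_inside_overall_insect_box(self, control_truth):
        img, _ = aw.render_frame(control_truth, 250, noise_sd=5.0, seed=1)
        mask = aw.preprocess(img)
        ys, xs = np.nonzero(mask)
        overall = (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
        for det in aw.label_frame(img):
            assert det.bbox[0] >= overall[0] and det.bbox[1] >= overall[1]
            assert det.bbox[2] <= overall[2] and det.bbox[3] <= overall[3]

    def test_empty_frame_raises_no_insect(self):
        with pytest.raises(NoInsectError):
            aw.label_frame(np.full((50, 50), 255, np.uint8))

    def test_unsplittable_blob_raises_or_falls_back(self):
        img = np.full((80, 80), 200, np.uint8)
        img[disc_mask((80, 80), (40, 40), 25)] = 10
        with pytest.raises(NoSplitError):
            aw.label_frame(img)
        head, back = aw.label_frame(img, LabelParams(axis_split_fallback=True))
        assert head.area <= back.area


class TestExportDataset:
    @staticmethod
    def _dets(n, w=960, h=540, rng=None):
        rng = rng or np.random.default_rng(0)
        out = []
        for _ in range(n):
            x, y = rng.uniform(50, w - 80), rng.uniform(50, h - 80)
            out.append([
                aw.PartDetection("head", (x, y, x + 12, y + 10), (x + 6, y + 5), 120.0),
                aw.PartDetection("back", (x + 10, y, x + 34, y + 18), (x + 22, y + 9), 430.0),
            ])
        return out

    def test_split_counts_for_1200_frames(self, tmp_path):
        counts = aw.export_dataset(self._dets(1200), (540, 960), tmp_path,
                                   (0.7, 0.2, 0.1), seed=0)
        assert (counts.train, counts.val, counts.test) == (840, 240, 120)

    def test_all_to_train_when_ratio_is_one(self, tmp_path):
        counts = aw.export_dataset(self._dets(17), (540, 960), tmp_path,
                                   (1.0, 0.0, 0.0), seed=0)
        assert (counts.train, counts.val, counts.test) == (17, 0, 0)

    def test_bad_ratio_sum_rejected(self, tmp_path):
        with pytest.raises(InvalidParameterError):
            aw.export_dataset(self._dets(5), (540, 960), tmp_path,
                              (0.7, 0.2, 0.2), seed=0)

    def test_annotation_round_trip_preserves_centres(self, tmp_path):
        """Write-read round trip through the normalised text format keeps
        box centres within the 0.5-px quantisation bound."""
        dets = self._dets(20)
        aw.export_dataset(dets, (540, 960), tmp_path, (1.0, 0.0, 0.0), seed=0)
        from arenawalk.autolabel import load_annotation
        for i, frame_dets in enumerate(dets):
            back = load_annotation(tmp_path / "train" / "labels" /
                                   f"frame_{i:06d}.txt", (540, 960))
            assert len(back) == 2
            for (part, bbox), det in zip(back, frame_dets):
                assert part == det.part
                cx = (bbox[0] + bbox[2]) / 2
                cy = (bbox[1] + bbox[3]) / 2
                assert abs(cx - (det.bbox[0] + det.bbox[2]) / 2) <= 0.5
                assert abs(cy - (det.bbox[1] + det.bbox[3]) / 2) <= 0.5


def brute_force_detection_counts(preds, truths, thr):
    """Oracle: exhaustive search over injective prediction-truth
    assignments within a frame and class, maximising the match count."""
    tp = 0
    for pf, tf in zip(preds, truths):
        for cls in ("head", "back"):
            p = [d for d in pf if d.part == cls]
            t = [d for d in tf if d.part == cls]
            best = 0
            for perm in itertools.permutations(range(len(t)), min(len(p), len(t))):
                n = sum(bbox_iou(p[i].bbox, t[j].bbox) >= thr
                        for i, j in enumerate(perm))
                best = max(best, n)
            tp += best
    n_pred = sum(len(f) for f in preds)
    n_truth = sum(len(f) for f in truths)
    return tp, n_pred - tp, n_truth - tp


class TestEvaluateDetection:
    def test_perfect_predictions_score_one(self, control_truth):
        from conftest import truth_detections
        truths = [truth_detections(control_truth, i) for i in range(5)]
        m = aw.evaluate_detection(truths, truths)
        assert m.precision == m.recall == m.f1 == m.map50 == 1.0

    def test_mismatched_frame_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            aw.evaluate_detection([[]], [[], []])

    def test_no_boxes_anywhere_scores_one_by_convention(self):
        m = aw.evaluate_detection([[], []], [[], []])
        assert m.precision == m.recall == m.f1 == 1.0

    def test_counts_match_brute_force_oracle(self):
        """Five frames with hand-placed boxes (2 extra predictions, one
        missed truth) reproduce the exhaustive-matching oracle."""
        def det(part, x, y, w=20, h=16, conf=1.0):
            return aw.PartDetection(part, (x, y, x + w, y + h),
                                    (x + w / 2, y + h / 2), w * h, conf)

        truths, preds = [], []
        for k in range(5):
            truths.append([det("head", 30 + 5 * k, 40), det("back", 80 + 5 * k, 40)])
        preds = [
            [det("head", 31, 41, conf=0.9), det("back", 81, 40, conf=0.8)],
            [det("head", 36, 39, conf=0.95), det("back", 85, 40, conf=0.9),
             det("back", 200, 200, conf=0.4)],               # FP (far away)
            [det("head", 140, 140, conf=0.3), det("back", 90, 41, conf=0.85)],
            [det("head", 45, 40, conf=0.9), det("back", 95, 40, conf=0.9)],
            [det("back", 100, 40, conf=0.7)],                # head missed -> FN
        ]
        tp, fp, fn = brute_force_detection_counts(preds, truths, 0.5)
        m = aw.evaluate_detection(preds, truths, 0.5)
        got = {c: (cm.tp, cm.fp, cm.fn) for c, cm in m.per_class.items()}
        assert sum(v[0] for v in got.values()) == tp
        assert sum(v[1] for v in got.values()) == fp
        assert sum(v[2] for v in got.values()) == fn
        for cm in m.per_class.values():
            assert cm.precision == pytest.approx(cm.tp / (cm.tp + cm.fp))
            assert cm.recall == pytest.approx(cm.tp / (cm.tp + cm.fn))

    def test_f1_is_harmonic_mean(self):
        assert aw.f1_score(0.5, 0.5) == pytest.approx(0.5)
        assert aw.f1_score(1.0, 0.0) == 0.0
        m = aw.f1_score(0.6, 0.8)
        assert m == pytest.approx(2 * 0.6 * 0.8 / 1.4)
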