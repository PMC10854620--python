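"""IoU/GIoU geometry, YOLO reference losses, matching and metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbisim import (
    Annotation,
    Box,
    ConfusionCounts,
    Detection,
    GridTarget,
    LesionClass,
    average_precision,
    classification_loss,
    compute_metrics,
    confidence_loss,
    evaluate,
    f1_score,
    giou,
    giou_loss,
    iou,
    match_detections,
)
from nbisim.detection_eval import (
    read_detections_jsonl,
    write_detections_jsonl,
)

boxes_strategy = st.builds(
    lambda x, y, w, h: Box(x, y, x + w, y + h),
    st.floats(0, 50), st.floats(0, 50),
    st.floats(0.5, 50), st.floats(0.5, 50),
)


class TestGeometry:
    def test_identical_boxes(self):
        b = Box(3, 4, 10, 12)
        assert iou(b, b) == 1.0
        assert giou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(Box(0, 0, 1, 1), Box(5, 5, 6, 6)) == 0.0

    def test_partial_overlap_thirds(self):
        assert iou(Box(0, 0, 2, 2), Box(1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_giou_disjoint_enclosure_penalty(self):
        # IoU 0, union 2, enclosing 3 → GIoU = −1/3
        assert giou(Box(0, 0, 1, 1), Box(2, 0, 3, 1)) == pytest.approx(-1 / 3)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(boxes_strategy, boxes_strategy)
    def test_giou_bounded_by_iou(self, a, b):
        assert giou(a, b) <= iou(a, b) + 1e-12
        assert giou(a, b) > -1.0


def perfect_grid(rng, s2=4, nb=2, nc=3, n_obj=3):
    ind = np.zeros((s2, nb))
    flat = rng.choice(s2 * nb, size=n_obj, replace=False)
    ind[np.unravel_index(flat, (s2, nb))] = 1.0
    conf = ind.copy()
    cls = np.zeros((s2, nc))
    cls[np.arange(s2), rng.integers(0, nc, s2)] = 1.0
    return GridTarget(
        obj_indicator=ind,
        true_confidence=conf, pred_confidence=conf.copy(),
        true_class_prob=cls, pred_class_prob=cls.copy(),
    )


class TestLosses:
    def test_giou_loss_zero_at_perfect(self, rng):
        t = perfect_grid(rng)
        grid_boxes = [
            [Box(i, j, i + 2, j + 2) for j in range(2)] for i in range(4)
        ]
        assert giou_loss(t, grid_boxes, grid_boxes) == 0.0

    def test_giou_loss_single_active_slot(self):
        t = GridTarget(
            obj_indicator=[[1.0]], true_confidence=[[1.0]],
            pred_confidence=[[1.0]], true_class_prob=[[1.0]],
            pred_class_prob=[[1.0]],
        )
        pred = [[Box(0, 0, 1, 1)]]
        true = [[Box(2, 0, 3, 1)]]
        # 1 − (−1/3) = 4/3
        assert giou_loss(t, pred, true) == pytest.approx(4 / 3)

    def test_giou_loss_masked_slots_ignored(self):
        t = GridTarget(
            obj_indicator=[[0.0, 0.0]], true_confidence=[[0.0, 0.0]],
            pred_confidence=[[0.3, 0.9]], true_class_prob=[[1.0]],
            pred_class_prob=[[0.2]],
        )
        pred = [[Box(0, 0, 1, 1), Box(5, 5, 9, 9)]]
        true = [[Box(9, 9, 10, 10), Box(0, 0, 1, 1)]]
        assert giou_loss(t, pred, true) == 0.0

    def test_confidence_loss_near_zero_when_perfect(self, rng):
        t = perfect_grid(rng)
        assert confidence_loss(t) <= t.obj_indicator.size * 1e-6

    def test_confidence_loss_single_term_ln2(self):
        t = GridTarget(
            obj_indicator=[[1.0]], true_confidence=[[1.0]],
            pred_confidence=[[0.5]], true_class_prob=[[1.0]],
            pred_class_prob=[[1.0]],
        )
        assert confidence_loss(t) == pytest.approx(math.log(2), abs=1e-9)

    def test_lambda_noobj_scales_noobj_term_linearly(self, rng):
        t = perfect_grid(rng)
        t.pred_confidence = np.clip(
            t.pred_confidence + rng.uniform(0.05, 0.3, t.pred_confidence.shape),
            0, 1,
        )
        obj_part = confidence_loss(t, lambda_noobj=0.0)
        assert confidence_loss(t, lambda_noobj=1.0) - obj_part == \
            pytest.approx(2 * (confidence_loss(t, lambda_noobj=0.5) - obj_part))

    def test_classification_loss_near_zero_one_hot(self, rng):
        assert classification_loss(perfect_grid(rng)) <= 1e-5

    def test_classification_loss_uniform_prediction(self):
        t = GridTarget(
            obj_indicator=[[1.0]], true_confidence=[[1.0]],
            pred_confidence=[[1.0]],
            true_class_prob=[[1.0, 0.0, 0.0]],
            pred_class_prob=[[0.5, 0.5, 0.5]],
        )
        assert classification_loss(t) == pytest.approx(3 * math.log(2),
                                                       abs=1e-9)

    def test_classification_loss_permutation_invariant(self, rng):
        t = perfect_grid(rng)
        t.pred_class_prob = rng.uniform(0.1, 0.9, t.pred_class_prob.shape)
        perm = rng.permutation(t.true_class_prob.shape[1])
        t2 = GridTarget(
            obj_indicator=t.obj_indicator,
            true_confidence=t.true_confidence,
            pred_confidence=t.pred_confidence,
            true_class_prob=t.true_class_prob[:, perm],
            pred_class_prob=t.pred_class_prob[:, perm],
        )
        assert classification_loss(t) == pytest.approx(classification_loss(t2),
                                                       abs=1e-12)


def make_ann(image_id, boxes):
    return Annotation(image_id, 640, 640, tuple(boxes))


def bruteforce_match(dets, truths, lesion, iou_threshold=0.5):
    """Exhaustive restatement of the greedy matching definition."""
    tp = fp = fn = tn = 0
    for ann in truths:
        gt = [b for b, c in ann.boxes if c is lesion]
        dd = [d for d in dets if d.image_id == ann.image_id
              and d.lesion is lesion]
        if not gt and not dd:
            tn += 1
            continue
        dd = sorted(dd, key=lambda d: -d.confidence)
        used = set()
        for d in dd:
            cands = [(iou(d.box, g), k) for k, g in enumerate(gt)
                     if k not in used and iou(d.box, g) >= iou_threshold]
            if cands:
                best = max(cands, key=lambda t: t[0])[1]
                used.add(best)
                tp += 1
            else:
                fp += 1
        fn += len(gt) - len(used)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def bruteforce_ap(dets, truths, lesion, iou_threshold=0.5):
    """Step-area AP from an explicitly constructed PR curve."""
    n_pos = sum(1 for a in truths for _, c in a.boxes if c is lesion)
    dd = sorted([d for d in dets if d.lesion is lesion],
                key=lambda d: -d.confidence)
    used = {a.image_id: set() for a in truths}
    gt = {a.image_id: [b for b, c in a.boxes if c is lesion] for a in truths}
    points = [(0.0, 1.0)]
    tp = fp = 0
    for d in dd:
        cands = [(iou(d.box, g), k) for k, g in enumerate(gt[d.image_id])
                 if k not in used[d.image_id] and
                 iou(d.box, g) >= iou_threshold]
        if cands:
            used[d.image_id].add(max(cands, key=lambda t: t[0])[1])
            tp += 1
        else:
            fp += 1
        points.append((tp / n_pos, tp / (tp + fp)))
    area = 0.0
    for (r0, _), (r1, p1) in zip(points, points[1:]):
        area += (r1 - r0) * p1
    return area


def random_toy_scene(seed):
    rng = np.random.default_rng(seed)
    truths, dets = [], []
    for i in range(3):
        boxes = []
        for _ in range(rng.integers(0, 3)):
            x, y = rng.uniform(0, 500, 2)
            boxes.append((Box(x, y, x + rng.uniform(20, 100),
                              y + rng.uniform(20, 100)),
                          LesionClass.from_index(int(rng.integers(0, 2)))))
        truths.append(make_ann(f"img{i}", boxes))
        for _ in range(rng.integers(0, 3)):
            x, y = rng.uniform(0, 500, 2)
            dets.append(Detection(
                f"img{i}",
                Box(x, y, x + rng.uniform(20, 100), y + rng.uniform(20, 100)),
                LesionClass.from_index(int(rng.integers(0, 2))),
                float(rng.uniform(0.05, 0.99)),
            ))
        # echo some truths with jitter so TPs occur
        for b, c in boxes:
            if rng.uniform() < 0.7:
                j = rng.uniform(-5, 5, 4)
                dets.append(Detection(
                    f"img{i}",
                    Box(b.x_min + j[0], b.y_min + j[1],
                        b.x_max + j[2], b.y_max + j[3]),
                    c, float(rng.uniform(0.5, 1.0)),
                ))
    return dets, truths


class TestMatching:
    def test_perfect_detections(self):
        truths = [
            make_ann("a", [(Box(0, 0, 50, 50), LesionClass.SCC),
                           (Box(100, 100, 180, 160), LesionClass.POLYP)]),
            make_ann("b", []),
        ]
        dets = [Detection(a.image_id, b, c, 0.9)
                for a in truths for b, c in a.boxes]
        counts = match_detections(dets, truths)
        assert vars(counts[LesionClass.SCC]) == dict(tp=1, fp=0, fn=0, tn=1)
        assert vars(counts[LesionClass.POLYP]) == dict(tp=1, fp=0, fn=0, tn=1)
        assert vars(counts[LesionClass.DYSPLASIA]) == dict(tp=0, fp=0, fn=0,
                                                           tn=2)

    def test_greedy_one_to_one_double_detection(self):
        truths = [make_ann("a", [(Box(0, 0, 100, 100), LesionClass.SCC)])]
        dets = [
            Detection("a", Box(0, 0, 100, 100), LesionClass.SCC, 0.9),
            Detection("a", Box(5, 5, 105, 105), LesionClass.SCC, 0.8),
        ]
        counts = match_detections(dets, truths)[LesionClass.SCC]
        assert (counts.tp, counts.fp) == (1, 1)

    def test_unknown_image_id_rejected(self):
        truths = [make_ann("a", [])]
        dets = [Detection("zzz", Box(0, 0, 10, 10), LesionClass.SCC, 0.5)]
        with pytest.raises(KeyError, match="zzz"):
            match_detections(dets, truths)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        dets, truths = random_toy_scene(seed)
        counts = match_detections(dets, truths)
        for lesion in LesionClass:
            oracle = bruteforce_match(dets, truths, lesion)
            assert vars(counts[lesion]) == vars(oracle)

    def test_invariant_under_input_permutation(self):
        dets, truths = random_toy_scene(99)
        base = match_detections(dets, truths)
        rng = np.random.default_rng(1)
        shuffled = [dets[i] for i in rng.permutation(len(dets))]
        # same multiset of confidences but different tie order: restrict to
        # distinct-confidence scenes, which random_toy_scene provides
        assert len({d.confidence for d in dets}) == len(dets)
        perm = match_detections(shuffled, truths)
        for lesion in LesionClass:
            assert vars(base[lesion]) == vars(perm[lesion])


class TestMetrics:
    @pytest.mark.parametrize(
        "precision, recall, f1_2dp",
        [(0.99, 0.86, 0.92), (0.56, 0.39, 0.46), (0.65, 0.78, 0.71)],
    )
    def test_f1_harmonic_mean_at_two_decimals(self, precision, recall, f1_2dp):
        assert round(f1_score(precision, recall), 2) == f1_2dp

    def test_degenerate_counts_conventions(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
        assert (m.specificity, m.accuracy) == (1.0, 1.0)

    def test_all_outputs_within_unit_interval(self, rng):
        for _ in range(50):
            c = ConfusionCounts(*(int(v) for v in rng.integers(0, 20, 4)))
            m = compute_metrics(c)
            for v in vars(m).values():
                assert 0.0 <= v <= 1.0

    def test_f1_equals_precision_when_balanced(self):
        m = compute_metrics(ConfusionCounts(tp=6, fp=2, fn=2, tn=1))
        assert m.precision == m.recall == m.f1


class TestAveragePrecision:
    def test_single_correct_detection(self):
        truths = [make_ann("a", [(Box(0, 0, 50, 50), LesionClass.SCC)])]
        dets = [Detection("a", Box(0, 0, 50, 50), LesionClass.SCC, 0.9)]
        assert average_precision(dets, truths, LesionClass.SCC) == 1.0

    def test_trailing_false_positive_keeps_ap_one(self):
        truths = [make_ann("a", [(Box(0, 0, 50, 50), LesionClass.SCC)])]
        dets = [
            Detection("a", Box(0, 0, 50, 50), LesionClass.SCC, 0.9),
            Detection("a", Box(300, 300, 400, 400), LesionClass.SCC, 0.8),
        ]
        assert average_precision(dets, truths, LesionClass.SCC) == 1.0

    def test_leading_false_positive_lowers_ap(self):
        truths = [make_ann("a", [(Box(0, 0, 50, 50), LesionClass.SCC)])]
        correct = Detection("a", Box(0, 0, 50, 50), LesionClass.SCC, 0.7)
        spurious = Detection("a", Box(300, 300, 400, 400), LesionClass.SCC,
                             0.95)
        assert average_precision([correct], truths, LesionClass.SCC) == 1.0
        assert average_precision([spurious, correct], truths,
                                 LesionClass.SCC) == pytest.approx(0.5)

    def test_no_ground_truth_is_error_not_zero(self):
        truths = [make_ann("a", [(Box(0, 0, 50, 50), LesionClass.SCC)])]
        with pytest.raises(ValueError, match="polyp"):
            average_precision([], truths, LesionClass.POLYP)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_pr_curve(self, seed):
        dets, truths = random_toy_scene(seed)
        for lesion in (LesionClass.DYSPLASIA, LesionClass.SCC):
            n_pos = sum(1 for a in truths for _, c in a.boxes if c is lesion)
            if n_pos == 0:
                continue
            got = average_precision(dets, truths, lesion)
            assert got == pytest.approx(bruteforce_ap(dets, truths, lesion),
                                        abs=1e-9)


class TestEvaluateAndIo:
    def test_evaluate_bundles_map50(self):
        truths = [
            make_ann("a", [(Box(0, 0, 50, 50), LesionClass.SCC)]),
            make_ann("b", [(Box(10, 10, 90, 90), LesionClass.POLYP)]),
        ]
        dets = [Detection(a.image_id, b, c, 0.9)
                for a in truths for b, c in a.boxes]
        report = evaluate(dets, truths)
        assert report.map50 == 1.0
        assert set(report.ap50) == {LesionClass.SCC, LesionClass.POLYP}
        frame = report.to_frame()
        assert list(frame["class"]) == ["dysplasia", "SCC", "polyp"]

    def test_jsonl_round_trip(self):
        dets = [
            Detection("x", Box(1.5, 2.5, 30.0, 40.0), LesionClass.DYSPLASIA,
                      0.75),
            Detection("y", Box(0, 0, 10, 10), LesionClass.POLYP, 0.5),
        ]
        assert read_detections_jsonl(write_detections_jsonl(dets)) == dets
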