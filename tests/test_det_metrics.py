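"""Detection metric calculus: closed-form cases, brute-force oracles, and
the published reference-table identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apexseg.benchmarks import (REFERENCE_DETECTION_METRICS,
                                REFERENCE_READER_METRICS)
from apexseg.det_metrics import (BoxAnnotation, Detection, DetectionConfusion,
                                 average_precision, box_iou,
                                 diagnosis_from_detections, f1, f1_from_pr,
                                 match_detections, mean_ap, paired_t_test,
                                 pr_curve, precision, recall, roc_auc)


def random_scene(rng, n_dets=5, n_truths=4, categories=(0, 1)):
    truths = [BoxAnnotation(int(rng.integers(0, len(categories))),
                            float(rng.uniform(0.2, 0.8)),
                            float(rng.uniform(0.2, 0.8)),
                            float(rng.uniform(0.05, 0.3)),
                            float(rng.uniform(0.05, 0.3)))
              for _ in range(n_truths)]
    dets = []
    for _ in range(n_dets):
        if truths and rng.random() < 0.7:   # perturb a truth
            t = truths[int(rng.integers(0, len(truths)))]
            dets.append(Detection(t.category,
                                  float(np.clip(t.cx + rng.normal(0, 0.05),
                                                0.1, 0.9)),
                                  float(np.clip(t.cy + rng.normal(0, 0.05),
                                                0.1, 0.9)),
                                  t.w, t.h,
                                  confidence=float(rng.uniform(0, 1))))
        else:
            dets.append(Detection(int(rng.integers(0, len(categories))),
                                  float(rng.uniform(0.2, 0.8)),
                                  float(rng.uniform(0.2, 0.8)),
                                  float(rng.uniform(0.05, 0.3)),
                                  float(rng.uniform(0.05, 0.3)),
                                  confidence=float(rng.uniform(0, 1))))
    return dets, truths


def brute_force_match(dets, truths, thr):
    """Oracle: literal restatement of the greedy one-to-one procedure."""
    per_cat = {}
    for cat in {d.category for d in dets} | {t.category for t in truths}:
        ds = sorted([i for i, d in enumerate(dets) if d.category == cat],
                    key=lambda i: (-dets[i].confidence, i))
        ts = [j for j, t in enumerate(truths) if t.category == cat]
        used = []
        tp = 0
        for i in ds:
            candidates = [(box_iou(dets[i], truths[j]), j)
                          for j in ts if j not in used]
            candidates = [(v, j) for v, j in candidates if v >= thr]
            if candidates:
                best = max(candidates, key=lambda vj: vj[0])
                used.append(best[1])
                tp += 1
        per_cat[cat] = (tp, len(ds) - tp, len(ts) - tp)
    return per_cat


# -- box IoU ---------------------------------------------------------------

def test_box_iou_identical_is_one():
    b = BoxAnnotation(0, 0.5, 0.5, 0.2, 0.4)
    assert box_iou(b, b) == pytest.approx(1.0)


def test_box_iou_disjoint_is_zero():
    a = BoxAnnotation(0, 0.2, 0.2, 0.1, 0.1)
    b = BoxAnnotation(0, 0.8, 0.8, 0.1, 0.1)
    assert box_iou(a, b) == 0.0


def test_box_iou_half_overlapping_halves():
    a = BoxAnnotation(0, 0.25, 0.5, 0.5, 1.0)
    b = BoxAnnotation(0, 0.5, 0.5, 0.5, 1.0)
    assert box_iou(a, b) == pytest.approx(1 / 3)


# -- matching --------------------------------------------------------------

def test_exact_hit_is_tp():
    t = BoxAnnotation(0, 0.5, 0.5, 0.2, 0.2)
    d = Detection(0, 0.5, 0.5, 0.2, 0.2, confidence=0.9)
    m = match_detections([d], [t], 0.5)
    assert m.pooled == DetectionConfusion(1, 0, 0)


def test_double_detection_yields_one_fp():
    t = BoxAnnotation(0, 0.5, 0.5, 0.2, 0.2)
    d1 = Detection(0, 0.5, 0.5, 0.2, 0.2, confidence=0.9)
    d2 = Detection(0, 0.51, 0.5, 0.2, 0.2, confidence=0.6)
    m = match_detections([d1, d2], [t], 0.5)
    assert m.pooled == DetectionConfusion(1, 1, 0)
    assert m.det_is_tp == [True, False]


def test_category_mismatch_never_matches():
    t = BoxAnnotation(0, 0.5, 0.5, 0.2, 0.2)
    d = Detection(1, 0.5, 0.5, 0.2, 0.2, confidence=0.9)
    m = match_detections([d], [t], 0.5)
    assert m.pooled == DetectionConfusion(0, 1, 1)


def test_matching_agrees_with_brute_force_on_random_scenes(rng):
    for _ in range(300):
        dets, truths = random_scene(rng,
                                    n_dets=int(rng.integers(0, 7)),
                                    n_truths=int(rng.integers(1, 6)))
        m = match_detections(dets, truths, 0.5)
        oracle = brute_force_match(dets, truths, 0.5)
        got = {c: (v.tp, v.fp, v.fn) for c, v in m.per_category.items()}
        assert got == oracle


# -- precision / recall / F1 ----------------------------------------------

@pytest.mark.parametrize("tp,fp,fn", [(3, 1, 2), (0, 0, 0), (5, 0, 0),
                                      (0, 4, 3)])
def test_f1_is_harmonic_mean_of_precision_recall(tp, fp, fn):
    c = DetectionConfusion(tp, fp, fn)
    p, r = precision(c), recall(c)
    expected = 2 * p * r / (p + r) if p + r else 0.0
    assert f1(c) == pytest.approx(expected)


def test_f1_reproduces_reference_operating_points():
    """Every published P/R pair reproduces its printed F1 to 3 decimals."""
    for row in REFERENCE_DETECTION_METRICS.values():
        assert f1_from_pr(row["precision"], row["recall"]) == \
            pytest.approx(row["f1"], abs=5e-4)
    for phase in REFERENCE_READER_METRICS.values():
        for row in phase.values():
            assert f1_from_pr(row["precision"], row["recall"]) == \
                pytest.approx(row["f1"], abs=5e-4)


def test_reference_map_is_category_mean():
    per_cat = [row["map50"] for name, row in
               REFERENCE_DETECTION_METRICS.items() if name != "All"]
    assert np.mean(per_cat) == pytest.approx(
        REFERENCE_DETECTION_METRICS["All"]["map50"], abs=5e-4)


# -- PR curve and AP -------------------------------------------------------

def _scene_for_sweep():
    """2 truths; detections at 0.9 TP, 0.8 FP, 0.7 TP, 0.6 FP."""
    truths = [BoxAnnotation(0, 0.3, 0.3, 0.2, 0.2),
              BoxAnnotation(0, 0.7, 0.7, 0.2, 0.2)]
    dets = [Detection(0, 0.3, 0.3, 0.2, 0.2, confidence=0.9),
            Detection(0, 0.5, 0.1, 0.1, 0.1, confidence=0.8),
            Detection(0, 0.7, 0.7, 0.2, 0.2, confidence=0.7),
            Detection(0, 0.1, 0.9, 0.1, 0.1, confidence=0.6)]
    return dets, truths


def test_pr_curve_sweep_points():
    dets, truths = _scene_for_sweep()
    curve = pr_curve(dets, truths, 0.5)
    assert curve == [(0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3), (1.0, 0.5)]


def test_ap_matches_hand_summed_interpolated_area():
    # envelope: precision 1 on recall [0,0.5], 2/3 on (0.5,1]
    dets, truths = _scene_for_sweep()
    ap = average_precision(pr_curve(dets, truths, 0.5))
    assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))


def test_single_tp_gives_ap_one():
    t = BoxAnnotation(0, 0.5, 0.5, 0.2, 0.2)
    d = Detection(0, 0.5, 0.5, 0.2, 0.2, confidence=0.9)
    assert average_precision(pr_curve([d], [t], 0.5)) == pytest.approx(1.0)


def test_all_fp_gives_ap_zero():
    t = BoxAnnotation(0, 0.5, 0.5, 0.2, 0.2)
    d = Detection(0, 0.1, 0.1, 0.05, 0.05, confidence=0.9)
    assert average_precision(pr_curve([d], [t], 0.5)) == 0.0


def test_ap_monotonicity_under_appended_detections(rng):
    dets, truths = random_scene(rng, n_dets=5, n_truths=3, categories=(0,))
    base_ap = average_precision(pr_curve(dets, truths, 0.5))
    min_conf = min(d.confidence for d in dets) if dets else 1.0
    fp_low = Detection(0, 0.95, 0.95, 0.05, 0.05,
                       confidence=max(min_conf - 0.05, 0.0))
    assert average_precision(
        pr_curve(dets + [fp_low], truths, 0.5)) <= base_ap + 1e-12
    unmatched = [t for t in truths]
    tp_high = Detection(0, unmatched[0].cx, unmatched[0].cy,
                        unmatched[0].w, unmatched[0].h, confidence=1.0)
    assert average_precision(
        pr_curve(dets + [tp_high], truths, 0.5)) >= base_ap - 1e-12


def test_pr_curve_requires_truths():
    with pytest.raises(ValueError):
        pr_curve([], [], 0.5)


def test_mean_ap_is_arithmetic_mean():
    aps = {0: 0.71, 1: 0.868, 2: 0.802, 3: 0.827}
    assert mean_ap(aps) == pytest.approx(sum(aps.values()) / 4)
    assert mean_ap({2: 0.6}) == pytest.approx(0.6)
    with pytest.raises(ValueError):
        mean_ap({})


# -- ROC / AUC -------------------------------------------------------------

def test_auc_perfect_separation_is_one():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0


def test_auc_all_ties_is_half():
    assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)


def test_auc_matches_all_pairs_concordance(rng):
    scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.4]
    labels = [0, 0, 1, 1, 0, 1]
    conc = 0.0
    npairs = 0
    for s1, l1 in zip(scores, labels):
        for s0, l0 in zip(scores, labels):
            if l1 == 1 and l0 == 0:
                npairs += 1
                conc += 1.0 if s1 > s0 else (0.5 if s1 == s0 else 0.0)
    assert roc_auc(scores, labels) == pytest.approx(conc / npairs)


def test_auc_agrees_with_sklearn(rng):
    from sklearn.metrics import roc_auc_score
    scores = rng.normal(size=40)
    labels = rng.integers(0, 2, size=40)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert roc_auc(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores))


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 10 ** 6))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=12)
    labels = np.array([0, 1] * 6)
    base = roc_auc(scores, labels)
    assert roc_auc(np.exp(scores), labels) == pytest.approx(base)
    assert roc_auc(3 * scores - 7, labels) == pytest.approx(base)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


# -- paired comparison -----------------------------------------------------

def test_paired_t_sign_convention_for_improvement(rng):
    before = np.array([0.5, 0.55, 0.6, 0.52, 0.58])
    after = before + 0.2 + rng.normal(0, 1e-3, size=5)
    t, p = paired_t_test(before, after)
    assert t < 0 and p < 0.05


def test_paired_t_degenerate_zero_variance():
    with pytest.raises(ValueError):
        paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_paired_t_matches_scalar_formula():
    before = [12.0, 14.5, 11.0, 13.0, 15.5]
    after = [13.5, 14.0, 12.5, 15.0, 16.0]
    d = np.array(before) - np.array(after)
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    t, p = paired_t_test(before, after)
    assert t == pytest.approx(t_hand)
    assert 0.0 < p < 1.0


# -- per-side diagnosis ----------------------------------------------------

def test_single_fracture_left_detection():
    calls = diagnosis_from_detections(
        [Detection(1, 0.7, 0.3, 0.2, 0.2, confidence=0.8)])
    assert calls == {"R": False, "L": True}


def test_competing_categories_highest_confidence_wins():
    dets = [Detection(0, 0.3, 0.3, 0.2, 0.2, confidence=0.6),   # Fracture(R)
            Detection(2, 0.3, 0.3, 0.2, 0.2, confidence=0.9)]   # Non-f.(R)
    assert diagnosis_from_detections(dets)["R"] is False
    dets[1] = Detection(2, 0.3, 0.3, 0.2, 0.2, confidence=0.5)
    assert diagnosis_from_detections(dets)["R"] is True


def test_diagnosis_matches_brute_force_rule(rng):
    for _ in range(100):
        dets = [Detection(int(rng.integers(0, 4)), 0.5, 0.5, 0.2, 0.2,
                          confidence=float(rng.uniform(0, 1)))
                for _ in range(int(rng.integers(0, 6)))]
        calls = diagnosis_from_detections(dets)
        for side, frac_cat, nonfrac_cat in (("R", 0, 2), ("L", 1, 3)):
            side_dets = [d for d in dets if d.category in (frac_cat,
                                                           nonfrac_cat)]
            if not side_dets:
                assert calls[side] is False
            else:
                top = max(side_dets, key=lambda d: d.confidence)
                assert calls[side] == (top.category == frac_cat)
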