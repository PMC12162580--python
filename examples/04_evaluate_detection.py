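"""Run the toy detector over phantoms and compute the detection metrics:
per-category precision/recall/F1, AP and mAP@0.5."""

import numpy as np

from apexseg.benchmarks import easy_benchmark_config
from apexseg.det_metrics import (CATEGORY_NAMES, average_precision,
                                 match_detections, mean_ap, precision,
                                 recall, f1)
from apexseg.io import pixel_box_to_annotation
from apexseg.phantom import generate_dataset
from apexseg.toydet import ToyDetectorConfig, detect

_, test = generate_dataset(100, easy_benchmark_config(), seed=3,
                           split_ratio=0.01)
det_cfg = ToyDetectorConfig(jitter=0.02, miss_rate=0.1, flip_rate=0.1,
                            spurious_rate=0.1)

records, n_truth = [], {}
pooled_tp = pooled_fp = pooled_fn = 0
for s in test:
    truths = [pixel_box_to_annotation(b, s.image.shape[0]) for b in s.boxes]
    dets = detect(s, det_cfg, seed=1)
    m = match_detections(dets, truths, 0.5)
    p = m.pooled
    pooled_tp, pooled_fp, pooled_fn = (pooled_tp + p.tp, pooled_fp + p.fp,
                                       pooled_fn + p.fn)
    for t in truths:
        n_truth[t.category] = n_truth.get(t.category, 0) + 1
    for cat, conf in m.per_category.items():
        cd = [d for d in dets if d.category == cat]
        flags = match_detections(cd, [t for t in truths
                                      if t.category == cat], 0.5).det_is_tp
        records += [(cat, d.confidence, fl) for d, fl in zip(cd, flags)]

aps = {}
for cat in sorted(n_truth):
    rs = sorted([r for r in records if r[0] == cat], key=lambda r: -r[1])
    tp = fp = 0
    curve = []
    for _, _, is_tp in rs:
        tp, fp = tp + is_tp, fp + (not is_tp)
        curve.append((tp / n_truth[cat], tp / (tp + fp)))
    aps[cat] = average_precision(curve)
    print(f"{CATEGORY_NAMES[cat]:16s} AP@0.5 = {aps[cat]:.3f} "
          f"({n_truth[cat]} truths)")

from apexseg.det_metrics import DetectionConfusion
pooled = DetectionConfusion(pooled_tp, pooled_fp, pooled_fn)
print(f"pooled precision {precision(pooled):.3f}  recall "
      f"{recall(pooled):.3f}  F1 {f1(pooled):.3f}")
print(f"mAP@0.5 = {mean_ap(aps):.3f}")
# mAP is the plain mean of the four per-category APs; the toy detector's
# error knobs (miss/flip/spurious rates) move it over the full [0,1] range.
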