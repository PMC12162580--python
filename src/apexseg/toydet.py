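"""A deliberately trivial box detector for exercising the evaluation
pipeline end-to-end on phantoms.

It is *not* a learned detector: it perturbs the ground-truth geometry with
seeded jitter, flips the category with a configurable error rate, drops
boxes, and emits spurious ones, with confidences correlated with
correctness.  That yields detection sets whose PR curves, AP and mAP sweep
the full quality range as the error knobs move — which is all the
evaluation machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .det_metrics import Detection
from .io import pixel_box_to_annotation
from .phantom import (CAT_FRACTURE_L, CAT_FRACTURE_R, CAT_NONFRACTURE_L,
                      CAT_NONFRACTURE_R, PhantomSlice)

_FLIP = {CAT_FRACTURE_R: CAT_NONFRACTURE_R, CAT_NONFRACTURE_R: CAT_FRACTURE_R,
         CAT_FRACTURE_L: CAT_NONFRACTURE_L, CAT_NONFRACTURE_L: CAT_FRACTURE_L}


@dataclass(frozen=True)
class ToyDetectorConfig:
    jitter: float = 0.02        # box corner noise, fraction of image side
    miss_rate: float = 0.1      # probability of dropping a true box
    flip_rate: float = 0.1      # probability of mislabelling the category
    spurious_rate: float = 0.1  # expected spurious boxes per image


def detect(slice_: PhantomSlice, config: ToyDetectorConfig = ToyDetectorConfig(),
           seed: int = 0) -> list[Detection]:
    """Emit noisy detections for one phantom slice."""
    rng = np.random.default_rng([int(seed), int(slice_.seed_used), 0x70D])
    size = slice_.image.shape[0]
    dets: list[Detection] = []
    for box in slice_.boxes:
        if rng.random() < config.miss_rate:
            continue
        ann = pixel_box_to_annotation(box, size)
        j = config.jitter
        cx = float(np.clip(ann.cx + rng.normal(0, j), 0.01, 0.99))
        cy = float(np.clip(ann.cy + rng.normal(0, j), 0.01, 0.99))
        w = float(np.clip(ann.w * (1 + rng.normal(0, j * 4)), 0.02, 1.0))
        h = float(np.clip(ann.h * (1 + rng.normal(0, j * 4)), 0.02, 1.0))
        flipped = rng.random() < config.flip_rate
        cat = _FLIP[ann.category] if flipped else ann.category
        conf = float(np.clip(rng.uniform(0.3, 0.6) if flipped
                             else rng.uniform(0.5, 0.99), 0.0, 1.0))
        dets.append(Detection(cat, cx, cy, w, h, confidence=conf))
    n_spur = rng.poisson(config.spurious_rate)
    for _ in range(n_spur):
        cat = int(rng.integers(0, 4))
        dets.append(Detection(cat,
                              float(rng.uniform(0.15, 0.85)),
                              float(rng.uniform(0.15, 0.85)),
                              float(rng.uniform(0.05, 0.2)),
                              float(rng.uniform(0.05, 0.2)),
                              confidence=float(rng.uniform(0.05, 0.5))))
    return dets
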