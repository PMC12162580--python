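"""Ablation harness: train the four variants under shared seeds and emit a
per-class IoU/Dice table.

The four variants (base UNet, +SK, +TEB, improved) are built from the same
backbone spec and the same seed, so every layer present in more than one
variant starts from bit-identical parameters; the comparison isolates the
skip modules.  Cells are means over the supplied seeds of held-out-split
evaluation.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field

import numpy as np

from .arch import ModelSpec, variant_spec, VARIANT_NAMES
from .io import config_hash
from .phantom import CLASS_NAMES, OC, ICA, SS
from .seg_metrics import evaluate_dataset
from .training import TrainConfig, predict, train

CLASS_ORDER = (OC, ICA, SS)
COLUMNS = ("mIoU", "IoU-OC", "IoU-ICA", "IoU-SS",
           "mDice", "Dice-OC", "Dice-ICA", "Dice-SS")


@dataclass
class AblationResult:
    """variant -> column -> value, plus run provenance."""
    cells: dict                      # variant -> {column: float}
    miou_with_background: dict = field(default_factory=dict)
    mdice_with_background: dict = field(default_factory=dict)
    seeds: tuple = ()
    config_hash_: str = ""

    def row(self, variant: str) -> list[float]:
        return [self.cells[variant][c] for c in COLUMNS]


def _evaluate(params, spec, test_set, aggregation: str = "macro"):
    preds = [predict(params, spec, s.image) for s in test_set]
    truths = [s.mask for s in test_set]
    fg = evaluate_dataset(preds, truths, classes=CLASS_ORDER,
                         include_background=False, aggregation=aggregation)
    bg = evaluate_dataset(preds, truths, classes=CLASS_ORDER,
                         include_background=True, aggregation=aggregation)
    return fg, bg


def run_ablation(dataset, model_base: ModelSpec, train_config: TrainConfig,
                 seeds, variants=VARIANT_NAMES,
                 aggregation: str = "macro") -> AblationResult:
    """Train every variant for every seed and average the test metrics.

    ``dataset`` is a (train_set, test_set) pair of phantom slices.
    """
    seeds = tuple(int(s) for s in seeds)
    if not seeds:
        raise ValueError("need at least one seed")
    train_set, test_set = dataset
    cells: dict = {}
    miou_bg: dict = {}
    mdice_bg: dict = {}
    for name in variants:
        spec = variant_spec(name, model_base)
        rows = []
        bg_rows = []
        for seed in seeds:
            cfg = TrainConfig(**{**train_config.__dict__, "seed": seed})
            try:
                params, _ = train(spec, train_set, cfg)
            except Exception as e:
                raise RuntimeError(f"training variant {name!r} failed") from e
            fg, bg = _evaluate(params, spec, test_set, aggregation)
            rows.append([fg.miou] + [fg.per_class[c][0] for c in CLASS_ORDER]
                        + [fg.mdice] + [fg.per_class[c][1] for c in CLASS_ORDER])
            bg_rows.append([bg.miou, bg.mdice])
        mean = np.mean(rows, axis=0)
        cells[name] = dict(zip(COLUMNS, (float(v) for v in mean)))
        bg_mean = np.mean(bg_rows, axis=0)
        miou_bg[name] = float(bg_mean[0])
        mdice_bg[name] = float(bg_mean[1])
    return AblationResult(cells=cells, miou_with_background=miou_bg,
                          mdice_with_background=mdice_bg, seeds=seeds,
                          config_hash_=config_hash({
                              "spec": repr(model_base),
                              "train": repr(train_config),
                              "seeds": seeds}))


def tabulate(result: AblationResult) -> tuple[str, str]:
    """(csv, aligned text) renderings of the ablation table."""
    buf = _stdio.StringIO()
    w = csv.writer(buf)
    w.writerow(("variant",) + COLUMNS)
    for name in result.cells:
        w.writerow([name] + [f"{v:.6f}" for v in result.row(name)])
    csv_text = buf.getvalue()
    widths = [max(len(c), 8) for c in ("variant",) + COLUMNS]
    lines = ["  ".join(c.ljust(w) for c, w in
                       zip(("variant",) + COLUMNS, widths))]
    for name in result.cells:
        vals = [name] + [f"{v:.4f}" for v in result.row(name)]
        lines.append("  ".join(v.ljust(w) for v, w in zip(vals, widths)))
    return csv_text, "\n".join(lines)


def table_from_csv(text: str) -> dict:
    """Inverse of the CSV rendering: variant -> {column: value}."""
    rows = list(csv.reader(_stdio.StringIO(text)))
    header = rows[0][1:]
    return {r[0]: {c: float(v) for c, v in zip(header, r[1:])}
            for r in rows[1:] if r}
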