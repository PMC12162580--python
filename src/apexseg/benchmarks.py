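"""Benchmark conditions and published reference operating points.

Two phantom families drive the desk-scale experiments:

``easy_benchmark_config``
    classes separated by both mean intensity and texture; low noise.  The
    improved variant is expected to segment this family almost perfectly
    within a short training budget.
``texture_benchmark_config``
    the three structures share the same mean intensity and differ only in
    texture grain, so multi-scale texture sensitivity (the selective-kernel
    skips) is the discriminating capability.

``REFERENCE_DETECTION_METRICS`` and ``REFERENCE_READER_METRICS`` hold the
published per-category operating points of the four-category optic-canal
fracture detector and of the resident reader study that this toolkit's
evaluation calculus follows.  They are used as *inputs* to metric-identity
checks (F1 as the harmonic mean of precision and recall; overall mAP@0.5 as
the mean of per-category APs), never as training targets.
"""

from __future__ import annotations

from .arch import ModelSpec, TEBSpec, SKConvSpec
from .phantom import BACKGROUND, ICA, OC, SS, PhantomConfig
from .training import TrainConfig

# category -> (precision, recall, mAP@0.5, F1) ; "All" is the pooled row
REFERENCE_DETECTION_METRICS = {
    "All":             {"precision": 0.795, "recall": 0.743,
                        "map50": 0.802, "f1": 0.768},
    "Non-fracture(R)": {"precision": 0.74, "recall": 0.686,
                        "map50": 0.71, "f1": 0.712},
    "Fracture(R)":     {"precision": 0.886, "recall": 0.739,
                        "map50": 0.868, "f1": 0.806},
    "Non-fracture(L)": {"precision": 0.804, "recall": 0.714,
                        "map50": 0.802, "f1": 0.756},
    "Fracture(L)":     {"precision": 0.75, "recall": 0.833,
                        "map50": 0.827, "f1": 0.789},
}

# reader study: five residents, before/after decision support
REFERENCE_READER_METRICS = {
    "before": {
        "OR1": {"precision": 0.733, "recall": 0.71, "f1": 0.721},
        "OR2": {"precision": 0.69, "recall": 0.645, "f1": 0.667},
        "OR3": {"precision": 0.593, "recall": 0.516, "f1": 0.552},
        "OR4": {"precision": 0.643, "recall": 0.581, "f1": 0.610},
        "OR5": {"precision": 0.703, "recall": 0.613, "f1": 0.655},
    },
    "after": {
        "OR1": {"precision": 0.903, "recall": 0.903, "f1": 0.903},
        "OR2": {"precision": 0.794, "recall": 0.871, "f1": 0.831},
        "OR3": {"precision": 0.757, "recall": 0.903, "f1": 0.824},
        "OR4": {"precision": 0.866, "recall": 0.839, "f1": 0.852},
        "OR5": {"precision": 0.892, "recall": 0.806, "f1": 0.847},
    },
}


def easy_benchmark_config() -> PhantomConfig:
    """Intensity- and texture-separable phantoms, low noise."""
    return PhantomConfig(
        image_size=64,
        intensity_levels={BACKGROUND: 0.40, OC: 0.78, ICA: 0.92, SS: 0.08},
        noise_sd=0.02,
        texture_contrast=0.20,
        texture_scales={BACKGROUND: 3.0, OC: 0.8, ICA: 0.5, SS: 6.0})


def texture_benchmark_config() -> PhantomConfig:
    """Texture-confusable phantoms: all structures share mean intensity."""
    return PhantomConfig(
        image_size=64,
        intensity_levels={BACKGROUND: 0.45, OC: 0.55, ICA: 0.55, SS: 0.55},
        noise_sd=0.02,
        texture_contrast=0.40,
        texture_scales={BACKGROUND: 3.0, OC: 1.0, ICA: 0.0, SS: 6.0})


def benchmark_model_spec() -> ModelSpec:
    """The desk-scale backbone used by the benchmark experiments."""
    return ModelSpec(depth=5, base_channels=4, num_classes=4,
                     sk_spec=SKConvSpec(), teb_spec=TEBSpec())


def benchmark_train_config(seed: int = 0, epochs: int = 20) -> TrainConfig:
    """Desk-scale training budget: small batches, combined CE+Dice loss."""
    return TrainConfig(epochs=epochs, batch_size=4, learning_rate=3e-3,
                       loss_name="combined", seed=seed)
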