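"""Seeded training and inference for the UNet family.

The loop is deliberately plain: Adam over mini-batches of whole images,
cross-entropy (optionally plus a soft-Dice term, which helps the thin optic
canal ring against class imbalance), one log entry per epoch with the mean
training loss and the held-out mIoU over the three foreground classes.
Everything is a deterministic function of (spec, dataset, config): parameter
initialisation, batch order and any augmentation draws all derive from the
config seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .arch import Model, ModelSpec, build_model
from .nn import Adam, Tensor, logsumexp, softmax
from .phantom import PhantomSlice, augment
from .seg_metrics import confusion_matrix_pixels, iou

LOSS_NAMES = ("cross_entropy", "dice", "combined")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 2e-3
    loss_name: str = "cross_entropy"
    augmentation_ops: tuple = ()
    seed: int = 0
    checkpoint_every: int = 0          # 0 disables checkpoints
    checkpoint_dir: str | None = None
    dtype: str = "float32"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.loss_name not in LOSS_NAMES:
            raise ValueError(f"loss_name must be one of {LOSS_NAMES}")


def _stack(slices) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([s.image for s in slices])[:, None, :, :]
    masks = np.stack([s.mask for s in slices]).astype(np.int64)
    return imgs, masks


def one_hot(masks: np.ndarray, num_classes: int,
            dtype=np.float64) -> np.ndarray:
    """(N,H,W) int labels -> (N,K,H,W) indicator array."""
    return np.moveaxis(np.eye(num_classes, dtype=dtype)[masks], -1, 1)


def segmentation_loss(logits: Tensor, masks: np.ndarray, loss_name: str,
                      num_classes: int) -> Tensor:
    """Differentiable loss over a (N,K,H,W) score map."""
    oh = one_hot(masks, num_classes, dtype=logits.data.dtype)
    logp = logits - logsumexp(logits, axis=1, keepdims=True)
    ce = -(Tensor(oh) * logp).sum(axis=1).mean()
    if loss_name == "cross_entropy":
        return ce
    probs = softmax(logits, axis=1)
    inter = (probs * oh).sum(axis=(0, 2, 3))
    denom = probs.sum(axis=(0, 2, 3)) + oh.sum(axis=(0, 2, 3))
    dice = ((inter * 2.0 + 1.0) / (denom + 1.0)).mean()
    dice_loss = 1.0 - dice
    if loss_name == "dice":
        return dice_loss
    return ce + dice_loss


def predict(params: dict, spec: ModelSpec, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax class map; ties break toward the lower class index."""
    model = Model(spec=spec, params=params, seed=-1)
    x = np.asarray(image, dtype=next(iter(params.values())).dtype)
    if x.ndim == 2:
        x = x[None, None]
        squeeze = True
    elif x.ndim == 3:
        x = x[:, None]
        squeeze = False
    else:
        raise ValueError("image must be (H,W) or (N,H,W)")
    logits = model.forward(model.tensors(False), Tensor(x)).data
    out = logits.argmax(axis=1).astype(np.uint8)
    return out[0] if squeeze else out


def validation_miou(params: dict, spec: ModelSpec, slices,
                    batch_size: int = 16) -> float:
    """Mean IoU over the foreground classes, pooled over the whole set."""
    fg = list(range(1, spec.num_classes))
    total = np.zeros((spec.num_classes, spec.num_classes), dtype=np.int64)
    for i in range(0, len(slices), batch_size):
        chunk = slices[i:i + batch_size]
        imgs, masks = _stack(chunk)
        pred = predict(params, spec, imgs[:, 0])
        total += confusion_matrix_pixels(pred, masks, spec.num_classes)
    ious = []
    for c in fg:
        tp = total[c, c]
        fp = total[:, c].sum() - tp
        fn = total[c, :].sum() - tp
        ious.append(iou_from_counts(tp, fp, fn))
    return float(np.mean(ious))


def iou_from_counts(tp: int, fp: int, fn: int) -> float:
    if tp + fp + fn == 0:
        return 1.0
    return tp / (tp + fp + fn)


def train(spec: ModelSpec, train_set, config: TrainConfig,
          val_set=None) -> tuple[dict, list[dict]]:
    """Train a freshly built model; returns (params, per-epoch log).

    The log holds one dict per epoch: ``{"epoch", "loss", "val_miou"}``
    (``val_miou`` is None when no validation set is given).
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    sizes = {s.image.shape for s in train_set}
    if len(sizes) != 1:
        raise ValueError(f"inconsistent image sizes: {sizes}")
    side = next(iter(sizes))[0]
    if side % 2 ** (spec.depth - 1):
        raise ValueError(
            f"image side {side} incompatible with depth {spec.depth}")
    dtype = np.float32 if config.dtype == "float32" else np.float64
    model = build_model(spec, config.seed, input_size=side)
    model.params = {k: v.astype(dtype) for k, v in model.params.items()}
    opt = Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng([config.seed, 0xBEEF])
    log: list[dict] = []
    n = len(train_set)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = [train_set[j] for j in order[start:start + config.batch_size]]
            if config.augmentation_ops:
                aug = []
                for s in batch:
                    aseed = int(rng.integers(0, 2 ** 31 - 1))
                    img, msk = augment(s.image, s.mask,
                                       config.augmentation_ops, seed=aseed)
                    aug.append(PhantomSlice(image=img, mask=msk,
                                            boxes=s.boxes,
                                            seed_used=s.seed_used))
                batch = aug
            imgs, masks = _stack(batch)
            pt = {k: Tensor(v, requires_grad=True)
                  for k, v in model.params.items()}
            logits = model.forward(pt, Tensor(imgs.astype(dtype)))
            loss = segmentation_loss(logits, masks, config.loss_name,
                                     spec.num_classes)
            loss.backward()
            opt.step({k: t.grad for k, t in pt.items()})
            losses.append(float(loss.data))
        entry = {"epoch": epoch + 1, "loss": float(np.mean(losses)),
                 "val_miou": None}
        if val_set:
            entry["val_miou"] = validation_miou(model.params, spec, val_set,
                                                config.batch_size)
        log.append(entry)
        if (config.checkpoint_every and config.checkpoint_dir and
                (epoch + 1) % config.checkpoint_every == 0):
            os.makedirs(config.checkpoint_dir, exist_ok=True)
            np.savez(os.path.join(config.checkpoint_dir,
                                  f"epoch{epoch + 1:03d}.npz"),
                     **model.params)
    return model.params, log
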