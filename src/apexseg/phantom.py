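"""Synthetic orbital-apex CT phantom generator.

Each phantom is an axial slice through the orbital apex rendered at desk
scale: a soft-tissue background with, on each side (patient right = image
left), a dark air-filled sphenoid sinus, a bright contrast-enhanced internal
carotid artery disc touching the sinus' lateral border, and a thin
ring-shaped optic canal wall superior-lateral to the sinus.  A fracture, when
drawn, cuts an angular gap of at least two pixels through the ring and
deposits a displaced bone fragment outside it; the side's bounding-box
category switches from non-fracture to fracture accordingly.

The geometry is deliberately schematic — what it preserves is the statistical
structure the downstream tasks need: four box categories, three segmentation
classes plus background, and class-specific *intensity and texture*
signatures (texture is what the selective-kernel skips exploit).  Mask label
codes are fixed: 0=background, 1=OC, 2=ICA, 3=SS.

All randomness flows from explicit integer seeds; generation is a pure
function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

BACKGROUND, OC, ICA, SS = 0, 1, 2, 3
CLASS_NAMES = {BACKGROUND: "background", OC: "OC", ICA: "ICA", SS: "SS"}

# category ids shared with the YOLO reader/writer (fractures first)
CAT_FRACTURE_R, CAT_FRACTURE_L = 0, 1
CAT_NONFRACTURE_R, CAT_NONFRACTURE_L = 2, 3
CATEGORY_NAMES = ("Fracture(R)", "Fracture(L)",
                  "Non-fracture(R)", "Non-fracture(L)")

AUGMENT_OPS = ("resize", "flip", "normalize", "pad", "rotate", "crop",
               "intensity_shift", "noise")


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one phantom family."""
    image_size: int = 64
    intensity_levels: dict = field(default_factory=lambda: {
        BACKGROUND: 0.40, OC: 0.78, ICA: 0.92, SS: 0.08})
    noise_sd: float = 0.02
    texture_contrast: float = 0.20
    # per-class texture correlation length in px (smaller = finer grain);
    # classes keep distinct texture even when intensities coincide
    texture_scales: dict = field(default_factory=lambda: {
        BACKGROUND: 3.0, OC: 0.8, ICA: 0.5, SS: 6.0})
    fracture_prob_left: float = 0.5
    fracture_prob_right: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32 or self.image_size % 2:
            raise ValueError("image_size must be even and >= 32")
        for cls, v in self.intensity_levels.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"intensity for class {cls} outside [0,1]")
        for p in (self.fracture_prob_left, self.fracture_prob_right):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fracture probabilities must be in [0,1]")
        if not 0.0 <= self.texture_contrast <= 1.0:
            raise ValueError("texture_contrast must be in [0,1]")


@dataclass(frozen=True)
class PixelBox:
    """Half-open pixel extent [x0,x1) x [y0,y1) with a category id."""
    category: int
    x0: int
    y0: int
    x1: int
    y1: int

    def contains(self, row: int, col: int) -> bool:
        return self.y0 <= row < self.y1 and self.x0 <= col < self.x1


@dataclass(frozen=True)
class Primitive:
    """One analytic shape painted into the mask, in paint order.

    kinds: ``ellipse`` (cx, cy, a, b), ``disc`` (cx, cy, r),
    ``ring`` (cx, cy, r_in, r_out, gap_start, gap_end — radians; the gap
    interval is cut out; equal angles mean no gap), ``rect`` (x0, y0, x1, y1
    half-open pixel extent).
    """
    class_id: int
    kind: str
    params: tuple

    def contains(self, row: int, col: int) -> bool:
        """Scalar pixel-center membership test (cx,cy in pixel units)."""
        y, x = row + 0.5, col + 0.5
        if self.kind == "ellipse":
            cx, cy, a, b = self.params
            return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0
        if self.kind == "disc":
            cx, cy, r = self.params
            return (x - cx) ** 2 + (y - cy) ** 2 <= r * r
        if self.kind == "ring":
            cx, cy, r_in, r_out, g0, g1 = self.params
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            if not r_in * r_in <= d2 <= r_out * r_out:
                return False
            if g0 == g1:
                return True
            ang = math.atan2(y - cy, x - cx) % (2 * math.pi)
            width = (g1 - g0) % (2 * math.pi)
            return not (ang - g0) % (2 * math.pi) < width
        if self.kind == "rect":
            x0, y0, x1, y1 = self.params
            return x0 <= x - 0.5 < x1 and y0 <= y - 0.5 < y1
        raise ValueError(f"unknown primitive kind {self.kind!r}")


@dataclass(frozen=True)
class SlicePlan:
    """Geometry of one slice: primitives in paint order plus box extents."""
    primitives: tuple      # of Primitive
    boxes: tuple           # of PixelBox, (right side, left side)
    fractured: tuple       # (right, left) booleans


@dataclass(frozen=True)
class PhantomSlice:
    image: np.ndarray      # float in [0,1], (H, W)
    mask: np.ndarray       # uint8 labels, same shape
    boxes: tuple           # of PixelBox, one per side (R first)
    seed_used: int
    plan: SlicePlan | None = None


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def plan_slice(config: PhantomConfig, seed: int) -> SlicePlan:
    """Lay out the analytic geometry for one slice (no rasterisation)."""
    s = config.image_size
    if s < 32:
        raise ValueError("image too small to place all structures")
    rng = _rng([int(seed), 0x9E3779B9])
    prims: list[Primitive] = []
    boxes: list[PixelBox] = []
    fractured: list[bool] = []
    for side, (cx_frac, prob) in enumerate(
            ((0.26, config.fracture_prob_right),
             (0.74, config.fracture_prob_left))):
        lateral = -1.0 if side == 0 else 1.0  # away from the midline
        jit = rng.uniform(-1.0, 1.0, size=6) * s / 64.0
        cx = cx_frac * s + jit[0] * 1.5
        cy = 0.56 * s + jit[1] * 1.5
        # sphenoid sinus: medial dark ellipse
        a_ss = 0.105 * s + jit[2] * 0.8
        b_ss = 0.135 * s + jit[3] * 0.8
        ss_cx = cx - lateral * 0.04 * s
        prims.append(Primitive(SS, "ellipse", (ss_cx, cy, a_ss, b_ss)))
        # ICA: bright disc touching the sinus' lateral border
        r_ica = 0.048 * s + jit[4] * 0.4
        ica_cx = ss_cx + lateral * (a_ss + r_ica * 0.8)
        ica_cy = cy + 0.03 * s
        prims.append(Primitive(ICA, "disc", (ica_cx, ica_cy, r_ica)))
        # optic canal: thin ring superior-lateral to the sinus
        oc_cx = ss_cx + lateral * 0.135 * s
        oc_cy = cy - 0.27 * s + jit[5] * 1.0
        r_out = 0.078 * s
        r_in = r_out - max(2.2, 0.036 * s)
        fracture = rng.random() < prob
        frag = None
        if fracture:
            g0 = rng.uniform(0.0, 2 * math.pi)
            g1 = g0 + rng.uniform(math.pi / 3, math.pi / 2)  # >= 2 px arc
            prims.append(Primitive(
                OC, "ring", (oc_cx, oc_cy, r_in, r_out, g0 % (2 * math.pi),
                             g1 % (2 * math.pi))))
            # displaced fragment just outside the gap centre
            mid = (g0 + g1) / 2.0
            fx = oc_cx + (r_out + 0.05 * s) * math.cos(mid)
            fy = oc_cy + (r_out + 0.05 * s) * math.sin(mid)
            w, h = max(2, round(0.05 * s)), max(2, round(0.035 * s))
            x0 = int(np.clip(round(fx - w / 2), 0, s - w))
            y0 = int(np.clip(round(fy - h / 2), 0, s - h))
            frag = Primitive(OC, "rect", (x0, y0, x0 + w, y0 + h))
            prims.append(frag)
        else:
            prims.append(Primitive(
                OC, "ring", (oc_cx, oc_cy, r_in, r_out, 0.0, 0.0)))
        # box: extent of the canal (ring + fragment) with a 2 px margin
        xs = [oc_cx - r_out, oc_cx + r_out]
        ys = [oc_cy - r_out, oc_cy + r_out]
        if frag is not None:
            xs += [frag.params[0], frag.params[2]]
            ys += [frag.params[1], frag.params[3]]
        x0 = int(np.clip(math.floor(min(xs)) - 2, 0, s))
        y0 = int(np.clip(math.floor(min(ys)) - 2, 0, s))
        x1 = int(np.clip(math.ceil(max(xs)) + 2, 0, s))
        y1 = int(np.clip(math.ceil(max(ys)) + 2, 0, s))
        cat = ((CAT_FRACTURE_R, CAT_FRACTURE_L) if fracture else
               (CAT_NONFRACTURE_R, CAT_NONFRACTURE_L))[side]
        boxes.append(PixelBox(cat, x0, y0, x1, y1))
        fractured.append(fracture)
    return SlicePlan(tuple(prims), tuple(boxes), tuple(fractured))


def _rasterize(plan: SlicePlan, size: int) -> np.ndarray:
    """Paint primitives in order (later overwrite earlier) — vectorised."""
    mask = np.zeros((size, size), dtype=np.uint8)
    yy, xx = np.mgrid[0:size, 0:size]
    yc, xc = yy + 0.5, xx + 0.5
    for p in plan.primitives:
        if p.kind == "ellipse":
            cx, cy, a, b = p.params
            hit = ((xc - cx) / a) ** 2 + ((yc - cy) / b) ** 2 <= 1.0
        elif p.kind == "disc":
            cx, cy, r = p.params
            hit = (xc - cx) ** 2 + (yc - cy) ** 2 <= r * r
        elif p.kind == "ring":
            cx, cy, r_in, r_out, g0, g1 = p.params
            d2 = (xc - cx) ** 2 + (yc - cy) ** 2
            hit = (d2 >= r_in ** 2) & (d2 <= r_out ** 2)
            if g0 != g1:
                ang = np.arctan2(yc - cy, xc - cx) % (2 * math.pi)
                width = (g1 - g0) % (2 * math.pi)
                hit &= ~((ang - g0) % (2 * math.pi) < width)
        elif p.kind == "rect":
            x0, y0, x1, y1 = p.params
            hit = (xx >= x0) & (xx < x1) & (yy >= y0) & (yy < y1)
        else:  # pragma: no cover
            raise ValueError(p.kind)
        mask[hit] = p.class_id
    return mask


def _texture_field(rng: np.random.Generator, size: int,
                   scale: float) -> np.ndarray:
    """Unit-variance band-limited noise with correlation length ``scale``."""
    white = rng.normal(size=(size, size))
    if scale > 0:
        field_ = ndimage.gaussian_filter(white, scale, mode="wrap")
    else:
        field_ = white
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def render(plan: SlicePlan, config: PhantomConfig,
           seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise a plan into (image, mask)."""
    s = config.image_size
    mask = _rasterize(plan, s)
    rng = _rng([int(seed), 0x51ED270])
    image = np.empty((s, s), dtype=np.float64)
    for cls in (BACKGROUND, OC, ICA, SS):
        sel = mask == cls
        level = config.intensity_levels.get(cls, 0.5)
        tex = _texture_field(rng, s, config.texture_scales.get(cls, 2.0))
        image[sel] = level + config.texture_contrast * 0.5 * tex[sel]
    image += rng.normal(0.0, config.noise_sd, size=(s, s))
    return np.clip(image, 0.0, 1.0), mask


def generate_slice(config: PhantomConfig, seed: int | None = None,
                   keep_plan: bool = True) -> PhantomSlice:
    """Deterministically generate one phantom slice from (config, seed)."""
    seed = config.seed if seed is None else int(seed)
    plan = plan_slice(config, seed)
    image, mask = render(plan, config, seed)
    return PhantomSlice(image=image, mask=mask, boxes=plan.boxes,
                        seed_used=seed, plan=plan if keep_plan else None)


def generate_dataset(n: int, config: PhantomConfig, seed: int | None = None,
                     split_ratio: float = 0.8):
    """Generate ``n`` slices and split them train/test (default 8:2).

    Per-slice seeds are drawn from a seed sequence keyed by the master seed,
    so different masters give disjoint slice streams.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 < split_ratio < 1.0:
        raise ValueError("split_ratio must be in (0,1)")
    seed = config.seed if seed is None else int(seed)
    slice_seeds = np.random.SeedSequence(int(seed)).generate_state(
        max(n, 1), np.uint32)[:n]
    slices = [generate_slice(config, int(s)) for s in slice_seeds]
    n_train = int(round(n * split_ratio))
    return slices[:n_train], slices[n_train:]


# -- augmentation ----------------------------------------------------------

def _nearest_resize(mask: np.ndarray, shape) -> np.ndarray:
    ry = np.clip((np.arange(shape[0]) + 0.5) * mask.shape[0] / shape[0],
                 0, mask.shape[0] - 1).astype(int)
    rx = np.clip((np.arange(shape[1]) + 0.5) * mask.shape[1] / shape[1],
                 0, mask.shape[1] - 1).astype(int)
    return mask[np.ix_(ry, rx)]


def augment(image: np.ndarray, mask: np.ndarray, ops,
            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Apply a deterministic augmentation pipeline.

    ``ops`` is a list whose items are op names or ``(name, kwargs)`` pairs;
    names are drawn from :data:`AUGMENT_OPS`.  Geometric ops transform image
    and mask identically (mask via nearest neighbour); intensity ops touch
    the image only.  Unspecified op parameters are drawn from ``seed``.
    """
    rng = _rng([int(seed), 0xA5A5A5])
    img = np.asarray(image, dtype=np.float64).copy()
    msk = np.asarray(mask).copy()
    for op in ops:
        name, kw = (op, {}) if isinstance(op, str) else (op[0], dict(op[1]))
        if name not in AUGMENT_OPS:
            raise ValueError(f"unknown augmentation op {name!r}")
        if name == "flip":
            axis = kw.get("axis", int(rng.integers(0, 2)))
            img = np.flip(img, axis=axis).copy()
            msk = np.flip(msk, axis=axis).copy()
        elif name == "rotate":
            angle = kw.get("angle")
            if angle is None:
                angle = float(rng.uniform(-15.0, 15.0))
            if angle % 90 == 0:  # exact pixel permutation
                k = int(angle // 90) % 4
                img = np.rot90(img, k).copy()
                msk = np.rot90(msk, k).copy()
            else:
                img = ndimage.rotate(img, angle, reshape=False, order=1,
                                     mode="nearest")
                msk = ndimage.rotate(msk, angle, reshape=False, order=0,
                                     mode="nearest")
        elif name == "resize":
            size = kw.get("size")
            if size is None:
                size = max(8, round(img.shape[0] *
                                    float(rng.uniform(0.9, 1.1))))
            zoom = (size / img.shape[0], size / img.shape[1])
            img = ndimage.zoom(img, zoom, order=1)
            msk = _nearest_resize(msk, img.shape)
        elif name == "pad":
            w = int(kw.get("width", 4))
            img = np.pad(img, w)
            msk = np.pad(msk, w)
        elif name == "crop":
            size = int(kw.get("size", round(img.shape[0] * 7 / 8)))
            if size > min(img.shape):
                raise ValueError("crop size exceeds image")
            y0 = kw.get("y0", int(rng.integers(0, img.shape[0] - size + 1)))
            x0 = kw.get("x0", int(rng.integers(0, img.shape[1] - size + 1)))
            img = img[y0:y0 + size, x0:x0 + size].copy()
            msk = msk[y0:y0 + size, x0:x0 + size].copy()
        elif name == "normalize":
            lo, hi = img.min(), img.max()
            if hi > lo:
                img = (img - lo) / (hi - lo)
        elif name == "intensity_shift":
            shift = kw.get("shift", float(rng.uniform(-0.1, 0.1)))
            img = np.clip(img + shift, 0.0, 1.0)
        elif name == "noise":
            sd = float(kw.get("sd", 0.02))
            img = np.clip(img + rng.normal(0.0, sd, img.shape), 0.0, 1.0)
    return img, msk


def transform_box(box: PixelBox, op: str, size: int, **kw) -> PixelBox:
    """Transform a pixel box under an exact geometric op (flip / rot90)."""
    if op == "flip":
        axis = kw["axis"]
        if axis == 0:
            return replace(box, y0=size - box.y1, y1=size - box.y0)
        return replace(box, x0=size - box.x1, x1=size - box.x0)
    if op == "rotate":
        k = (int(kw.get("angle", 90)) // 90) % 4
        b = box
        for _ in range(k):  # one CCW quarter turn (matches np.rot90)
            b = PixelBox(b.category, x0=b.y0, y0=size - b.x1,
                         x1=b.y1, y1=size - b.x0)
        return b
    raise ValueError(f"box transform undefined for op {op!r}")
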