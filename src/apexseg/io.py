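"""File formats: YOLO box text, polygon annotations, PNG/NIfTI images,
paletted mask PNGs, and JSON/CSV metric reports.

Internally everything is 0-based, row-major, origin top-left; boxes live as
half-open pixel extents (:class:`apexseg.phantom.PixelBox`) and the dialects
appear only here.  The category-id table is defined once, in
:data:`apexseg.phantom.CATEGORY_NAMES` (0=Fracture(R), 1=Fracture(L),
2=Non-fracture(R), 3=Non-fracture(L)), and every reader/writer shares it.
"""

from __future__ import annotations

import csv
import hashlib
import io as _stdio
import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from . import __version__
from .det_metrics import BoxAnnotation, Detection
from .phantom import CATEGORY_NAMES, OC, ICA, SS, PixelBox
from .seg_metrics import SegReport

LABEL_OF_NAME = {"OC": OC, "ICA": ICA, "SS": SS}

# palette for mask PNGs: background black, OC red, ICA green, SS blue
MASK_PALETTE = [0, 0, 0, 255, 0, 0, 0, 255, 0, 0, 0, 255]


# -- box conversions -------------------------------------------------------

def pixel_box_to_annotation(box: PixelBox, image_size: int) -> BoxAnnotation:
    """Half-open pixel extent -> normalised centre form."""
    s = float(image_size)
    return BoxAnnotation(category=box.category,
                         cx=(box.x0 + box.x1) / (2 * s),
                         cy=(box.y0 + box.y1) / (2 * s),
                         w=(box.x1 - box.x0) / s,
                         h=(box.y1 - box.y0) / s)


def annotation_to_pixel_box(ann: BoxAnnotation, image_size: int) -> PixelBox:
    s = image_size
    x0, y0, x1, y1 = ann.corners
    return PixelBox(category=ann.category,
                    x0=int(round(x0 * s)), y0=int(round(y0 * s)),
                    x1=int(round(x1 * s)), y1=int(round(y1 * s)))


# -- YOLO text dialect -----------------------------------------------------

def write_yolo(annotations, path) -> None:
    """One ``category cx cy w h`` record per line, floats at 6 decimals.

    Detections additionally carry a sixth confidence field.
    """
    lines = []
    for a in annotations:
        fields = [str(int(a.category))] + [f"{v:.6f}"
                                           for v in (a.cx, a.cy, a.w, a.h)]
        if isinstance(a, Detection):
            fields.append(f"{a.confidence:.6f}")
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo(path, with_confidence: bool = False):
    """Parse a YOLO-dialect annotation file into box objects."""
    out = []
    want = 6 if with_confidence else 5
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.split()
        if len(parts) != want:
            raise ValueError(
                f"{path}:{ln}: expected {want} fields, got {len(parts)}")
        try:
            cat = int(parts[0])
            vals = [float(v) for v in parts[1:]]
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: unparsable field ({e})") from None
        if not 0 <= cat < len(CATEGORY_NAMES):
            raise ValueError(f"{path}:{ln}: category id {cat} out of range")
        if with_confidence:
            out.append(Detection(cat, *vals[:4], confidence=vals[4]))
        else:
            out.append(BoxAnnotation(cat, *vals))
    return out


# -- polygon annotations ---------------------------------------------------

def _points_in_polygon(xs: np.ndarray, ys: np.ndarray,
                       verts: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) test, half-open on edges."""
    inside = np.zeros(xs.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        crosses = (y1 <= ys) != (y2 <= ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (xs < xint)
    return inside


def polygons_to_mask(polys, shape) -> np.ndarray:
    """Rasterise labeled polygons to a label mask.

    ``polys``: iterable of (label, vertices) where label is a structure name
    ("OC", "ICA", "SS") or an integer class id and vertices is an (M,2)
    array of (x, y) pixel coordinates, M >= 3.  A pixel gets a label when
    its centre lies inside the polygon (even-odd rule); later polygons
    overwrite earlier ones.
    """
    mask = np.zeros(shape, dtype=np.uint8)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    xc, yc = xx + 0.5, yy + 0.5
    for label, verts in polys:
        cls = LABEL_OF_NAME[label] if isinstance(label, str) else int(label)
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
            raise ValueError("polygon needs at least 3 (x,y) vertices")
        mask[_points_in_polygon(xc, yc, verts)] = cls
    return mask


def read_labelme_json(path):
    """Read a LabelMe-style JSON file into (label, vertices) pairs."""
    doc = json.loads(Path(path).read_text())
    return [(s["label"], np.asarray(s["points"], dtype=float))
            for s in doc.get("shapes", [])]


def write_labelme_json(polys, shape, path) -> None:
    doc = {"imageHeight": int(shape[0]), "imageWidth": int(shape[1]),
           "shapes": [{"label": (label if isinstance(label, str) else
                                 {v: k for k, v in LABEL_OF_NAME.items()}[label]),
                       "points": np.asarray(verts, dtype=float).tolist(),
                       "shape_type": "polygon"} for label, verts in polys]}
    Path(path).write_text(json.dumps(doc, indent=1))


# -- images and masks ------------------------------------------------------

def write_image(image: np.ndarray, path) -> None:
    """Write a [0,1] float image as 8-bit PNG or single-slice NIfTI."""
    path = Path(path)
    if path.suffix == ".png":
        q = np.floor(np.clip(image, 0, 1) * 255.0 + 0.5).astype(np.uint8)
        Image.fromarray(q, mode="L").save(path)
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32),
                                 affine=np.eye(4)), str(path))
    else:
        raise ValueError(f"unsupported image extension: {path.name}")


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".png":
        arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
        return arr / 255.0
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    raise ValueError(f"unsupported image extension: {path.name}")


def write_mask(mask: np.ndarray, path) -> None:
    """Write an integer label mask as a paletted PNG (lossless)."""
    mask = np.asarray(mask)
    if mask.max(initial=0) > 255:
        raise ValueError("mask labels exceed 8-bit range")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    img.putpalette(MASK_PALETTE + [0] * (768 - len(MASK_PALETTE)))
    img.save(Path(path))


def read_mask(path) -> np.ndarray:
    img = Image.open(Path(path))
    if img.mode != "P":
        img = img.convert("L")
    return np.asarray(img, dtype=np.uint8)


# -- reports ---------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of any JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(report, path, seed: int | None = None,
                 config=None) -> None:
    """Serialise a SegReport / dict to JSON (or CSV for tabular dicts)."""
    path = Path(path)
    if isinstance(report, SegReport):
        payload = {"kind": "segmentation",
                   "per_class": {str(k): list(v)
                                 for k, v in report.per_class.items()},
                   "miou": report.miou, "mdice": report.mdice,
                   "include_background": report.include_background,
                   "k": report.k}
    elif isinstance(report, dict):
        payload = {"kind": "generic", **report}
    else:
        payload = {"kind": type(report).__name__, **asdict(report)}
    payload["toolkit_version"] = __version__
    if seed is not None:
        payload["seed"] = int(seed)
    if config is not None:
        payload["config_hash"] = config_hash(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif path.suffix == ".csv":
        buf = _stdio.StringIO()
        w = csv.writer(buf)
        flat = _flatten(payload)
        w.writerow(flat.keys())
        w.writerow(flat.values())
        path.write_text(buf.getvalue())
    else:
        raise ValueError(f"unsupported report extension: {path.suffix}")


def read_report(path):
    path = Path(path)
    if path.suffix != ".json":
        raise ValueError("only JSON reports can be read back")
    payload = json.loads(path.read_text())
    if payload.get("kind") == "segmentation":
        return SegReport(
            per_class={int(k): tuple(v)
                       for k, v in payload["per_class"].items()},
            miou=payload["miou"], mdice=payload["mdice"],
            include_background=payload["include_background"],
            k=payload["k"])
    return payload


def _flatten(d, prefix=""):
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


# -- dataset manifests -----------------------------------------------------

def write_dataset(train, test, directory, config=None) -> dict:
    """Write a phantom dataset (PNG images + mask PNGs + YOLO boxes) plus a
    JSON manifest listing paths, seeds and split membership."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"toolkit_version": __version__,
                "category_names": list(CATEGORY_NAMES), "items": []}
    if config is not None:
        manifest["config_hash"] = config_hash(
            config if isinstance(config, dict) else asdict(config))
    for split, slices in (("train", train), ("test", test)):
        for i, s in enumerate(slices):
            stem = f"{split}_{i:04d}"
            write_image(s.image, directory / f"{stem}.png")
            write_mask(s.mask, directory / f"{stem}_mask.png")
            size = s.image.shape[0]
            write_yolo([pixel_box_to_annotation(b, size) for b in s.boxes],
                       directory / f"{stem}.txt")
            manifest["items"].append({"stem": stem, "split": split,
                                      "seed": int(s.seed_used)})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
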