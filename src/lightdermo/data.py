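"""Manifest-driven dataset handling: preprocessing, ROI cropping, and the
class-balancing augmentation engine.

The unit of work is the :class:`DatasetManifest`, a list of image records
(id, class label, provenance, optional transform) serialized as CSV.
Balancing brings every class to exactly ``target_per_class`` images:
under-represented classes keep all originals and gain augmented copies
(round-robin over the originals, each with a freshly sampled random
transform), over-represented classes are subsampled without replacement.
Augmented records store their sampled transform parameters, so any augmented
image can be re-materialized bit-identically from its original.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "CLASSES",
    "AugmentationConfig",
    "BalancingError",
    "DatasetManifest",
    "ImageRecord",
    "TransformParams",
    "apply_transform",
    "balance_augment",
    "load_manifest",
    "preprocess",
    "resolve_image",
    "roi_crop_centroid",
    "sample_transform",
    "write_image_tree",
]

CLASSES = ("AK", "BCC", "BKL", "DF", "MEL", "NV", "VASC")


class BalancingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TransformParams:
    """One sampled augmentation: geometric warp, photometric jitter, noise."""

    rotation_deg: float = 0.0
    brightness: float = 1.0
    zoom: float = 1.0
    shear: float = 0.0
    hflip: bool = False
    vflip: bool = False
    noise_sigma: float = 0.0
    noise_seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "TransformParams":
        return cls(**json.loads(s))


@dataclass
class ImageRecord:
    id: str
    class_label: str
    path: str | None = None
    image: np.ndarray | None = None
    provenance: str = "original"  # original | augmented | downsampled-out
    origin_id: str | None = None
    transform: TransformParams | None = None

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise ValueError(
                f"class_label {self.class_label!r} not one of {CLASSES}"
            )


class DatasetManifest:
    """Ordered collection of image records with class accounting."""

    def __init__(self, records: list[ImageRecord]):
        self.records = list(records)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            if rec.provenance != "downsampled-out":
                counts[rec.class_label] = counts.get(rec.class_label, 0) + 1
        return counts

    def active_records(self) -> list[ImageRecord]:
        return [r for r in self.records if r.provenance != "downsampled-out"]

    def index(self) -> dict[str, ImageRecord]:
        return {r.id: r for r in self.records}

    def subset(self, ids) -> "DatasetManifest":
        wanted = set(ids)
        return DatasetManifest([r for r in self.records if r.id in wanted])

    def to_csv(self, path) -> None:
        rows = [
            {
                "id": r.id,
                "path": r.path or "",
                "label": r.class_label,
                "provenance": r.provenance,
                "origin_id": r.origin_id or "",
                "transform_json": r.transform.to_json() if r.transform else "",
            }
            for r in self.records
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def load_manifest(path) -> DatasetManifest:
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ImageRecord(
                id=str(row.id),
                class_label=row.label,
                path=row.path or None,
                provenance=row.provenance,
                origin_id=row.origin_id or None,
                transform=TransformParams.from_json(row.transform_json)
                if row.transform_json
                else None,
            )
        )
    return DatasetManifest(records)


@dataclass(frozen=True)
class AugmentationConfig:
    """Augmentation ranges (symmetric unless stated) on [0,1]-scaled pixels."""

    rotation_deg: float = 30.0
    brightness_range: tuple = (0.9, 1.1)
    zoom: float = 0.1
    shear: float = 0.1
    hflip: bool = True
    vflip: bool = True
    rescale: float = 1.0 / 255.0
    noise: float = 0.45  # upper bound of the per-image uniform draw of sigma
    seed: int = 0


# -- image operations ---------------------------------------------------------

def _to_unit_float(image) -> np.ndarray:
    """uint8 images are rescaled by 1/255; float images are assumed in [0,1]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) image, got shape {image.shape}")
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("zero-size image")
    if image.dtype == np.uint8:
        return image.astype(np.float32) / 255.0
    return image.astype(np.float32)


def preprocess(image, size: int = 256) -> np.ndarray:
    """Bilinear resize to ``size`` x ``size`` and rescale into [0, 1]."""
    image = _to_unit_float(image)
    h, w = image.shape[:2]
    if (h, w) != (size, size):
        image = ndimage.zoom(image, (size / h, size / w, 1.0), order=1)
        image = np.ascontiguousarray(image[:size, :size], dtype=np.float32)
    return np.clip(image, 0.0, 1.0)


def roi_crop_centroid(image) -> np.ndarray:
    """Square region-of-interest crop around the lesion's intensity centroid.

    Lesions are darker than the surrounding skin, so the centroid of
    (1 - grayscale) locates the lesion.  The crop is the largest square
    centred on the centroid that fits inside the image, never smaller than
    half the short side (the window is shifted inward if needed).  A uniform
    image has no centroid signal and falls back to the geometric centre.
    """
    image = _to_unit_float(image)
    h, w = image.shape[:2]
    gray = image.mean(axis=2)
    weight = 1.0 - gray
    total = weight.sum()
    if total <= 1e-6 or np.ptp(gray) < 1e-6:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    else:
        yy, xx = np.mgrid[0:h, 0:w]
        cy = float((weight * yy).sum() / total)
        cx = float((weight * xx).sum() / total)
    short = min(h, w)
    side = int(round(max(2 * min(cx, w - 1 - cx, cy, h - 1 - cy), short / 2)))
    side = max(1, min(side, short))
    top = int(round(cy - side / 2))
    left = int(round(cx - side / 2))
    top = max(0, min(top, h - side))
    left = max(0, min(left, w - side))
    return image[top : top + side, left : left + side]


def sample_transform(cfg: AugmentationConfig, rng) -> TransformParams:
    """Sample one augmentation: rotation U(-a, a), brightness U(lo, hi),
    zoom U(1-z, 1+z), shear U(-s, s), fair-coin flips, per-image Gaussian
    noise sigma ~ U(0, noise)."""
    return TransformParams(
        rotation_deg=float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)),
        brightness=float(rng.uniform(*cfg.brightness_range)),
        zoom=float(rng.uniform(1.0 - cfg.zoom, 1.0 + cfg.zoom)),
        shear=float(rng.uniform(-cfg.shear, cfg.shear)),
        hflip=bool(cfg.hflip and rng.random() < 0.5),
        vflip=bool(cfg.vflip and rng.random() < 0.5),
        noise_sigma=float(rng.uniform(0.0, cfg.noise)),
        noise_seed=int(rng.integers(0, 2**31 - 1)),
    )


def apply_transform(image, params: TransformParams) -> np.ndarray:
    """Deterministically apply a sampled transform to a [0, 1] RGB image.

    Geometry (zoom, shear, rotation about the centre, constant black fill),
    then flips, brightness, Gaussian noise from the stored seed, and a final
    clip to [0, 1].  Replays are bit-identical given identical parameters.
    """
    image = _to_unit_float(image)
    h, w = image.shape[:2]
    theta = np.deg2rad(params.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shear = np.array([[1.0, params.shear], [0.0, 1.0]])
    fwd = params.zoom * (shear @ rot)
    if abs(np.linalg.det(fwd)) < 1e-8:
        raise ValueError("degenerate geometric transform")
    inv = np.linalg.inv(fwd)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - inv @ center
    if not np.allclose(fwd, np.eye(2)):
        out = np.empty_like(image)
        for c in range(3):
            out[..., c] = ndimage.affine_transform(
                image[..., c], inv, offset=offset, order=1, mode="constant", cval=0.0
            )
        image = out
    if params.hflip:
        image = image[:, ::-1]
    if params.vflip:
        image = image[::-1, :]
    image = image * np.float32(params.brightness)
    if params.noise_sigma > 0:
        noise_rng = np.random.default_rng(params.noise_seed)
        image = image + noise_rng.normal(0.0, params.noise_sigma, image.shape).astype(
            np.float32
        )
    return np.clip(image, 0.0, 1.0).astype(np.float32)


# -- record materialization ---------------------------------------------------

def resolve_image(record: ImageRecord, index: dict[str, ImageRecord] | None = None) -> np.ndarray:
    """Materialize a record's pixels as a float32 [0, 1] array.

    Augmented records replay their stored transform on the original image.
    """
    if record.provenance == "augmented":
        if index is None or record.origin_id not in index:
            raise KeyError(f"origin record {record.origin_id!r} not available")
        base = resolve_image(index[record.origin_id], index)
        return apply_transform(base, record.transform)
    if record.image is not None:
        return _to_unit_float(record.image)
    if record.path:
        with Image.open(record.path) as im:
            return _to_unit_float(np.asarray(im.convert("RGB")))
    raise ValueError(f"record {record.id} has neither in-memory pixels nor a path")


def write_image_tree(manifest: DatasetManifest, out_dir) -> None:
    """Write active records as class-per-folder PNGs plus ``manifest.csv``."""
    out_dir = os.fspath(out_dir)
    index = manifest.index()
    for rec in manifest.active_records():
        folder = os.path.join(out_dir, rec.class_label)
        os.makedirs(folder, exist_ok=True)
        img = resolve_image(rec, index)
        path = os.path.join(folder, f"{rec.id}.png")
        Image.fromarray((img * 255).round().astype(np.uint8)).save(path)
        rec.path = path
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"))


# -- balancing ----------------------------------------------------------------

def balance_augment(
    manifest: DatasetManifest,
    target_per_class: int = 4000,
    cfg: AugmentationConfig | None = None,
) -> DatasetManifest:
    """Bring every class to exactly ``target_per_class`` active records.

    Deficit classes keep all originals and append augmented copies, cycling
    round-robin over the originals with a fresh sampled transform each; the
    surplus class is subsampled without replacement (dropped records are kept
    but marked ``downsampled-out``).  Seeded by ``cfg.seed``; idempotent on an
    already balanced manifest.
    """
    cfg = cfg or AugmentationConfig()
    counts = manifest.class_counts
    for label in CLASSES:
        if counts.get(label, 0) < 1:
            raise BalancingError(f"class {label} has no images; cannot balance")
    rng = np.random.default_rng(cfg.seed)
    out_records: list[ImageRecord] = [replace_record(r) for r in manifest.records]
    by_class: dict[str, list[ImageRecord]] = {c: [] for c in CLASSES}
    for rec in out_records:
        if rec.provenance != "downsampled-out":
            by_class[rec.class_label].append(rec)
    for label in CLASSES:
        recs = by_class[label]
        n = len(recs)
        if n > target_per_class:
            keep = set(rng.choice(n, size=target_per_class, replace=False).tolist())
            for i, rec in enumerate(recs):
                if i not in keep:
                    rec.provenance = "downsampled-out"
        elif n < target_per_class:
            originals = [r for r in recs if r.provenance == "original"] or recs
            for i in range(target_per_class - n):
                base = originals[i % len(originals)]
                out_records.append(
                    ImageRecord(
                        id=f"{base.id}_aug{i:05d}",
                        class_label=label,
                        provenance="augmented",
                        origin_id=base.id,
                        transform=sample_transform(cfg, rng),
                    )
                )
    return DatasetManifest(out_records)


def replace_record(rec: ImageRecord) -> ImageRecord:
    return ImageRecord(
        id=rec.id,
        class_label=rec.class_label,
        path=rec.path,
        image=rec.image,
        provenance=rec.provenance,
        origin_id=rec.origin_id,
        transform=rec.transform,
    )
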