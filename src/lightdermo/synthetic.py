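"""Synthetic dermoscopy-like image generator.

Produces labelled, visually separable images for the seven pigmented-skin-
lesion classes (AK, BCC, BKL, DF, MEL, NV, VASC): a skin-toned background
with mild illumination drift plus one lesion — a border-perturbed, rotated
ellipse with class-specific colour, eccentricity, border irregularity,
texture frequency and (for some classes) darker globule dots — together with
its binary mask.  The classes are deliberately discriminable by lesion
colour and shape so that classifier and saliency behaviour can be tested
end-to-end without any image downloads.  The generator is deterministic
given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import CLASSES, DatasetManifest, ImageRecord, write_image_tree

__all__ = [
    "CLASS_STYLES",
    "HAM10000_COUNTS",
    "SyntheticSpec",
    "generate_image",
    "make_fixture",
]

# class imbalance of the combined HAM10000/ISIC source archives
HAM10000_COUNTS = {
    "AK": 500,
    "BCC": 2000,
    "BKL": 2000,
    "DF": 200,
    "NV": 6000,
    "MEL": 3000,
    "VASC": 300,
}

# per-class generative style: lesion colour (RGB in [0,1]), ellipse
# eccentricity, border-irregularity amplitude, texture frequency (cycles per
# image), texture amplitude, globule dots.  Styles are pairwise distinct in
# at least two of {colour, shape, texture}.
CLASS_STYLES = {
    "AK": dict(color=(0.72, 0.45, 0.38), ecc=0.25, border=0.25, tex_freq=9.0, tex_amp=0.05, globules=False),
    "BCC": dict(color=(0.80, 0.62, 0.58), ecc=0.15, border=0.10, tex_freq=3.0, tex_amp=0.03, globules=True),
    "BKL": dict(color=(0.55, 0.40, 0.20), ecc=0.35, border=0.18, tex_freq=6.0, tex_amp=0.06, globules=False),
    "DF": dict(color=(0.48, 0.30, 0.26), ecc=0.10, border=0.05, tex_freq=2.0, tex_amp=0.02, globules=False),
    "MEL": dict(color=(0.20, 0.12, 0.10), ecc=0.45, border=0.40, tex_freq=5.0, tex_amp=0.08, globules=True),
    "NV": dict(color=(0.45, 0.29, 0.15), ecc=0.20, border=0.08, tex_freq=4.0, tex_amp=0.03, globules=False),
    "VASC": dict(color=(0.58, 0.22, 0.45), ecc=0.18, border=0.06, tex_freq=3.0, tex_amp=0.04, globules=False),
}

_SKIN_RGB = np.array([0.85, 0.68, 0.60], dtype=np.float32)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults suit fast desk-scale testing."""

    image_size: int = 64
    seed: int = 0
    area_range: tuple = (0.08, 0.30)  # lesion area as fraction of image
    center_range: tuple = (0.32, 0.68)  # lesion centre, fractional coords
    color_jitter: float = 0.02  # per-image lesion colour sd
    pixel_noise: float = 0.012  # per-pixel sensor noise sd
    styles: dict = field(default_factory=lambda: CLASS_STYLES)


def generate_image(class_label: str, spec: SyntheticSpec | None = None, rng=None):
    """One synthetic lesion image.  Returns ``(image, mask)`` with image a
    float32 (S, S, 3) array in [0, 1] and mask a boolean (S, S) array."""
    spec = spec or SyntheticSpec()
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}; expected one of {CLASSES}")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    style = spec.styles[class_label]
    s = spec.image_size

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    # skin background with smooth illumination drift
    drift = (
        0.04 * np.sin(2 * np.pi * (xx * rng.uniform(0.3, 1.0) / s + rng.uniform(0, 1)))
        + 0.04 * np.sin(2 * np.pi * (yy * rng.uniform(0.3, 1.0) / s + rng.uniform(0, 1)))
    )
    img = np.empty((s, s, 3), dtype=np.float32)
    skin = _SKIN_RGB + rng.normal(0, 0.015, 3).astype(np.float32)
    img[...] = skin + drift[..., None]

    # lesion geometry: rotated ellipse with harmonic border perturbation
    cx = rng.uniform(*spec.center_range) * s
    cy = rng.uniform(*spec.center_range) * s
    frac = rng.uniform(*spec.area_range)
    ecc = style["ecc"]
    # semi-axes a, b with b = a*(1-ecc); pi*a*b = frac*s^2
    a = np.sqrt(frac * s * s / (np.pi * (1 - ecc)))
    b = a * (1 - ecc)
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    r = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    ang = np.arctan2(yr / b, xr / a)
    wobble = np.zeros_like(ang)
    for k in (3, 5, 7):
        wobble += rng.uniform(-1, 1) * np.sin(k * ang + rng.uniform(0, 2 * np.pi))
    boundary = 1.0 + style["border"] * wobble / 3.0
    mask = r <= boundary

    color = np.asarray(style["color"], dtype=np.float32) + rng.normal(
        0, spec.color_jitter, 3
    ).astype(np.float32)
    texture = style["tex_amp"] * np.sin(
        2 * np.pi * style["tex_freq"] * (xr / s) + rng.uniform(0, 2 * np.pi)
    )
    lesion = color[None, None, :] + texture[..., None]
    # soft edge: blend over a thin annulus for a dermoscopy-like border
    edge = np.clip((boundary - r) / 0.05, 0.0, 1.0)[..., None]
    img = (img * (1 - edge) + lesion * edge).astype(np.float32)

    if style["globules"]:
        n_dots = rng.integers(3, 7)
        inside = np.argwhere(mask)
        if len(inside):
            for _ in range(n_dots):
                py, px = inside[rng.integers(len(inside))]
                rad = rng.uniform(0.03, 0.07) * s
                dot = (xx - px) ** 2 + (yy - py) ** 2 <= rad**2
                img[dot & mask] *= 0.6

    img += rng.normal(0, spec.pixel_noise, img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0, out=img), mask


def make_fixture(
    counts: dict[str, int] | None = None,
    spec: SyntheticSpec | None = None,
    seed: int | None = None,
    out_dir=None,
    keep_masks: bool = False,
    store_uint8: bool = False,
):
    """Generate a labelled dataset with the requested per-class counts.

    Returns a :class:`DatasetManifest` whose records hold in-memory images;
    with ``out_dir`` the images are also written as a class-per-folder PNG
    tree plus a manifest CSV.  Each image gets an independent deterministic
    RNG stream derived from ``seed``, so fixtures are reproducible and two
    different seeds give disjoint pixel content with identical counts.
    """
    counts = dict(counts or HAM10000_COUNTS)
    spec = spec or SyntheticSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    records = []
    masks = {} if keep_masks else None
    for ci, label in enumerate(CLASSES):
        for i in range(int(counts.get(label, 0))):
            rng = np.random.default_rng([spec.seed, ci, i])
            img, mask = generate_image(label, spec, rng)
            if store_uint8:  # quarter the memory footprint of big fixtures
                img = (img * 255).round().astype(np.uint8)
            rec_id = f"{label}_{i:05d}"
            records.append(
                ImageRecord(id=rec_id, class_label=label, image=img, provenance="original")
            )
            if keep_masks:
                masks[rec_id] = mask
    manifest = DatasetManifest(records)
    if out_dir is not None:
        write_image_tree(manifest, out_dir)
    if keep_masks:
        return manifest, masks
    return manifest
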