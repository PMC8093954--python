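"""Image augmentation and per-backend preprocessing.

Augmentation multiplies each source image into ``factor`` randomized
variants (rotation, shear, zoom, shift, flips, crop) with parameters drawn
reproducibly from the policy seed.  Derived records inherit label, patient
and magnification, so patient-disjoint splits remain disjoint after
augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from skimage import transform as sktransform

from .manifest import DatasetManifest, ManifestRecord

KNOWN_TRANSFORMS = ("resize", "shear", "rotate", "crop", "zoom", "shift", "flip")

# Parameter ranges: the transforms are named in the source method without
# ranges; these are conventional magnitudes for texture imagery.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "rotate": (-30.0, 30.0),       # degrees
    "shear": (-10.0, 10.0),        # degrees
    "zoom": (0.9, 1.1),            # scale factor
    "shift": (-0.1, 0.1),          # fraction of side length
    "crop": (0.9, 1.0),            # retained fraction of each side
}


@dataclass
class AugmentationPolicy:
    factor: int = 30
    transforms: tuple[str, ...] = ("rotate", "shear", "zoom", "shift", "flip", "crop")
    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_RANGES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        for t in self.transforms:
            if t not in KNOWN_TRANSFORMS:
                raise ValueError(f"unknown transform {t!r}")
            if t in ("rotate", "shear", "zoom", "shift", "crop"):
                lo, hi = self.ranges.get(t, (np.nan, np.nan))
                if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                    raise ValueError(f"transform {t!r} needs a finite parameter range")


def _draw_params(policy: AugmentationPolicy, rng: np.random.Generator) -> dict:
    """One variant's transform parameters, in a fixed draw order."""
    p: dict[str, float] = {}
    for t in ("rotate", "shear", "zoom", "shift", "crop"):
        if t in policy.transforms:
            lo, hi = policy.ranges[t]
            if t == "shift":
                p["shift_y"] = rng.uniform(lo, hi)
                p["shift_x"] = rng.uniform(lo, hi)
            else:
                p[t] = rng.uniform(lo, hi)
    if "flip" in policy.transforms:
        p["flip_h"] = bool(rng.random() < 0.5)
        p["flip_v"] = bool(rng.random() < 0.5)
    return p


def render_augmented(image: np.ndarray, params: Mapping[str, float]) -> np.ndarray:
    """Apply one variant's transforms to a pixel array (float output).

    Order: rotate -> shear -> zoom -> shift (one affine warp), flips, then
    centre crop + resize back to the original shape.  An empty parameter
    dict is the identity.
    """
    if not params:
        return np.asarray(image).copy()
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]
    angle = np.deg2rad(params.get("rotate", 0.0))
    shear = np.deg2rad(params.get("shear", 0.0))
    zoom = params.get("zoom", 1.0)
    ty = params.get("shift_y", 0.0) * h
    tx = params.get("shift_x", 0.0) * w
    if angle or shear or zoom != 1.0 or tx or ty:
        centre = np.array([w / 2, h / 2])
        tf = (
            sktransform.AffineTransform(translation=-centre)
            + sktransform.AffineTransform(rotation=angle, shear=shear, scale=1.0 / zoom)
            + sktransform.AffineTransform(translation=centre + np.array([tx, ty]))
        )
        img = sktransform.warp(img, tf.inverse, mode="reflect", preserve_range=True)
    if params.get("flip_h"):
        img = img[:, ::-1]
    if params.get("flip_v"):
        img = img[::-1, :]
    crop = params.get("crop", 1.0)
    if crop < 1.0:
        ch, cw = max(1, round(h * crop)), max(1, round(w * crop))
        y0, x0 = (h - ch) // 2, (w - cw) // 2
        img = img[y0 : y0 + ch, x0 : x0 + cw]
        img = sktransform.resize(img, (h, w) + img.shape[2:], order=1,
                                 preserve_range=True, anti_aliasing=False)
    return np.ascontiguousarray(img)


def augment_dataset(
    manifest: DatasetManifest,
    images: Mapping[str, np.ndarray] | Callable[[ManifestRecord], np.ndarray] | None,
    policy: AugmentationPolicy,
) -> tuple[DatasetManifest, Callable[[ManifestRecord], np.ndarray]]:
    """Expand a manifest by ``policy.factor`` variants per source image.

    Returns the augmented manifest plus a lazy loader: variants are rendered
    only when requested, so count-level properties cost no pixel work.
    ``images`` maps source path -> array (or is a loader); it may be None if
    the returned loader is never called.
    """
    params_by_path: dict[str, dict] = {}
    records: list[ManifestRecord] = []
    for idx, rec in enumerate(manifest.records):
        rng = np.random.default_rng(np.random.SeedSequence([policy.seed, idx]))
        for k in range(policy.factor):
            params = _draw_params(policy, rng)
            stem, dot, ext = rec.image_path.rpartition(".")
            base = stem if dot else rec.image_path
            suffix = f".{ext}" if dot else ""
            new_path = f"{base}__aug{k}{suffix}"
            params_by_path[new_path] = {"source": rec.image_path, "params": params}
            records.append(
                ManifestRecord(new_path, rec.label, rec.patient_id, rec.magnification)
            )
    augmented = DatasetManifest(records)

    def loader(rec: ManifestRecord) -> np.ndarray:
        info = params_by_path[rec.image_path]
        if images is None:
            raise ValueError("no image source supplied to augment_dataset")
        if callable(images):
            src = images(info["source"])  # type: ignore[call-arg]
        else:
            src = images[info["source"]]
        return render_augmented(src, info["params"])

    loader.params_by_path = params_by_path  # type: ignore[attr-defined]
    return augmented, loader


LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) image to a single luminance channel."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3:
        w = np.asarray(LUMINANCE_WEIGHTS)
        return img[..., :3] @ w
    raise ValueError(f"expected 2-D or 3-D image, got shape {img.shape}")


def preprocess_for_backend(
    image: np.ndarray, target_size: tuple[int, int], order: int = 1
) -> np.ndarray:
    """Resize to a backend's input size (bilinear by default).

    An image already at the target size is returned unchanged.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    th, tw = target_size
    if th <= 0 or tw <= 0:
        raise ValueError("target size must be positive")
    if img.shape[:2] == (th, tw):
        return img
    out_shape = (th, tw) + img.shape[2:]
    return sktransform.resize(img, out_shape, order=order, preserve_range=True,
                              anti_aliasing=False)
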