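"""Synthetic data with controlled class separability.

Two generators make the whole cascade testable at desk scale:

* textured images — oriented band-pass filtered Gaussian noise whose
  dominant spatial frequency and orientation dispersion differ by class,
  scaled by an effect size; both gradient-histogram and wavelet features
  pick the differences up.  A per-patient intensity offset makes
  patient-disjoint splitting consequential.
* feature blocks — class-conditional Gaussians with unit within-class
  variance and a configurable mean separation on a chosen number of
  informative coordinates; separation 0 is exactly chance, separation d
  gives a closed-form two-class Bayes accuracy of Phi(d/2) on one
  coordinate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .blocks import FeatureBlock
from .manifest import DatasetManifest, ManifestRecord


@dataclass
class TextureSpec:
    n_images_per_class: int = 20
    classes: tuple[str, ...] = ("benign", "malignant")
    image_size: tuple[int, int] = (64, 64)
    #  per-class (frequency in cycles/pixel, orientation dispersion in rad)
    #  offsets from the base; scaled by effect_size
    base_frequency: float = 0.15
    base_dispersion: float = 0.5
    frequency_step: float = 0.03
    dispersion_step: float = 0.15
    effect_size: float = 1.0
    patients_per_class: int = 4
    patient_offset_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) == 0:
            raise ValueError("at least one class required")
        if self.n_images_per_class < 1:
            raise ValueError("n_images_per_class must be >= 1")
        if self.patients_per_class < 1:
            raise ValueError("patients_per_class must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def _oriented_texture(
    rng: np.random.Generator,
    size: tuple[int, int],
    frequency: float,
    orientation: float,
    dispersion: float,
) -> np.ndarray:
    """Band-pass filtered white noise with an oriented annular passband."""
    h, w = size
    noise = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    r = np.hypot(fy, fx)
    theta = np.arctan2(fy, fx)
    radial = np.exp(-((r - frequency) ** 2) / (2 * 0.03**2))
    # orientation response is pi-periodic for real textures
    dtheta = np.angle(np.exp(2j * (theta - orientation))) / 2.0
    angular = np.exp(-(dtheta**2) / (2 * max(dispersion, 1e-3) ** 2))
    spectrum = np.fft.fft2(noise) * radial * angular
    img = np.real(np.fft.ifft2(spectrum))
    sd = img.std()
    if sd > 0:
        img = img / sd
    return img


def generate_texture_dataset(
    spec: TextureSpec,
) -> tuple[dict[str, np.ndarray], DatasetManifest]:
    """Return ``{path: image}`` plus the matching manifest.

    Images are float arrays in [0, 1]; classes are exactly balanced and
    patient ids are assigned round-robin within each class.  Bit-identical
    for identical (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    images: dict[str, np.ndarray] = {}
    records: list[ManifestRecord] = []
    for ci, cls in enumerate(spec.classes):
        freq = spec.base_frequency + spec.effect_size * spec.frequency_step * ci
        disp = spec.base_dispersion + spec.effect_size * spec.dispersion_step * ci
        patient_offsets = rng.normal(0.0, spec.patient_offset_sd, spec.patients_per_class)
        for k in range(spec.n_images_per_class):
            patient_idx = k % spec.patients_per_class
            patient = f"{cls}_p{patient_idx:02d}"
            orientation = rng.uniform(0, np.pi)
            img = _oriented_texture(rng, spec.image_size, freq, orientation, disp)
            img = 0.5 + 0.15 * img + patient_offsets[patient_idx]
            img = np.clip(img, 0.0, 1.0)
            path = f"{cls}/img{k:04d}.png"
            images[path] = img
            records.append(ManifestRecord(path, cls, patient, "none"))
    return images, DatasetManifest(records)


@dataclass
class BlockSpec:
    name: str
    dim: int
    class_mean_separation: float = 0.0
    n_informative: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not 0 <= self.n_informative <= self.dim:
            raise ValueError("n_informative must lie in [0, dim]")
        if self.class_mean_separation < 0:
            raise ValueError("class_mean_separation must be >= 0")


def generate_feature_blocks(
    specs: list[BlockSpec],
    n_samples: int,
    n_classes: int = 2,
    seed: int = 0,
) -> tuple[list[FeatureBlock], np.ndarray]:
    """Draw mutually independent Gaussian blocks over shared labels.

    Within-class variance is 1 on every coordinate.  The first
    ``n_informative`` coordinates of each block have class means placed at
    ``class_index * separation`` so adjacent classes are ``separation``
    within-class standard deviations apart; the rest are pure noise.
    """
    if n_samples < 2 * n_classes:
        raise ValueError("need at least 2 samples per class")
    base = np.random.default_rng(seed)
    labels = np.arange(n_samples) % n_classes  # exact balance up to remainder
    labels = np.asarray(sorted(labels))
    blocks: list[FeatureBlock] = []
    for spec in specs:
        name_hash = zlib.crc32(spec.name.encode())  # stable across interpreter runs
        rng = np.random.default_rng(np.random.SeedSequence([seed, spec.seed, name_hash]))
        X = rng.standard_normal((n_samples, spec.dim))
        if spec.n_informative > 0 and spec.class_mean_separation > 0:
            means = labels[:, None] * spec.class_mean_separation
            X[:, : spec.n_informative] += means
        blocks.append(
            FeatureBlock(name=spec.name, matrix=X, provenance=f"synthetic:sep={spec.class_mean_separation}")
        )
    # shared shuffle so rows are not sorted by class
    perm = base.permutation(n_samples)
    labels = labels[perm]
    blocks = [
        FeatureBlock(name=b.name, matrix=b.matrix[perm], provenance=b.provenance)
        for b in blocks
    ]
    return blocks, labels


def synthetic_patient_ids(labels: np.ndarray, patients_per_class: int = 4) -> list[str]:
    """Assign round-robin patient ids within each class (for split tests)."""
    counters: dict[int, int] = {}
    out = []
    for y in labels:
        k = counters.get(int(y), 0)
        counters[int(y)] = k + 1
        out.append(f"c{int(y)}_p{k % patients_per_class:02d}")
    return out
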