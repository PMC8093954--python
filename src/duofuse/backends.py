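"""Pluggable deep-feature backends.

A backend is anything that maps a preprocessed image to a fixed-length
vector, deterministically for fixed parameters.  Pretrained CNN backbones
(AlexNet, GoogleNet, ResNet-50, ShuffleNet, Inception-ResNet V2) plug in
through this contract via :func:`register_backend`; the repository itself
ships a weight-free filter-bank backend — seeded random convolution filters,
a ReLU, and grid average pooling — which is deterministic, discriminative on
textured inputs, and needs no downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import fftconvolve

from .augment import preprocess_for_backend, to_luminance


@dataclass
class DeepBackend:
    name: str
    input_size: tuple[int, int]
    declared_dim: int
    extract_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def extract(self, image: np.ndarray) -> np.ndarray:
        vec = np.asarray(self.extract_fn(image), dtype=float).ravel()
        if vec.shape[0] != self.declared_dim:
            raise RuntimeError(
                f"backend {self.name}: output length {vec.shape[0]} != declared {self.declared_dim}"
            )
        return vec


_REGISTRY: dict[str, Callable[[], DeepBackend]] = {}


def register_backend(name: str, factory: Callable[[], DeepBackend]) -> None:
    _REGISTRY[name] = factory


def get_backend(name: str) -> DeepBackend:
    if name not in _REGISTRY:
        raise KeyError(f"backend unavailable: {name!r} (no weights registered)")
    return _REGISTRY[name]()


def deep_extract(image: np.ndarray, backend: DeepBackend) -> np.ndarray:
    img = preprocess_for_backend(np.asarray(image, dtype=float), backend.input_size)
    return backend.extract(img)


def make_filterbank_backend(
    n_filters: int = 8,
    input_size: tuple[int, int] = (64, 64),
    pooling_grid: tuple[int, int] = (4, 4),
    seed: int = 0,
    kernel_size: int = 7,
    name: str = "filterbank",
) -> DeepBackend:
    """Seeded random-filter convolution + ReLU + grid average pooling.

    declared_dim = n_filters * grid_h * grid_w.  Fully deterministic given
    the seed; two backends built with the same arguments agree bit-exactly.
    """
    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    gh, gw = pooling_grid
    if gh < 1 or gw < 1:
        raise ValueError("pooling grid must be positive")
    rng = np.random.default_rng(seed)
    filters = rng.standard_normal((n_filters, kernel_size, kernel_size))
    filters -= filters.mean(axis=(1, 2), keepdims=True)  # zero-DC, edge-sensitive

    def _extract(image: np.ndarray) -> np.ndarray:
        img = to_luminance(image)
        img = preprocess_for_backend(img, input_size)
        h, w = img.shape
        ys = np.linspace(0, h, gh + 1).astype(int)
        xs = np.linspace(0, w, gw + 1).astype(int)
        feats = np.empty(n_filters * gh * gw)
        k = 0
        for f in filters:
            resp = np.maximum(fftconvolve(img, f, mode="same"), 0.0)
            for i in range(gh):
                for j in range(gw):
                    feats[k] = resp[ys[i] : ys[i + 1], xs[j] : xs[j + 1]].mean()
                    k += 1
        return feats

    return DeepBackend(
        name=name,
        input_size=input_size,
        declared_dim=n_filters * gh * gw,
        extract_fn=_extract,
    )
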