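"""Handcrafted feature extraction: HOG and wavelet-packet descriptors.

Both extractors operate on the luminance channel of the (resized) image.

HOG proceeds in five stages — global gamma normalization, first-order x/y
gradients, per-cell orientation histograms weighted by gradient magnitude,
per-block contrast normalization over overlapping 2x2-cell blocks, and
flattening.  With the defaults (64x64 input, 8-px cells, 2x2-cell blocks at
one-cell stride, 11 unsigned bins) the descriptor length is
7 x 7 x 4 x 11 = 2,156.

WPD expands the full wavelet-packet tree: every subband — approximation and
detail alike — is re-filtered by the low-pass/high-pass pair and
downsampled by two at each level.  All terminal coefficients of the chosen
level (default 4, i.e. 4^4 = 256 2-D subbands) are flattened in natural
order.  With an orthogonal wavelet and periodization the transform is an
isometry: coefficient count and total energy both equal the input's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from skimage.feature import hog as _skimage_hog

from .augment import preprocess_for_backend, to_luminance


@dataclass
class HOGConfig:
    resize_to: tuple[int, int] = (64, 64)
    cell_size: int = 8
    block_size: int = 2
    block_stride: int = 1
    n_orientation_bins: int = 11
    signed_gradients: bool = False
    block_norm: str = "L2"
    norm_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        h, w = self.resize_to
        if h % self.cell_size or w % self.cell_size:
            raise ValueError("cell_size must divide resize_to exactly")
        cells_y, cells_x = h // self.cell_size, w // self.cell_size
        if self.block_size > min(cells_y, cells_x):
            raise ValueError("block_size exceeds the cell grid")
        if self.block_stride != 1:
            raise ValueError("only a one-cell block stride is supported")
        if self.signed_gradients:
            raise ValueError("signed (0-360) gradient bins are not supported")
        if self.block_norm not in ("L2", "L2-Hys"):
            raise ValueError("block_norm must be 'L2' or 'L2-Hys'")

    @property
    def descriptor_length(self) -> int:
        h, w = self.resize_to
        cells_y, cells_x = h // self.cell_size, w // self.cell_size
        blocks_y = cells_y - self.block_size + 1
        blocks_x = cells_x - self.block_size + 1
        return blocks_y * blocks_x * self.block_size**2 * self.n_orientation_bins


def extract_hog(image: np.ndarray, cfg: HOGConfig | None = None) -> np.ndarray:
    cfg = cfg or HOGConfig()
    img = to_luminance(image)
    if img.size == 0:
        raise ValueError("empty image")
    img = preprocess_for_backend(img, cfg.resize_to)
    if min(img.shape) < cfg.cell_size:
        raise ValueError("image smaller than one cell")
    vec = _skimage_hog(
        img,
        orientations=cfg.n_orientation_bins,
        pixels_per_cell=(cfg.cell_size, cfg.cell_size),
        cells_per_block=(cfg.block_size, cfg.block_size),
        block_norm="L2" if cfg.block_norm == "L2" else "L2-Hys",
        transform_sqrt=True,
        feature_vector=True,
    )
    return np.asarray(vec, dtype=float)


@dataclass
class WPDConfig:
    wavelet: str = "haar"
    levels: int = 4
    boundary_mode: str = "periodization"
    basis_criterion: str = "full_tree"
    resize_to: tuple[int, int] | None = (64, 64)

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.basis_criterion != "full_tree":
            raise ValueError("only the fully expanded tree is supported")
        if self.boundary_mode not in ("periodization", "symmetric", "zero"):
            raise ValueError(f"unknown boundary mode {self.boundary_mode!r}")
        if self.resize_to is not None and 2**self.levels > min(self.resize_to):
            raise ValueError("2^levels exceeds the resized image side")


def extract_wpd(signal: np.ndarray, cfg: WPDConfig | None = None) -> np.ndarray:
    """Terminal wavelet-packet coefficients, flattened in natural order.

    Accepts a 1-D signal or a 2-D image; images are resized to
    ``cfg.resize_to`` (luminance) first.
    """
    cfg = cfg or WPDConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim == 1:
        if 2**cfg.levels > x.shape[0]:
            raise ValueError("2^levels exceeds the signal length")
        wp = pywt.WaveletPacket(x, cfg.wavelet, mode=cfg.boundary_mode,
                                maxlevel=cfg.levels)
        nodes = wp.get_level(cfg.levels, order="natural")
        return np.concatenate([np.ravel(n.data) for n in nodes])
    img = to_luminance(x)
    if cfg.resize_to is not None:
        img = preprocess_for_backend(img, cfg.resize_to)
    if 2**cfg.levels > min(img.shape):
        raise ValueError("2^levels exceeds the image side")
    wp2 = pywt.WaveletPacket2D(img, cfg.wavelet, mode=cfg.boundary_mode,
                               maxlevel=cfg.levels)
    nodes = wp2.get_level(cfg.levels, order="natural")
    return np.concatenate([np.ravel(n.data) for n in nodes])
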