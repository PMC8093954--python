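"""Feature blocks: the named n x d matrices the fusion stages compose.

A block is the output of one extractor over the whole manifest, rows in
manifest order.  Blocks are stored in HDF5 (one group per block + shared
labels) with a CSV export for interoperability.

The canonical block widths follow the published system: the two handcrafted
widths (HOG 2,156; WPD 1,067) and the five deep widths (Inception-ResNet V2
7,852; ResNet-50 5,000; ShuffleNet 6,034; AlexNet 3,520; GoogleNet 4,600).
None of the deep widths matches the native pooling outputs of the standard
architectures, so a dimension adapter (seeded random projection by default)
maps extractor-native vectors onto the canonical widths; the adapter is an
explicit stand-in, not a claim about how the original widths arose.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import h5py
import numpy as np
import pandas as pd

#: canonical block name -> published feature-space width
CANONICAL_DIMS: dict[str, int] = {
    "inception_resnet_v2": 7852,
    "resnet50": 5000,
    "shufflenet": 6034,
    "alexnet": 3520,
    "googlenet": 4600,
    "hog": 2156,
    "wpd": 1067,
}

#: canonical backend name -> expected input size (height, width)
BACKEND_INPUT_SIZES: dict[str, tuple[int, int]] = {
    "googlenet": (224, 224),
    "alexnet": (227, 227),
    "resnet50": (224, 224),
    "shufflenet": (224, 224),
    "inception_resnet_v2": (229, 229),
}


@dataclass
class FeatureBlock:
    name: str
    matrix: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("block matrix must be 2-D (n_samples x dim)")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DimensionAdapter:
    """Reconcile an extractor's native width with a declared block width.

    Modes: ``identity`` (dims must already agree), ``truncate`` (keep the
    leading coordinates), ``zero_pad`` (append zeros), and
    ``fixed_seed_projection`` (multiply by a seed-fixed random matrix with
    orthonormal rows when reducing, orthonormal columns when expanding —
    distances are preserved up to the usual random-projection distortion).
    """

    mode: str = "identity"
    target_dim: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("identity", "truncate", "zero_pad", "fixed_seed_projection"):
            raise ValueError(f"unknown adapter mode {self.mode!r}")
        if self.mode != "identity" and self.target_dim < 1:
            raise ValueError("target_dim must be positive")

    def matrix_for(self, source_dim: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        if self.target_dim <= source_dim:
            g = rng.standard_normal((source_dim, self.target_dim))
            q, _ = np.linalg.qr(g)  # source x target, orthonormal columns
            return q.T  # target x source, orthonormal rows
        g = rng.standard_normal((self.target_dim, source_dim))
        q, _ = np.linalg.qr(g)  # target x source, orthonormal columns
        return q


def adapt_dimension(vector: np.ndarray, adapter: DimensionAdapter) -> np.ndarray:
    v = np.asarray(vector, dtype=float).ravel()
    d = v.shape[0]
    if adapter.mode == "identity":
        if adapter.target_dim and adapter.target_dim != d:
            raise ValueError(f"identity adapter: source dim {d} != target {adapter.target_dim}")
        return v
    t = adapter.target_dim
    if adapter.mode == "truncate":
        if t > d:
            raise ValueError(f"cannot truncate length-{d} vector to {t}")
        return v[:t].copy()
    if adapter.mode == "zero_pad":
        if t < d:
            raise ValueError(f"cannot zero-pad length-{d} vector down to {t}")
        out = np.zeros(t)
        out[:d] = v
        return out
    return adapter.matrix_for(d) @ v


def build_feature_block(
    images,
    manifest,
    extractor: Callable[[np.ndarray], np.ndarray],
    name: str,
    adapter: DimensionAdapter | None = None,
    provenance: str = "",
) -> FeatureBlock:
    """Run an extractor over every manifest record, one row per record.

    ``images`` maps record path -> pixel array, or is a loader callable
    taking the record.  Any per-image failure aborts with the failing
    record named.
    """
    adapter = adapter or DimensionAdapter()
    rows: list[np.ndarray] = []
    proj: np.ndarray | None = None
    for rec in manifest:
        img = images(rec) if callable(images) else images[rec.image_path]
        try:
            vec = np.asarray(extractor(img), dtype=float).ravel()
        except Exception as exc:  # noqa: BLE001 - reported with context
            raise RuntimeError(f"extraction failed for {rec.image_path}: {exc}") from exc
        if adapter.mode == "fixed_seed_projection":
            if proj is None:
                proj = adapter.matrix_for(vec.shape[0])
            vec = proj @ vec
        else:
            vec = adapt_dimension(vec, adapter)
        rows.append(vec)
    if rows:
        matrix = np.vstack(rows)
    else:
        dim = adapter.target_dim if adapter.mode != "identity" else 0
        matrix = np.empty((0, dim))
    return FeatureBlock(name=name, matrix=matrix, provenance=provenance)


# ---------------------------------------------------------------------------
# persistence

def save_blocks(
    path: str | Path,
    blocks: list[FeatureBlock],
    labels: np.ndarray | list[str],
    patient_ids: list[str] | None = None,
) -> None:
    labels = np.asarray(labels)
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=labels.astype("S"))
        if patient_ids is not None:
            f.create_dataset("patients", data=np.asarray(patient_ids, dtype="S"))
        g = f.create_group("blocks")
        for b in blocks:
            if b.n_samples != len(labels):
                raise ValueError(f"block {b.name}: {b.n_samples} rows vs {len(labels)} labels")
            dg = g.create_dataset(b.name, data=b.matrix)
            dg.attrs["name"] = b.name
            dg.attrs["dim"] = b.dim
            dg.attrs["provenance"] = b.provenance


def load_blocks(path: str | Path) -> tuple[list[FeatureBlock], np.ndarray, list[str] | None]:
    with h5py.File(path, "r") as f:
        labels = np.array([s.decode() for s in f["labels"][:]])
        patients = None
        if "patients" in f:
            patients = [s.decode() for s in f["patients"][:]]
        blocks = [
            FeatureBlock(
                name=name,
                matrix=f["blocks"][name][:],
                provenance=f["blocks"][name].attrs.get("provenance", ""),
            )
            for name in sorted(f["blocks"])
        ]
    return blocks, labels, patients


def export_block_csv(block: FeatureBlock, path: str | Path) -> None:
    pd.DataFrame(block.matrix).to_csv(path, index=False)
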