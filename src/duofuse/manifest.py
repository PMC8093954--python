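"""Dataset manifests and patient-disjoint train/test splitting.

A manifest is the flat table that drives everything downstream: one record
per image, carrying the class label, an opaque patient identifier and the
microscope magnification.  Splits are always made at the patient level so
that no patient contributes images to both sides — image-level splits leak
patient identity and inflate test accuracy on histology data.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MAGNIFICATIONS = ("40x", "100x", "200x", "400x", "none")
IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")

# BreakHis-style filename: <procedure>_<class>-<subtype>-<year>-<slide>-<mag>-<seq>
# e.g. SOB_B_TA-14-4659-40-001.png  (class letter B/M after the procedure code)
_BREAKHIS_RE = re.compile(
    r"^(?P<proc>[A-Z]+)_(?P<cls>[BM])_?(?P<subtype>[A-Za-z]+)?-(?P<year>\d+)-"
    r"(?P<slide>[\dA-Za-z]+)-(?P<mag>\d+)-(?P<seq>\d+)$"
)


@dataclass(frozen=True)
class ManifestRecord:
    """One image: where it lives and what it is."""

    image_path: str
    label: str
    patient_id: str
    magnification: str = "none"

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("label must be non-empty")
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.magnification not in MAGNIFICATIONS:
            raise ValueError(
                f"magnification {self.magnification!r} not one of {MAGNIFICATIONS}"
            )


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        paths = [r.image_path for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("duplicate image_path in manifest")

    @property
    def class_set(self) -> set[str]:
        return {r.label for r in self.records}

    @property
    def patient_ids(self) -> list[str]:
        """Distinct patient ids in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "path": r.image_path,
                    "label": r.label,
                    "patient_id": r.patient_id,
                    "magnification": r.magnification,
                }
                for r in self.records
            ]
        )

    def save_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _parse_breakhis_name(stem: str) -> tuple[str, str, str] | None:
    """Return (label, patient_id, magnification) or None if unparseable."""
    m = _BREAKHIS_RE.match(stem)
    if m is None:
        return None
    label = "benign" if m.group("cls") == "B" else "malignant"
    patient = f"{m.group('year')}-{m.group('slide')}"
    mag = f"{m.group('mag')}x"
    if mag not in MAGNIFICATIONS:
        mag = "none"
    return label, patient, mag


def load_manifest(root: str | Path, layout: str = "folder_per_class") -> DatasetManifest:
    """Discover images under ``root`` and build a manifest.

    Layouts
    -------
    folder_per_class
        Label = immediate parent directory name.  Patient id comes from a
        sidecar ``patients.csv`` (columns path,patient_id) if present,
        otherwise defaults to the filename stem.
    breakhis_filenames
        Label / patient / magnification parsed from the BreakHis filename
        convention; files that do not parse fall back to folder_per_class
        semantics and are reported.
    csv_manifest
        ``root`` is (or contains) a manifest.csv with columns
        path,label,patient_id,magnification; row order preserved.
    """
    root = Path(root)
    if layout == "csv_manifest":
        csv_path = root if root.is_file() else root / "manifest.csv"
        if not csv_path.exists():
            raise FileNotFoundError(f"no manifest CSV at {csv_path}")
        df = pd.read_csv(csv_path, dtype=str)
        base = csv_path.parent
        records = [
            ManifestRecord(
                image_path=str(row["path"]),
                label=row["label"],
                patient_id=row["patient_id"],
                magnification=row.get("magnification", "none") or "none",
            )
            for _, row in df.iterrows()
        ]
        if not records:
            raise ValueError("no images found")
        for r in records:
            p = Path(r.image_path)
            if not (p.is_absolute() and p.exists()) and not (base / p).exists():
                raise FileNotFoundError(f"manifest references missing image {r.image_path}")
        return DatasetManifest(records)

    if layout not in ("folder_per_class", "breakhis_filenames"):
        raise ValueError(f"unsupported layout {layout!r}")
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")

    sidecar: dict[str, str] = {}
    sidecar_path = root / "patients.csv"
    if sidecar_path.exists():
        df = pd.read_csv(sidecar_path, dtype=str)
        sidecar = dict(zip(df["path"], df["patient_id"]))

    files = sorted(
        p for p in root.rglob("*") if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not files:
        raise ValueError("no images found")

    records: list[ManifestRecord] = []
    errors: list[str] = []
    for p in files:
        rel = p.relative_to(root).as_posix()
        if layout == "breakhis_filenames":
            parsed = _parse_breakhis_name(p.stem)
            if parsed is not None:
                label, patient, mag = parsed
                records.append(ManifestRecord(rel, label, patient, mag))
                continue
            errors.append(rel)
        # folder_per_class semantics (also the fallback)
        label = p.parent.name if p.parent != root else "unlabeled"
        patient = sidecar.get(rel, p.stem)
        records.append(ManifestRecord(rel, label, patient, "none"))
    if layout == "breakhis_filenames" and errors and len(errors) == len(files):
        raise ValueError(
            f"no filename matched the BreakHis convention ({len(errors)} failures, "
            f"first: {errors[0]})"
        )
    return DatasetManifest(records)


@dataclass
class SplitConfig:
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class Split:
    train_indices: list[int]
    test_indices: list[int]
    train_patients: set[str]
    test_patients: set[str]

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_indices": self.train_indices,
                    "test_indices": self.test_indices,
                    "train_patients": sorted(self.train_patients),
                    "test_patients": sorted(self.test_patients),
                }
            )
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "Split":
        d = json.loads(Path(path).read_text())
        return cls(
            d["train_indices"],
            d["test_indices"],
            set(d["train_patients"]),
            set(d["test_patients"]),
        )


def patient_disjoint_split(manifest: DatasetManifest, cfg: SplitConfig) -> Split:
    """Partition records by patient, never by image.

    Patients are sorted, shuffled by the seed, and the first
    round-half-up(train_fraction * #patients) go to the training side; every
    record follows its patient.  Deterministic given the seed.
    """
    patients = sorted(set(r.patient_id for r in manifest.records))
    if len(patients) < 2:
        raise ValueError("cannot form disjoint split: fewer than 2 patients")
    rng = np.random.default_rng(cfg.seed)
    order = list(rng.permutation(len(patients)))
    shuffled = [patients[i] for i in order]
    n_train = int(math.floor(cfg.train_fraction * len(patients) + 0.5))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_patients = set(shuffled[:n_train])
    test_patients = set(shuffled[n_train:])
    train_idx = [i for i, r in enumerate(manifest.records) if r.patient_id in train_patients]
    test_idx = [i for i, r in enumerate(manifest.records) if r.patient_id in test_patients]
    return Split(train_idx, test_idx, train_patients, test_patients)
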