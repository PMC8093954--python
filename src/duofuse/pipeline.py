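"""End-to-end orchestration of the duo-cascade.

One call runs the whole method: build (or load) feature blocks, rank them by
individual wrapper accuracy, run the greedy forward/backward set searches,
concatenate the selected blocks and reduce them with the autoencoder, train
the majority-voting ensemble on the fused code, and evaluate on the held-out
patients.  Every stage is seeded from the config, so a rerun from the saved
config snapshot reproduces the report bit-for-bit.

Two data modes are supported: ``blocks`` draws Gaussian feature blocks
directly (fast; exercises the fusion stages), ``texture`` synthesizes
labelled texture images and extracts HOG, wavelet-packet and filter-bank
blocks from them (exercises the extractors too).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .autoencoder import AEConfig
from .backends import make_filterbank_backend, deep_extract
from .blocks import FeatureBlock
from .features import HOGConfig, WPDConfig, extract_hog, extract_wpd
from .manifest import DatasetManifest, ManifestRecord, Split, SplitConfig, patient_disjoint_split
from .mcs import MCSConfig, predict_mcs, train_mcs
from .metrics import Metrics, compute_metrics, confusion_counts, macro_metrics
from .search import (
    Evaluator,
    FeatureSetRanking,
    SearchResult,
    ae_fuse,
    backward_search,
    concat_blocks,
    forward_search,
    rank_blocks,
)
from .synthetic import BlockSpec, TextureSpec, generate_feature_blocks, generate_texture_dataset, synthetic_patient_ids

log = logging.getLogger("duofuse")


@dataclass
class PipelineConfig:
    data_mode: str = "blocks"  # 'blocks' | 'texture'
    block_specs: list[dict] = field(
        default_factory=lambda: [
            {"name": "block_a", "dim": 20, "class_mean_separation": 1.5, "n_informative": 5},
            {"name": "block_b", "dim": 15, "class_mean_separation": 1.0, "n_informative": 5},
            {"name": "block_c", "dim": 10, "class_mean_separation": 0.8, "n_informative": 5},
            {"name": "noise_a", "dim": 12, "class_mean_separation": 0.0, "n_informative": 0},
            {"name": "noise_b", "dim": 18, "class_mean_separation": 0.0, "n_informative": 0},
        ]
    )
    n_samples: int = 300
    n_classes: int = 2
    texture: dict = field(default_factory=dict)
    train_fraction: float = 0.7
    strategy: str = "both"  # 'forward' | 'backward' | 'both'
    classifier_choice: str = "svm"
    use_ae_during_search: bool = False
    ae: dict = field(default_factory=lambda: {"profile": "practical", "epochs": 100})
    mcs: dict = field(default_factory=dict)
    positive_label: str | None = None
    macro: bool = False
    dataset_tag: str = "SYN"
    seed: int = 0

    def ae_config(self, **overrides) -> AEConfig:
        kw = {k: v for k, v in self.ae.items() if k != "profile"}
        kw.update(overrides)
        kw.setdefault("seed", self.seed)
        profile = self.ae.get("profile", "practical")
        if profile == "published":
            return AEConfig.published_profile(**kw)
        return AEConfig.practical_profile(**kw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


@dataclass
class RunReport:
    config: dict
    config_hash: str
    ranking: dict
    searches: dict
    stage1_metrics: dict
    stage2_metrics: dict
    fused_dim_before_ae: int
    fused_dim_after_ae: int
    member_test_accuracy: dict
    timings: dict

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "RunReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


def _metrics_dict(y_true, y_pred, positive_label: str | None, macro: bool) -> dict:
    labels = sorted(set(map(str, y_true)))
    if macro or (positive_label is None and len(labels) > 2):
        m = macro_metrics([str(v) for v in y_true], [str(v) for v in y_pred], labels)
    else:
        pos = positive_label if positive_label is not None else labels[0]
        m = compute_metrics(confusion_counts([str(v) for v in y_true], [str(v) for v in y_pred], pos))
    return m.as_dict()


def _build_blocks(cfg: PipelineConfig) -> tuple[list[FeatureBlock], np.ndarray, list[str]]:
    if cfg.data_mode == "blocks":
        specs = [BlockSpec(**s) for s in cfg.block_specs]
        blocks, labels = generate_feature_blocks(specs, cfg.n_samples, cfg.n_classes, seed=cfg.seed)
        patients = synthetic_patient_ids(labels, patients_per_class=6)
        labels = np.array([f"class{int(v)}" for v in labels])
        return blocks, labels, patients
    if cfg.data_mode == "texture":
        tex = TextureSpec(seed=cfg.seed, **cfg.texture)
        images, manifest = generate_texture_dataset(tex)
        labels = np.array(manifest.labels())
        patients = [r.patient_id for r in manifest.records]
        hog_cfg = HOGConfig()
        wpd_cfg = WPDConfig()
        backend = make_filterbank_backend(n_filters=8, input_size=tex.image_size, seed=cfg.seed)
        blocks = [
            FeatureBlock("hog", np.vstack([extract_hog(images[r.image_path], hog_cfg) for r in manifest]), "hog"),
            FeatureBlock("wpd", np.vstack([extract_wpd(images[r.image_path], wpd_cfg) for r in manifest]), "wpd"),
            FeatureBlock("filterbank", np.vstack([deep_extract(images[r.image_path], backend) for r in manifest]), "filterbank"),
        ]
        return blocks, labels, patients
    raise ValueError(f"unknown data_mode {cfg.data_mode!r}")


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    blocks, labels, patients = _build_blocks(cfg)
    timings["build_blocks"] = time.perf_counter() - t0
    log.info("built %d blocks, %d samples, seed %d", len(blocks), len(labels), cfg.seed)

    # patient-disjoint split
    manifest = DatasetManifest(
        [ManifestRecord(f"row{i:05d}", str(labels[i]), patients[i]) for i in range(len(labels))]
    )
    split = patient_disjoint_split(manifest, SplitConfig(cfg.train_fraction, seed=cfg.seed))

    evaluator = Evaluator(
        split=split,
        classifier_choice=cfg.classifier_choice,
        seed=cfg.seed,
        use_ae_during_search=cfg.use_ae_during_search,
        ae_config=cfg.ae_config() if cfg.use_ae_during_search else None,
    )

    t0 = time.perf_counter()
    ranking = rank_blocks(blocks, labels, evaluator)
    timings["rank"] = time.perf_counter() - t0
    log.info("ranking: %s", list(zip(ranking.ordered_blocks, ranking.accuracies)))

    searches: dict[str, SearchResult] = {}
    t0 = time.perf_counter()
    if cfg.strategy in ("forward", "both"):
        searches["forward"] = forward_search(ranking, blocks, labels, evaluator, cfg.dataset_tag)
    if cfg.strategy in ("backward", "both"):
        searches["backward"] = backward_search(ranking, blocks, labels, evaluator, cfg.dataset_tag)
    if not searches:
        raise ValueError(f"unknown strategy {cfg.strategy!r}")
    timings["search"] = time.perf_counter() - t0

    winner = max(searches.values(), key=lambda s: s.final_accuracy)
    by_name = {b.name: b for b in blocks}
    selected = [by_name[n] for n in winner.selected_blocks]

    t0 = time.perf_counter()
    fused = concat_blocks(selected)
    fused_ae, _model = ae_fuse(fused, split.train_indices, cfg.ae_config())
    timings["ae_fuse"] = time.perf_counter() - t0

    tr, te = split.train_indices, split.test_indices
    Xtr, Xte = fused_ae.matrix[tr], fused_ae.matrix[te]
    ytr, yte = labels[tr], labels[te]

    t0 = time.perf_counter()
    mcs_model = train_mcs(Xtr, ytr, MCSConfig(seed=cfg.seed, **cfg.mcs))
    yhat = predict_mcs(mcs_model, Xte)
    timings["mcs"] = time.perf_counter() - t0

    member_test = {
        name: float(np.mean(member.predict(Xte) == yte))
        for name, member in mcs_model.members.items()
    }
    stage2 = _metrics_dict(yte, yhat, cfg.positive_label, cfg.macro)
    stage2["vote_accuracy"] = float(np.mean(yhat == yte))

    return RunReport(
        config=asdict(cfg),
        config_hash=cfg.config_hash(),
        ranking={"ordered_blocks": ranking.ordered_blocks, "accuracies": ranking.accuracies},
        searches={
            k: json.loads(s.to_json()) for k, s in searches.items()
        },
        stage1_metrics={
            k: {"selected": s.selected_blocks, "accuracy": s.final_accuracy}
            for k, s in searches.items()
        },
        stage2_metrics=stage2,
        fused_dim_before_ae=int(fused.matrix.shape[1]),
        fused_dim_after_ae=int(fused_ae.matrix.shape[1]),
        member_test_accuracy=member_test,
        timings=timings,
    )
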