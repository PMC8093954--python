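import numpy as np
import pytest

import duofuse as d


def make_labeled_manifest(labels_patients):
    """Build a manifest from (label, patient) pairs with synthetic paths."""
    records = [
        d.ManifestRecord(f"r{i:04d}.png", lab, pat)
        for i, (lab, pat) in enumerate(labels_patients)
    ]
    return d.DatasetManifest(records)


def block_split(labels, patients_per_class=6, seed=0, train_fraction=0.7):
    """Patient-disjoint split for label-only synthetic blocks."""
    pats = d.synthetic_patient_ids(labels, patients_per_class)
    man = make_labeled_manifest(zip([str(v) for v in labels], pats))
    return d.patient_disjoint_split(man, d.SplitConfig(train_fraction, seed=seed))


@pytest.fixture(scope="session")
def texture_dataset():
    """Small two-class oriented-texture dataset with a clear class effect."""
    spec = d.TextureSpec(n_images_per_class=16, effect_size=3.0,
                         patients_per_class=4, seed=7)
    images, manifest = d.generate_texture_dataset(spec)
    return spec, images, manifest


@pytest.fixture(scope="session")
def separable_blocks():
    """One strongly informative block plus one pure-noise block, n=400."""
    specs = [
        d.BlockSpec("signal", dim=8, class_mean_separation=6.0, n_informative=1),
        d.BlockSpec("noise", dim=8),
    ]
    blocks, labels = d.generate_feature_blocks(specs, 400, 2, seed=3)
    return blocks, np.array([str(v) for v in labels])


class StubEvaluator:
    """Deterministic evaluator driven by a {frozenset(names): accuracy} table.

    Blocks must be built with :func:`tag_blocks` so that the member names of
    a candidate set can be recovered from the concatenated matrix columns.
    """

    def __init__(self, table):
        self.table = {frozenset(k): v for k, v in table.items()}
        self.calls = []

    def score(self, X, y):
        names = frozenset(f"B{int(c)}" for c in np.unique(np.asarray(X)[0]))
        self.calls.append(names)
        return self.table[names]


def tag_blocks(names, n_rows=4):
    """One single-column block per name; column value encodes the name B<i>."""
    return [
        d.FeatureBlock(name, np.full((n_rows, 1), float(name[1:])))
        for name in names
    ]
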