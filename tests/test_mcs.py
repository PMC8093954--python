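from itertools import product

import numpy as np
import pytest

import duofuse as d

from conftest import block_split


def _stub_model(val_acc, tie_rule="best_member"):
    return d.MCSModel(members={k: None for k in val_acc}, validation_accuracy=val_acc,
                      tie_rule=tie_rule, label_set=["a", "b", "c"])


class TestMajorityVote:
    def test_strict_majority_wins(self):
        model = _stub_model({"svm": 0.5, "rf": 0.5, "qda": 0.5})
        votes = [np.array([1]), np.array([1]), np.array([0])]
        assert d.majority_vote(votes, model)[0] == 1

    def test_unanimity_regardless_of_tie_rule(self):
        for rule in ("best_member", "first_member"):
            model = _stub_model({"svm": 0.1, "rf": 0.9, "qda": 0.5}, rule)
            votes = [np.array(["L"]), np.array(["L"]), np.array(["L"])]
            assert d.majority_vote(votes, model)[0] == "L"

    def test_three_way_tie_goes_to_best_member(self):
        model = _stub_model({"svm": 0.8, "rf": 0.9, "qda": 0.7})
        votes = [np.array(["a"]), np.array(["b"]), np.array(["c"])]
        assert d.majority_vote(votes, model)[0] == "b"

    def test_three_way_tie_first_member_rule(self):
        model = _stub_model({"svm": 0.8, "rf": 0.9, "qda": 0.7}, "first_member")
        votes = [np.array(["a"]), np.array(["b"]), np.array(["c"])]
        assert d.majority_vote(votes, model)[0] == "a"

    def test_length_mismatch_rejected(self):
        model = _stub_model({"svm": 0.5, "rf": 0.5, "qda": 0.5})
        with pytest.raises(ValueError, match="length"):
            d.majority_vote([np.array([1, 2]), np.array([1]), np.array([1, 2])], model)

    def test_vote_exhaustive_agreement_brute_force(self):
        """Whenever >= 2 of 3 members agree the vote equals that label —
        checked over all 27 three-member assignments of <= 3 classes, for
        both tie rules; with binary labels a tie is impossible."""
        labels = ["a", "b", "c"]
        for rule in ("best_member", "first_member"):
            model = _stub_model({"svm": 0.6, "rf": 0.9, "qda": 0.3}, rule)
            for combo in product(labels, repeat=3):
                votes = [np.array([v]) for v in combo]
                out = d.majority_vote(votes, model)[0]
                counts = {v: combo.count(v) for v in combo}
                if max(counts.values()) >= 2:
                    expected = max(counts, key=counts.get)
                    assert out == expected
                else:  # three-way tie
                    assert out == (combo[1] if rule == "best_member" else combo[0])
        # pigeonhole: 3 votes over 2 labels always produce a majority
        for combo in product(["a", "b"], repeat=3):
            assert max(combo.count(v) for v in combo) >= 2


class TestTrainPredict:
    def test_separable_fixture_all_members_strong(self, separable_blocks):
        blocks, labels = separable_blocks
        X = blocks[0].matrix
        model = d.train_mcs(X, labels, d.MCSConfig(seed=0))
        assert set(model.members) == {"svm", "rf", "qda"}
        for name, acc in model.validation_accuracy.items():
            assert acc >= 0.95, name

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            d.train_mcs(np.zeros((10, 2)), np.zeros(10), d.MCSConfig())

    def test_deterministic_predictions(self, separable_blocks):
        blocks, labels = separable_blocks
        X = blocks[0].matrix
        m1 = d.train_mcs(X, labels, d.MCSConfig(seed=3))
        m2 = d.train_mcs(X, labels, d.MCSConfig(seed=3))
        np.testing.assert_array_equal(d.predict_mcs(m1, X), d.predict_mcs(m2, X))

    def test_vote_tracks_best_member_on_training_data(self, separable_blocks):
        blocks, labels = separable_blocks
        X = blocks[0].matrix
        gaps = []
        for s in range(5):
            model = d.train_mcs(X, labels, d.MCSConfig(seed=s))
            yhat = d.predict_mcs(model, X)
            vote_acc = np.mean(yhat == labels)
            member_accs = [np.mean(model.members[k].predict(X) == labels)
                           for k in model.members]
            gaps.append(vote_acc - max(member_accs))
        assert np.median(gaps) >= -0.02

    def test_empty_input_empty_output(self, separable_blocks):
        blocks, labels = separable_blocks
        model = d.train_mcs(blocks[0].matrix, labels, d.MCSConfig(seed=0))
        assert d.predict_mcs(model, np.empty((0, blocks[0].dim))).shape == (0,)

    def test_width_mismatch_rejected(self, separable_blocks):
        blocks, labels = separable_blocks
        model = d.train_mcs(blocks[0].matrix, labels, d.MCSConfig(seed=0))
        with pytest.raises(ValueError, match="width"):
            d.predict_mcs(model, np.zeros((3, blocks[0].dim + 1)))

    def test_constant_member_stubs_give_unanimous_label(self):
        class Const:
            n_features_in_ = 2

            def predict(self, X):
                return np.array(["L"] * len(X))

        model = d.MCSModel(members={"svm": Const(), "rf": Const(), "qda": Const()},
                           validation_accuracy={"svm": 0.5, "rf": 0.5, "qda": 0.5},
                           tie_rule="best_member", label_set=["L"])
        out = d.predict_mcs(model, np.zeros((4, 2)))
        assert list(out) == ["L"] * 4

    def test_mcs_vote_near_member_median_on_moderate_problem(self):
        """Separation 2, n=600: the voted accuracy keeps up with the members
        (median over 20 seeds within 0.01 of the per-member medians)."""
        specs = [d.BlockSpec("a", dim=10, class_mean_separation=2.0, n_informative=2)]
        vote_accs, member_meds = [], []
        for s in range(20):
            blocks, labels = d.generate_feature_blocks(specs, 600, 2, seed=s)
            y = np.array([str(v) for v in labels])
            split = block_split(y, seed=s)
            tr, te = split.train_indices, split.test_indices
            X = blocks[0].matrix
            model = d.train_mcs(X[tr], y[tr], d.MCSConfig(seed=s))
            yhat = d.predict_mcs(model, X[te])
            vote_accs.append(np.mean(yhat == y[te]))
            member_meds.append(np.median([np.mean(model.members[k].predict(X[te]) == y[te])
                                          for k in model.members]))
        assert np.median(vote_accs) >= np.median(member_meds) - 0.01

    def test_model_save_load_round_trip(self, separable_blocks, tmp_path):
        blocks, labels = separable_blocks
        X = blocks[0].matrix
        model = d.train_mcs(X, labels, d.MCSConfig(seed=1))
        model.save(tmp_path / "mcs")
        loaded = d.MCSModel.load(tmp_path / "mcs")
        np.testing.assert_array_equal(d.predict_mcs(loaded, X), d.predict_mcs(model, X))
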