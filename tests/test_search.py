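import numpy as np
import pytest

import duofuse as d

from conftest import StubEvaluator, tag_blocks


def simulate_forward(ranked, score):
    """Independent step simulator for the forward rule: start from the top
    block; try each next block in rank order; keep it only on strict
    improvement."""
    current = [ranked[0]]
    best = score(current)
    for name in ranked[1:]:
        acc = score(current + [name])
        if acc > best:
            current, best = current + [name], acc
    return current, best


def simulate_backward(ranked, score):
    """Independent step simulator for the backward rule: start from all
    blocks; try removals from the lowest rank upward; a removal stands only
    on strict improvement, else the block is restored."""
    current = list(ranked)
    best = score(current)
    for name in reversed(ranked):
        if len(current) == 1:
            break
        if name not in current:
            continue
        candidate = [n for n in current if n != name]
        acc = score(candidate)
        if acc > best:
            current, best = candidate, acc
    return current, best


def random_score_table(names, rng):
    """Accuracy for every subset, rounded to 2 decimals so ties happen."""
    from itertools import combinations

    table = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            table[frozenset(combo)] = round(float(rng.uniform(0.5, 1.0)), 2)
    return table


labels4 = np.array(["x", "y", "x", "y"])


class TestRankBlocks:
    def test_orders_by_stubbed_scores_descending(self):
        blocks = tag_blocks(["B1", "B2", "B3"])
        ev = StubEvaluator({("B1",): 0.9, ("B2",): 0.7, ("B3",): 0.8})
        rk = d.rank_blocks(blocks, labels4, ev)
        assert rk.ordered_blocks == ["B1", "B3", "B2"]
        assert rk.accuracies == [0.9, 0.8, 0.7]

    def test_ties_broken_by_name_ascending(self):
        blocks = tag_blocks(["B2", "B1"])
        ev = StubEvaluator({("B1",): 0.8, ("B2",): 0.8})
        rk = d.rank_blocks(blocks, labels4, ev)
        assert rk.ordered_blocks == ["B1", "B2"]

    def test_single_block_singleton_ranking(self):
        blocks = tag_blocks(["B5"])
        rk = d.rank_blocks(blocks, labels4, StubEvaluator({("B5",): 0.66}))
        assert rk.ordered_blocks == ["B5"]
        assert rk.accuracies == [0.66]

    def test_misaligned_rows_rejected(self):
        blocks = tag_blocks(["B1"], n_rows=3)
        with pytest.raises(ValueError, match="misaligned"):
            d.rank_blocks(blocks, labels4, StubEvaluator({("B1",): 0.5}))


class TestForwardSearch:
    def test_hand_simulated_keep_and_reject(self):
        # {A}=0.80, {A,B}=0.78, {A,C}=0.85 -> B rejected, C kept on [A]
        # then the simulator and implementation both end at [A, C], 0.85
        blocks = tag_blocks(["B1", "B2", "B3"])
        table = {("B1",): 0.80, ("B2",): 0.75, ("B3",): 0.70,
                 ("B1", "B2"): 0.78, ("B1", "B3"): 0.85, ("B1", "B2", "B3"): 0.9}
        ev = StubEvaluator(table)
        rk = d.rank_blocks(blocks, labels4, ev)
        res = d.forward_search(rk, blocks, labels4, ev)
        assert res.selected_blocks == ["B1", "B3"]
        assert res.final_accuracy == 0.85

    def test_no_improvement_keeps_top_block_only(self):
        blocks = tag_blocks(["B1", "B2", "B3"])
        table = {("B1",): 0.9, ("B2",): 0.8, ("B3",): 0.7,
                 ("B1", "B2"): 0.9, ("B1", "B3"): 0.85}
        ev = StubEvaluator(table)
        res = d.forward_search(d.rank_blocks(blocks, labels4, ev), blocks, labels4, ev)
        assert res.selected_blocks == ["B1"]

    def test_monotone_improvement_selects_all(self):
        blocks = tag_blocks(["B1", "B2", "B3"])
        table = {("B1",): 0.7, ("B2",): 0.6, ("B3",): 0.5,
                 ("B1", "B2"): 0.8, ("B1", "B2", "B3"): 0.9}
        ev = StubEvaluator(table)
        res = d.forward_search(d.rank_blocks(blocks, labels4, ev), blocks, labels4, ev)
        assert res.selected_blocks == ["B1", "B2", "B3"]
        assert res.final_accuracy == 0.9

    def test_trajectory_ids_follow_fs_convention(self):
        blocks = tag_blocks(["B1", "B2"])
        ev = StubEvaluator({("B1",): 0.8, ("B2",): 0.7, ("B1", "B2"): 0.9})
        res = d.forward_search(d.rank_blocks(blocks, labels4, ev), blocks, labels4, ev,
                               dataset_tag="BH")
        assert [t.set_id for t in res.trajectory] == ["FS-1-BH-FW", "FS-2-BH-FW"]

    def test_final_at_least_top_single_block(self):
        rng = np.random.default_rng(0)
        names = [f"B{i}" for i in range(1, 6)]
        blocks = tag_blocks(names)
        for _ in range(10):
            table = random_score_table(names, rng)
            ev = StubEvaluator({tuple(k): v for k, v in table.items()})
            rk = d.rank_blocks(blocks, labels4, ev)
            res = d.forward_search(rk, blocks, labels4, ev)
            assert res.final_accuracy >= rk.accuracies[0]


class TestBackwardSearch:
    def test_hand_simulated_remove_and_restore(self):
        # {A,B,C}=0.80, drop C -> {A,B}=0.83 improves (removed),
        # drop B -> {A}=0.79 does not (restored), drop A -> {B}=0.7
        # (restored): selected [A, B], 0.83
        blocks = tag_blocks(["B1", "B2", "B3"])
        table = {("B1",): 0.79, ("B2",): 0.7, ("B3",): 0.6,
                 ("B1", "B2", "B3"): 0.80, ("B1", "B2"): 0.83,
                 ("B2", "B3"): 0.5}
        ev = StubEvaluator(table)
        rk = d.rank_blocks(blocks, labels4, ev)
        res = d.backward_search(rk, blocks, labels4, ev)
        assert res.selected_blocks == ["B1", "B2"]
        assert res.final_accuracy == 0.83
        decisions = [t.decision for t in res.trajectory]
        assert decisions == ["start", "removed", "restored", "restored"]

    def test_no_removal_keeps_all_blocks(self):
        blocks = tag_blocks(["B1", "B2", "B3"])
        table = {("B1",): 0.7, ("B2",): 0.65, ("B3",): 0.6,
                 ("B1", "B2", "B3"): 0.9, ("B1", "B2"): 0.85,
                 ("B1", "B3"): 0.8, ("B2", "B3"): 0.8}
        ev = StubEvaluator(table)
        res = d.backward_search(d.rank_blocks(blocks, labels4, ev), blocks, labels4, ev)
        assert res.selected_blocks == ["B1", "B2", "B3"]

    def test_final_at_least_all_blocks_fusion(self):
        rng = np.random.default_rng(1)
        names = [f"B{i}" for i in range(1, 6)]
        blocks = tag_blocks(names)
        for _ in range(10):
            table = random_score_table(names, rng)
            ev = StubEvaluator({tuple(k): v for k, v in table.items()})
            rk = d.rank_blocks(blocks, labels4, ev)
            res = d.backward_search(rk, blocks, labels4, ev)
            assert res.final_accuracy >= table[frozenset(names)]


class TestGreedyOracleEquivalence:
    @pytest.mark.parametrize("n_blocks", [2, 4, 7])
    def test_trajectories_match_independent_simulator(self, n_blocks):
        rng = np.random.default_rng(42)
        names = [f"B{i}" for i in range(1, n_blocks + 1)]
        blocks = tag_blocks(names)
        for _ in range(10):
            table = random_score_table(names, rng)
            score = lambda s: table[frozenset(s)]
            ev = StubEvaluator({tuple(k): v for k, v in table.items()})
            rk = d.rank_blocks(blocks, labels4, ev)
            fw = d.forward_search(rk, blocks, labels4, ev)
            bw = d.backward_search(rk, blocks, labels4, ev)
            fsel, facc = simulate_forward(rk.ordered_blocks, score)
            bsel, bacc = simulate_backward(rk.ordered_blocks, score)
            assert (fw.selected_blocks, fw.final_accuracy) == (fsel, facc)
            assert (bw.selected_blocks, bw.final_accuracy) == (bsel, bacc)


class TestEvaluatorCaching:
    def test_repeated_sets_scored_once(self):
        names = ["B1", "B2", "B3"]
        blocks = tag_blocks(names)
        table = random_score_table(names, np.random.default_rng(2))
        ev = StubEvaluator({tuple(k): v for k, v in table.items()})
        rk = d.rank_blocks(blocks, labels4, ev)
        ev.calls.clear()
        d.forward_search(rk, blocks, labels4, ev)
        assert len(ev.calls) == len(set(ev.calls))


class TestEvaluatorWrapper:
    def test_accuracy_in_unit_interval_and_deterministic(self, separable_blocks):
        from conftest import block_split

        blocks, labels = separable_blocks
        split = block_split(labels, seed=0)
        ev = d.Evaluator(split=split, seed=0)
        a1 = ev.score(blocks[0].matrix, labels)
        a2 = ev.score(blocks[0].matrix, labels)
        assert a1 == a2
        assert 0.0 <= a1 <= 1.0
        assert a1 >= 0.95  # separation 6 is nearly perfectly separable

    def test_misaligned_labels_rejected(self, separable_blocks):
        from conftest import block_split

        blocks, labels = separable_blocks
        ev = d.Evaluator(split=block_split(labels, seed=0))
        with pytest.raises(ValueError, match="misaligned"):
            ev.score(blocks[0].matrix[:-1], labels)
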