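import numpy as np
import pytest
from scipy import stats

from iclsim.category_tasks import (
    CategoryBoundary,
    CategoryTask,
    FeatureSpace,
    curriculum_from_json,
    curriculum_to_json,
    fisher_yates,
    make_curriculum,
    rotated_label,
    rule_label,
    sample_category_task,
)


class TestFeatureSpace:
    def test_defaults(self, space):
        assert space.pool_size == 200
        assert space.values_per_dim == 8

    @pytest.mark.parametrize("kwargs", [
        {"pool_size": 1}, {"values_per_dim": 1},
    ])
    def test_invalid_space_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FeatureSpace(**kwargs)


class TestRuleLabel:
    # Boundary at the midpoint: value <= 4 on the low side.
    boundary = CategoryBoundary(condition="rule_like", threshold=4,
                                relevant_dim=0, polarity=0)

    def test_low_side(self):
        assert rule_label((3, 7), self.boundary) == 0

    def test_boundary_value_is_low_side_inclusive(self):
        assert rule_label((4, 1), self.boundary) == 0

    def test_high_side(self):
        assert rule_label((5, 1), self.boundary) == 1

    def test_irrelevant_dim_never_matters(self):
        for v_rel in range(1, 9):
            labels = {rule_label((v_rel, v_irr), self.boundary)
                      for v_irr in range(1, 9)}
            assert len(labels) == 1

    def test_out_of_domain_value(self):
        with pytest.raises(ValueError):
            rule_label((0, 3), self.boundary)
        with pytest.raises(ValueError):
            rule_label((9, 3), self.boundary)

    def test_wrong_condition(self):
        rot = CategoryBoundary(condition="rotated", threshold=9)
        with pytest.raises(ValueError):
            rule_label((1, 1), rot)


class TestRotatedLabel:
    boundary = CategoryBoundary(condition="rotated", threshold=9, polarity=0)

    def test_balanced_by_enumeration(self):
        # independent count oracle: enumerate all 64 items
        counts = [0, 0]
        for v1 in range(1, 9):
            for v2 in range(1, 9):
                counts[rotated_label((v1, v2), self.boundary)] += 1
        assert counts == [32, 32]

    def test_polarity_flip_swaps_every_label(self):
        flipped = CategoryBoundary(condition="rotated", threshold=9, polarity=1)
        for v1 in range(1, 9):
            for v2 in range(1, 9):
                assert (rotated_label((v1, v2), self.boundary)
                        != rotated_label((v1, v2), flipped))

    def test_corner_item_is_low_side(self):
        # (1, 1): sum 2 < 9, so the low-side category
        assert rotated_label((1, 1), self.boundary) == 0

    def test_no_single_dimension_suffices(self):
        # changing either single dimension flips the label somewhere
        for dim in (0, 1):
            flips = False
            for v1 in range(1, 9):
                for v2 in range(1, 9):
                    other = [v1, v2]
                    for delta in range(1, 8):
                        cand = other.copy()
                        cand[dim] = 1 + (cand[dim] - 1 + delta) % 8
                        if (rotated_label((v1, v2), self.boundary)
                                != rotated_label(tuple(cand), self.boundary)):
                            flips = True
            assert flips


class TestSampleCategoryTask:
    @pytest.mark.parametrize("condition", ["rule_like", "rotated"])
    def test_structure(self, space, rng, condition):
        task = sample_category_task(space, condition, rng)
        assert len(task.items) == 64
        assert len(task.study_items) == 32
        assert len(task.heldout_items) == 32
        assert set(task.study_items) | set(task.heldout_items) == set(task.items)
        assert not set(task.study_items) & set(task.heldout_items)

    @pytest.mark.parametrize("condition", ["rule_like", "rotated"])
    def test_label_balance_exhaustive(self, space, rng, condition):
        for _ in range(20):
            task = sample_category_task(space, condition, rng)
            labels = [task.label_of(it) for it in task.items]
            assert sum(labels) == 32
            study_labels = [task.label_of(it) for it in task.study_items]
            assert sum(study_labels) == 16

    def test_seeded_determinism(self, space):
        t1 = sample_category_task(space, "rule_like", np.random.default_rng(7))
        t2 = sample_category_task(space, "rule_like", np.random.default_rng(7))
        assert t1 == t2

    def test_seed_7_has_64_items(self, space):
        task = sample_category_task(space, "rule_like", np.random.default_rng(7))
        assert len(task.items) == 64
        assert sum(task.labels) == 32

    def test_dimension_frequency_uniform(self, rng):
        # chi-square oracle over a brute-force tally of sampled dimensions
        space = FeatureSpace(pool_size=20)
        counts = np.zeros(20)
        n = 1000
        for _ in range(n):
            task = sample_category_task(space, "rule_like", rng)
            for d in task.dims:
                counts[d] += 1
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, df=19)
        assert p > 1e-4

    def test_invalid_pool(self, rng):
        with pytest.raises(ValueError):
            sample_category_task(FeatureSpace(pool_size=1), "rule_like", rng)


class TestCurriculum:
    def test_blocked_runs(self, space, rng):
        for _ in range(10):
            task = sample_category_task(space, "rule_like", rng)
            cur = make_curriculum(task, "blocked", rng)
            labels = cur.labels
            assert len(set(labels[:16])) == 1
            assert len(set(labels[16:])) == 1
            assert labels[0] != labels[16]
            assert cur.block_boundaries == (16,)

    def test_same_multiset(self, space, rng):
        task = sample_category_task(space, "rotated", rng)
        blocked = make_curriculum(task, "blocked", rng)
        inter = make_curriculum(task, "interleaved", rng)
        assert sorted(blocked.order) == sorted(inter.order)
        assert sorted(inter.order) == sorted(task.study_items)

    def test_interleaved_matches_fisher_yates_oracle(self, space):
        # independent re-implementation of the documented shuffle contract
        task = sample_category_task(space, "rule_like", np.random.default_rng(3))
        cur = make_curriculum(task, "interleaved", np.random.default_rng(11))

        oracle_rng = np.random.default_rng(11)
        expected = list(task.study_items)
        for i in range(len(expected) - 1, 0, -1):
            j = int(oracle_rng.integers(i + 1))
            expected[i], expected[j] = expected[j], expected[i]
        assert list(cur.order) == expected

    def test_first_block_label_randomized(self, space):
        rng = np.random.default_rng(0)
        task = sample_category_task(space, "rule_like", rng)
        firsts = {make_curriculum(task, "blocked", rng).labels[0]
                  for _ in range(30)}
        assert firsts == {0, 1}

    def test_fisher_yates_uniform(self):
        rng = np.random.default_rng(5)
        from collections import Counter
        c = Counter(tuple(fisher_yates([0, 1, 2], rng)) for _ in range(6000))
        assert len(c) == 6
        chi2 = sum((v - 1000) ** 2 / 1000 for v in c.values())
        assert stats.chi2.sf(chi2, df=5) > 1e-4


class TestSerialization:
    def test_task_roundtrip(self, space, rng):
        task = sample_category_task(space, "rotated", rng)
        assert CategoryTask.from_json(task.to_json()) == task

    def test_curriculum_roundtrip(self, space, rng):
        task = sample_category_task(space, "rule_like", rng)
        cur = make_curriculum(task, "blocked", rng)
        back = curriculum_from_json(curriculum_to_json(cur))
        assert back.order == cur.order
        assert back.task == task

    def test_jsonl_files(self, space, rng, tmp_path):
        from iclsim.category_tasks import load_tasks_jsonl, save_tasks_jsonl
        tasks = [sample_category_task(space, "rule_like", rng) for _ in range(5)]
        path = tmp_path / "tasks.jsonl"
        save_tasks_jsonl(tasks, path)
        assert list(load_tasks_jsonl(path)) == tasks
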