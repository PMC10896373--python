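import numpy as np
import pandas as pd
import pytest

from iclsim.encoding import build_vocab, encode_episode, strip_context
from iclsim.evaluation import (
    curriculum_effects_test,
    exact_match,
    forgetting_index,
    retention_eval,
    steps_to_criterion,
    sweep_summary,
)
from iclsim.grid_tasks import make_grid_curriculum, sample_grid_task
from iclsim.model import ModelConfig, init_model


class TestExactMatch:
    def test_all_correct(self):
        assert exact_match(np.array([1, 2, 3]), np.array([1, 2, 3])) == 1.0

    def test_three_of_four(self):
        assert exact_match(np.array([1, 2, 3, 9]), np.array([1, 2, 3, 4])) == 0.75

    def test_multi_token_requires_all(self):
        preds = np.array([[1, 2], [3, 5]])
        targets = np.array([[1, 2], [3, 4]])
        assert exact_match(preds, targets) == 0.5

    def test_empty_undefined(self):
        with pytest.raises(ValueError):
            exact_match(np.array([]), np.array([]))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            exact_match(np.array([1]), np.array([1, 2]))


def synthetic_trajectory(acc_by_phase, gradient="blocked"):
    """Blocked trajectory with one row per phase end."""
    rows = []
    for step, (group, a0, a1) in enumerate(acc_by_phase):
        rows.append({"step": step, "phase": step, "group_trained": group,
                     "acc_group0": a0, "acc_group1": a1,
                     "acc_study": (a0 + a1) / 2, "acc_test": 0.0,
                     "loss": 1.0, "cumulative_loss": step + 1.0,
                     "update_norm": 0.1})
    df = pd.DataFrame.from_records(rows)
    df.attrs["condition"] = {"gradient_curriculum": gradient}
    return df


class TestForgettingIndex:
    def test_constant_accuracy_zero(self):
        df = synthetic_trajectory([(0, 0.8, 0.2), (1, 0.8, 0.2)])
        idx = forgetting_index(df)
        assert idx[0] == pytest.approx(0.0)

    def test_planted_drop(self):
        # group 0 at 0.9 after its block, 0.2 after the other block
        df = synthetic_trajectory([(0, 0.9, 0.1), (1, 0.2, 0.9)])
        assert forgetting_index(df)[0] == pytest.approx(0.7)

    def test_interleaved_undefined(self):
        df = synthetic_trajectory([(-1, 0.5, 0.5), (-1, 0.6, 0.6)],
                                  gradient="interleaved")
        with pytest.raises(ValueError):
            forgetting_index(df)

    def test_single_block_undefined(self):
        df = synthetic_trajectory([(0, 0.9, 0.1)])
        with pytest.raises(ValueError):
            forgetting_index(df)


class TestRetention:
    def test_untrained_near_chance_and_params_untouched(self, grid_vocab, rng):
        task = sample_grid_task("rule_like", rng)
        cur = make_grid_curriculum(task, "blocked", rng)
        mc = ModelConfig(d_v=grid_vocab.d_v, n_layers=1, n_heads=2,
                         hidden_size=16, max_sequence_length=64, seed=0)
        state = init_model(mc)
        before = state.params_fingerprint()
        acc = retention_eval(state, cur, grid_vocab)
        assert state.params_fingerprint() == before
        assert acc <= 0.35  # far from the ~1.0 of a trained model

    def test_stripped_inputs_have_no_context(self, grid_vocab, rng):
        task = sample_grid_task("rule_like", rng)
        cur = make_grid_curriculum(task, "blocked", rng)
        ep = strip_context(encode_episode(cur, cur.study[0], grid_vocab))
        assert ep.context_len == 0 and len(ep.example_spans) == 0


class TestStepsToCriterion:
    def test_reached(self):
        df = synthetic_trajectory([(0, 0.2, 0.2), (1, 0.95, 0.95),
                                   (0, 1.0, 1.0)])
        assert steps_to_criterion(df) == 1

    def test_never_reached(self):
        df = synthetic_trajectory([(0, 0.2, 0.2), (1, 0.3, 0.3)])
        assert steps_to_criterion(df) == 2  # one past the last step


def planted_design(m_bb, m_bi, m_ib, m_ii, sd=0.05, n=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for cur, rot, mean in [("blocked", "rule_like", m_bb),
                           ("blocked", "rotated", m_bi),
                           ("interleaved", "rule_like", m_ib),
                           ("interleaved", "rotated", m_ii)]:
        for _ in range(n):
            rows.append({"curriculum": cur, "rotation": rot,
                         "accuracy": rng.normal(mean, sd)})
    return pd.DataFrame.from_records(rows)


def oracle_permutation_p(df, n_draws=10_000, seed=1):
    """Independent raw-permutation oracle for the interaction."""
    rng = np.random.default_rng(seed)
    y = df["accuracy"].to_numpy()
    a = (df["curriculum"] == "blocked").to_numpy()
    b = (df["rotation"] == "rule_like").to_numpy()

    def dd(yv):
        return abs((yv[a & b].mean() - yv[a & ~b].mean())
                   - (yv[~a & b].mean() - yv[~a & ~b].mean()))

    obs = dd(y)
    hits = sum(dd(y[rng.permutation(len(y))]) >= obs for _ in range(n_draws))
    return (hits + 1) / (n_draws + 1)


class TestCurriculumEffects:
    def test_constant_cells_no_interaction(self):
        df = planted_design(0.7, 0.7, 0.7, 0.7, sd=0.0, n=5)
        table = curriculum_effects_test(df, n_permutations=500)
        inter = table[table.effect.str.contains(":")].iloc[0]
        assert inter["F"] == 0.0
        assert inter["p_parametric"] == pytest.approx(1.0)

    def test_planted_crossover_significant(self):
        # means 0.9/0.6 vs 0.6/0.9, sd 0.05, n=10 per cell
        df = planted_design(0.9, 0.6, 0.6, 0.9, sd=0.05, n=10)
        table = curriculum_effects_test(df, n_permutations=10_000,
                                        rng=np.random.default_rng(2))
        inter = table[table.effect.str.contains(":")].iloc[0]
        assert inter["p_parametric"] < 0.001
        assert inter["p_permutation"] < 0.001
        # independent 10,000-draw oracle agrees
        assert oracle_permutation_p(df) < 0.001

    def test_label_swap_symmetry(self):
        df = planted_design(0.9, 0.6, 0.6, 0.9, sd=0.05, n=8, seed=3)
        swapped = df.copy()
        swapped["curriculum"] = swapped["curriculum"].map(
            {"blocked": "interleaved", "interleaved": "blocked"})
        swapped["rotation"] = swapped["rotation"].map(
            {"rule_like": "rotated", "rotated": "rule_like"})
        t1 = curriculum_effects_test(df, n_permutations=2000,
                                     rng=np.random.default_rng(0))
        t2 = curriculum_effects_test(swapped, n_permutations=2000,
                                     rng=np.random.default_rng(0))
        i1 = t1[t1.effect.str.contains(":")].iloc[0]["p_parametric"]
        i2 = t2[t2.effect.str.contains(":")].iloc[0]["p_parametric"]
        assert i1 == pytest.approx(i2)

    def test_parametric_and_permutation_agree_within_factor_two(self):
        # moderate effects spanning p in [0.001, 0.5]
        for mean_shift, seed in [(0.035, 0), (0.05, 1), (0.08, 2)]:
            df = planted_design(0.7 + mean_shift, 0.7, 0.7, 0.7 + mean_shift,
                                sd=0.05, n=10, seed=seed)
            table = curriculum_effects_test(df, n_permutations=20_000,
                                            rng=np.random.default_rng(7))
            inter = table[table.effect.str.contains(":")].iloc[0]
            p_par, p_perm = inter["p_parametric"], inter["p_permutation"]
            if 0.001 <= p_par <= 0.5:
                assert p_perm / p_par < 2.5 and p_par / p_perm < 2.5

    def test_empty_cell_rejected(self):
        df = planted_design(0.9, 0.6, 0.6, 0.9, n=4)
        df = df[~((df.curriculum == "blocked") & (df.rotation == "rotated"))]
        with pytest.raises(ValueError):
            curriculum_effects_test(df)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            curriculum_effects_test(pd.DataFrame({"accuracy": [1, 2]}))


class TestSweepSummary:
    def test_seed_averaging_sorted(self):
        df = pd.DataFrame({
            "p_a": [0.4, 0.0, 0.4, 0.0],
            "seed": [0, 0, 1, 1],
            "few_shot_accuracy": [0.5, 0.9, 0.7, 1.0],
            "steps_to_criterion": [4, 2, 6, 2],
            "cumulative_loss": [3.0, 1.0, 5.0, 1.0],
            "retention_accuracy": [0.8, 0.2, 0.9, 0.3],
        })
        s = sweep_summary(df)
        assert list(s["p_a"]) == [0.0, 0.4]
        assert s["few_shot_accuracy"].iloc[0] == pytest.approx(0.95)
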