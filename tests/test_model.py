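import numpy as np
import pytest

from iclsim.category_tasks import make_curriculum, sample_category_task
from iclsim.encoding import build_vocab, encode_episode
from iclsim.grid_tasks import make_grid_curriculum, sample_grid_task
from iclsim.model import (
    AblationSpec,
    Adam,
    Batch,
    ModelConfig,
    forward,
    greedy_decode,
    init_model,
    loss_and_grads,
    make_batch,
    param_count,
    save_checkpoint,
    load_checkpoint,
    teacher_forced_predictions,
)


@pytest.fixture(scope="module")
def grid_setup():
    vocab = build_vocab("compositional")
    rng = np.random.default_rng(0)
    task = sample_grid_task("rule_like", rng)
    cur = make_grid_curriculum(task, "blocked", rng)
    episodes = [encode_episode(cur, q, vocab) for q in task.cues]
    cfg = ModelConfig(d_v=vocab.d_v, n_layers=2, n_heads=4, hidden_size=32,
                      max_sequence_length=64, seed=3)
    return vocab, cur, episodes, cfg


class TestConfig:
    def test_ffn_is_twice_hidden(self):
        cfg = ModelConfig(d_v=10, hidden_size=64)
        assert cfg.ffn_size == 128

    def test_heads_must_divide_hidden(self):
        with pytest.raises(ValueError):
            ModelConfig(d_v=10, n_heads=7, hidden_size=64)

    def test_category_default_depth(self):
        cfg = ModelConfig(d_v=1604)  # reference category architecture
        assert cfg.n_layers == 4 and cfg.n_heads == 8 and cfg.hidden_size == 64


class TestInit:
    def test_bitwise_determinism(self):
        cfg = ModelConfig(d_v=21, n_layers=2, n_heads=2, hidden_size=16,
                          max_sequence_length=32, seed=9)
        s1, s2 = init_model(cfg), init_model(cfg)
        for k in s1.params:
            assert np.array_equal(s1.params[k], s2.params[k])

    def test_param_count_closed_form(self):
        # independent analytic count
        cfg = ModelConfig(d_v=21, n_layers=3, n_heads=4, hidden_size=24,
                          max_sequence_length=40)
        d, f, v, t, L = 24, 48, 21, 40, 3
        expected = (
            v * d + t * d
            + L * (4 * (d * d + d) + d * f + f + f * d + d + 4 * d)
            + 2 * d + d * v + v
        )
        assert param_count(cfg) == expected
        assert init_model(cfg).n_params == expected


class TestForward:
    def test_distributions_normalized(self, grid_setup):
        _, _, episodes, cfg = grid_setup
        state = init_model(cfg)
        probs = forward(state, episodes[:4])
        assert probs.shape[0] == 4
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-5)
        assert (probs >= 0).all()

    def test_overlong_sequence_rejected(self, grid_setup):
        vocab, cur, episodes, _ = grid_setup
        cfg = ModelConfig(d_v=21, n_layers=1, n_heads=2, hidden_size=16,
                          max_sequence_length=10)
        state = init_model(cfg)
        with pytest.raises(ValueError):
            forward(state, episodes[0])

    def test_causal_masking(self, grid_setup):
        # output at position i is invariant to perturbing tokens after i
        _, _, episodes, cfg = grid_setup
        state = init_model(cfg)
        ep = episodes[0]
        probs = forward(state, ep)
        perturbed = ep.tokens.copy()
        perturbed[-1] = (perturbed[-1] + 1) % cfg.d_v
        from dataclasses import replace
        ep2 = replace(ep, tokens=perturbed)
        probs2 = forward(state, ep2)
        i = len(ep.tokens) - 2
        np.testing.assert_allclose(probs[0, :i + 1], probs2[0, :i + 1],
                                   atol=1e-6)

    def test_p_a_zero_identical(self, grid_setup):
        _, _, episodes, cfg = grid_setup
        state = init_model(cfg)
        rng = np.random.default_rng(5)
        base = forward(state, episodes[:3])
        abl = forward(state, episodes[:3], ablation=AblationSpec(0.0), rng=rng)
        np.testing.assert_allclose(base, abl, atol=0)

    def test_p_a_one_context_invariance(self, grid_setup):
        # fully ablated: query outputs invariant to replacing study examples
        vocab, _, _, cfg = grid_setup
        state = init_model(cfg)
        rng = np.random.default_rng(1)
        outs = []
        query = ("red", "alligator")
        for seed in (10, 11):
            r = np.random.default_rng(seed)
            task = sample_grid_task("rule_like", r)
            cur = make_grid_curriculum(task, "blocked", r)
            ep = encode_episode(cur, query, vocab)
            probs = forward(state, ep, ablation=AblationSpec(1.0), rng=rng)
            # query positions only: <q>, color, animal (the teacher-forced
            # answer position depends on the fed ground-truth token)
            outs.append(probs[0, ep.context_len:ep.context_len + 3])
        np.testing.assert_allclose(outs[0], outs[1], atol=1e-5)

    def test_ablation_expected_visibility(self, grid_setup):
        # E[#visible examples] = (1 - p_a) * n_examples (Monte-Carlo)
        _, _, episodes, _ = grid_setup
        rng = np.random.default_rng(2)
        p_a = 0.3
        n_trials = 400
        visible = 0
        for _ in range(n_trials):
            batch = make_batch(episodes[:1], ablation=AblationSpec(p_a), rng=rng)
            for s, e in episodes[0].example_spans:
                visible += bool(batch.key_visible[0, s])
        expected = (1 - p_a) * 9
        got = visible / n_trials
        se = np.sqrt(9 * p_a * (1 - p_a) / n_trials)
        assert abs(got - expected) < 5 * se

    def test_invalid_ablation(self):
        with pytest.raises(ValueError):
            AblationSpec(1.5)
        with pytest.raises(NotImplementedError):
            AblationSpec(0.5, mode="noise")


class TestGreedyDecode:
    def test_deterministic(self, grid_setup):
        _, _, episodes, cfg = grid_setup
        state = init_model(cfg)
        p1 = greedy_decode(state, episodes[:5])
        p2 = greedy_decode(state, episodes[:5])
        assert np.array_equal(p1, p2)

    def test_rigged_output_layer(self, grid_setup):
        vocab, _, episodes, cfg = grid_setup
        state = init_model(cfg)
        t = vocab["c3"]
        state.params["w_out"][:] = 0
        state.params["b_out"][:] = 0
        state.params["b_out"][t] = 10.0
        preds = greedy_decode(state, episodes[:4])
        assert (preds == t).all()

    def test_matches_teacher_forced_on_single_token_targets(self, rng):
        # exact-match equivalence on 1-token category answers
        from iclsim.category_tasks import FeatureSpace
        space = FeatureSpace(pool_size=5)
        vocab = build_vocab("category", space)
        task = sample_category_task(space, "rule_like", rng)
        cur = make_curriculum(task, "blocked", rng)
        eps = [encode_episode(cur, q, vocab) for q in task.items[:16]]
        cfg = ModelConfig(d_v=vocab.d_v, n_layers=2, n_heads=4, hidden_size=32,
                          max_sequence_length=128, seed=0)
        state = init_model(cfg)
        greedy = greedy_decode(state, eps)
        tf = teacher_forced_predictions(state, make_batch(eps))
        assert np.array_equal(greedy, tf)

    def test_frozen_evaluation_contract(self, grid_setup):
        _, _, episodes, cfg = grid_setup
        state = init_model(cfg)
        before = state.params_fingerprint()
        forward(state, episodes[:2])
        greedy_decode(state, episodes[:2])
        assert state.params_fingerprint() == before


class TestTraining:
    def test_loss_decreases(self, grid_setup):
        _, _, episodes, cfg = grid_setup
        state = init_model(cfg)
        batch = make_batch(episodes[:8])
        opt = Adam(state.params, lr=1e-2)
        first, _ = loss_and_grads(state, batch)
        for _ in range(30):
            loss, grads = loss_and_grads(state, batch)
            opt.step(state.params, grads)
        last, _ = loss_and_grads(state, batch, train=False)
        assert last < first / 2

    def test_gradient_check(self):
        # finite differences on a tiny model
        from iclsim.encoding import Episode
        rng = np.random.default_rng(0)
        cfg = ModelConfig(d_v=11, n_layers=1, n_heads=2, hidden_size=8,
                          max_sequence_length=16, seed=1)
        state = init_model(cfg)
        state.params = {k: v.astype(np.float64) for k, v in state.params.items()}
        ep = Episode(
            tokens=rng.integers(0, 11, size=9), positions=np.arange(9),
            target=rng.integers(0, 11, size=2),
            target_positions=np.arange(9, 11), context_len=6,
            example_spans=((0, 3), (3, 6)), example_groups=(0, 1),
            query_group=0, split="train_query", family="compositional")
        batch = make_batch([ep])
        _, grads = loss_and_grads(state, batch, train=False)
        h = 1e-5
        for name in ("l0_wq", "w_out", "tok_emb", "l0_ln1_g"):
            flat = state.params[name].ravel()
            i = int(rng.integers(flat.size))
            old = flat[i]
            flat[i] = old + h
            lp, _ = loss_and_grads(state, batch, train=False)
            flat[i] = old - h
            lm, _ = loss_and_grads(state, batch, train=False)
            flat[i] = old
            num = (lp - lm) / (2 * h)
            ana = grads[name].ravel()[i]
            assert ana == pytest.approx(num, rel=2e-2, abs=1e-7)

    def test_context_supervision_layout(self, grid_setup):
        _, _, episodes, _ = grid_setup
        batch = make_batch(episodes[:3], context_supervision=True)
        # 9 examples x 2 answer tokens + 2 query answer tokens
        assert batch.loss_idx.shape == (3, 20)
        assert batch.targets.shape == (3, 20)
        # weights give the query answer half the total mass
        w = batch.target_weights
        assert w[-2:].sum() == pytest.approx(w[:-2].sum())

    def test_dropout_requires_rng(self, grid_setup):
        _, _, episodes, _ = grid_setup
        cfg = ModelConfig(d_v=21, n_layers=1, n_heads=2, hidden_size=16,
                          max_sequence_length=64, dropout=0.2)
        state = init_model(cfg)
        batch = make_batch(episodes[:2])
        with pytest.raises(ValueError):
            loss_and_grads(state, batch, train=True, drop_rng=None)
        loss, _ = loss_and_grads(state, batch, train=True,
                                 drop_rng=np.random.default_rng(0))
        assert np.isfinite(loss)


class TestCheckpoint:
    def test_roundtrip(self, grid_setup, tmp_path):
        _, _, episodes, cfg = grid_setup
        state = init_model(cfg)
        save_checkpoint(state, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        assert loaded.config == state.config
        assert loaded.params_fingerprint() == state.params_fingerprint()
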