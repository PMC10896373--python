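"""Metalearning (pretraining) and task-specific finetuning loops.

Metalearning trains the network on a distribution of freshly sampled tasks
so that in-context learning emerges in the forward pass; finetuning trains
on a single task's study examples with blocked or interleaved gradient
schedules, which is where in-context and in-weight learning interact.
Frozen-weight few-shot evaluation measures pure ICL.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from iclsim import category_tasks as ct
from iclsim import grid_tasks as gt
from iclsim.encoding import Episode, Vocabulary, build_vocab, encode_episode
from iclsim.model import (
    AblationSpec,
    Adam,
    ModelConfig,
    ModelState,
    greedy_decode,
    init_model,
    loss_and_grads,
    make_batch,
)

Family = Literal["category", "compositional"]
CurriculumCondition = Literal["blocked", "interleaved"]


class ContractError(RuntimeError):
    """Raised when a configuration contradicts itself (e.g. freeze+finetune)."""


@dataclass(frozen=True)
class MetaTrainConfig:
    """Task-distribution pretraining configuration.

    Defaults (via :meth:`category` / :meth:`compositional`) follow the
    reference settings: 12,000 training tasks, 100 validation and 10 test
    tasks; 20 epochs at lr 1e-4 (category) or 500 epochs at lr 1e-3
    (compositional), batch size 256, Adam, cross-entropy.
    """

    family: Family
    n_train_tasks: int = 12_000
    n_val_tasks: int = 100
    n_test_tasks: int = 10
    epochs: int = 20
    learning_rate: float = 1e-4
    batch_size: int = 256
    task_condition: ct.Condition = "rule_like"
    curriculum: CurriculumCondition = "blocked"
    query_policy: Literal["mixed", "train_only"] = "mixed"
    context_supervision: bool = True
    query_loss_share: float = 0.5
    micro_batch: int = 64  # gradient-accumulation chunk (memory bound)
    warmup_steps: int = 0
    adam_beta2: float = 0.999
    val_queries_per_task: int = 8
    val_every: int = 1

    @classmethod
    def category(cls, **overrides) -> "MetaTrainConfig":
        return replace(cls(family="category"), **overrides)

    @classmethod
    def compositional(cls, **overrides) -> "MetaTrainConfig":
        return replace(
            cls(family="compositional", epochs=500, learning_rate=1e-3),
            **overrides,
        )


@dataclass(frozen=True)
class FinetuneConfig:
    """Single-task training configuration.

    ``steps_per_block`` is the N gradient steps spent on one stimulus group
    before switching; context and gradient curricula are congruent by
    default.  ``blocked_batch`` resolves the ambiguity of what a blocked
    batch contains: the current group's study queries only (``group_only``)
    or all study queries (``mixed``).
    """

    family: Family
    learning_rate: float
    steps_per_block: int = 10
    n_block_alternations: int = 10
    context_curriculum: CurriculumCondition = "blocked"
    gradient_curriculum: CurriculumCondition = "blocked"
    blocked_batch: Literal["group_only", "mixed"] = "group_only"
    freeze_weights: bool = False
    keep_dropout: bool = False  # dropout is a metalearning regularizer
    eval_every: int = 1

    def __post_init__(self) -> None:
        if self.steps_per_block < 1:
            raise ValueError("steps_per_block must be >= 1")

    @classmethod
    def category(cls, **overrides) -> "FinetuneConfig":
        return replace(cls(family="category", learning_rate=1e-5), **overrides)

    @classmethod
    def compositional(cls, **overrides) -> "FinetuneConfig":
        return replace(cls(family="compositional", learning_rate=1e-4), **overrides)

    def with_condition(self, condition: CurriculumCondition) -> "FinetuneConfig":
        return replace(self, context_curriculum=condition,
                       gradient_curriculum=condition)


# ---------------------------------------------------------------------------
# task plumbing


def sample_tasks(
    family: Family,
    condition: ct.Condition,
    n: int,
    rng: np.random.Generator,
    space: ct.FeatureSpace | None = None,
    exclude: set | None = None,
):
    """Sample ``n`` tasks whose identity key avoids ``exclude`` (train/val
    separation: dimension pairs for category tasks, grid layout for grids)."""
    tasks = []
    keys = set()
    exclude = exclude or set()
    attempts = 0
    max_attempts = 200 * n + 10_000
    while len(tasks) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not sample {n} tasks outside the excluded identity set "
                f"({len(exclude)} keys) — task space too small?"
            )
        if family == "category":
            task = ct.sample_category_task(space or ct.FeatureSpace(), condition, rng)
            key = frozenset(task.dims)
        else:
            task = gt.sample_grid_task(condition, rng)
            key = (task.color_order, task.animal_order, task.color_is_x)
        if key in exclude:
            continue
        tasks.append(task)
        keys.add(key)
    return tasks, keys


def task_identity_key(task):
    if isinstance(task, ct.CategoryTask):
        return frozenset(task.dims)
    return (task.color_order, task.animal_order, task.color_is_x)


def make_task_curriculum(task, condition: CurriculumCondition,
                         rng: np.random.Generator):
    if isinstance(task, ct.CategoryTask):
        return ct.make_curriculum(task, condition, rng)
    return gt.make_grid_curriculum(task, condition, rng)


def all_queries(curriculum) -> tuple:
    if isinstance(curriculum, ct.Curriculum):
        return curriculum.task.items
    return curriculum.task.cues


def study_queries(curriculum) -> tuple:
    if isinstance(curriculum, ct.Curriculum):
        return curriculum.task.study_items
    return curriculum.study


def heldout_queries(curriculum) -> tuple:
    if isinstance(curriculum, ct.Curriculum):
        return curriculum.task.heldout_items
    return curriculum.test


def _sample_query(curriculum, policy: str, rng: np.random.Generator):
    pool = study_queries(curriculum) if policy == "train_only" else all_queries(curriculum)
    return pool[int(rng.integers(len(pool)))]


# ---------------------------------------------------------------------------
# metalearning


def metalearn(
    model_config: ModelConfig,
    meta_config: MetaTrainConfig,
    rng: np.random.Generator,
    space: ct.FeatureSpace | None = None,
    vocab: Vocabulary | None = None,
    init_state: ModelState | None = None,
    progress: bool = False,
):
    """Pretrain on a distribution of tasks; returns the best-validation
    checkpoint, the per-epoch report, and the (vocab, val/test task) bundle."""
    fam = meta_config.family
    vocab = vocab or build_vocab(fam, space)
    if vocab.d_v != model_config.d_v:
        raise ContractError(
            f"model d_v={model_config.d_v} != vocabulary d_v={vocab.d_v}"
        )
    # reserve the held-out task identities first so train tasks can avoid
    # them even when the identity space is small
    val_tasks, val_keys = sample_tasks(
        fam, meta_config.task_condition, meta_config.n_val_tasks, rng, space
    )
    test_tasks, test_keys = sample_tasks(
        fam, meta_config.task_condition, meta_config.n_test_tasks, rng, space,
        exclude=val_keys,
    )
    train_tasks, train_keys = sample_tasks(
        fam, meta_config.task_condition, meta_config.n_train_tasks, rng, space,
        exclude=val_keys | test_keys,
    )

    state = init_state.copy() if init_state is not None else init_model(model_config)
    opt = Adam(state.params, lr=meta_config.learning_rate,
               betas=(0.9, meta_config.adam_beta2))
    drop_rng = np.random.default_rng(rng.integers(2**63))
    val_rng_seed = int(rng.integers(2**63))

    best_acc, best_params = -1.0, None
    records = []
    n = len(train_tasks)
    for epoch in range(meta_config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, meta_config.batch_size):
            episodes = []
            for ti in order[start:start + meta_config.batch_size]:
                cur = make_task_curriculum(train_tasks[ti], meta_config.curriculum, rng)
                query = _sample_query(cur, meta_config.query_policy, rng)
                episodes.append(encode_episode(cur, query, vocab))
            # gradient accumulation keeps attention memory bounded
            mb = max(1, meta_config.micro_batch)
            grads_total: dict[str, np.ndarray] = {}
            loss_total = 0.0
            for ci in range(0, len(episodes), mb):
                chunk = episodes[ci:ci + mb]
                batch = make_batch(
                    chunk,
                    context_supervision=meta_config.context_supervision,
                    query_loss_share=meta_config.query_loss_share)
                loss, grads = loss_and_grads(state, batch, train=True,
                                             drop_rng=drop_rng)
                w = len(chunk) / len(episodes)
                loss_total += loss * w
                for k, g in grads.items():
                    if k in grads_total:
                        grads_total[k] += g * w
                    else:
                        grads_total[k] = g * w
            if meta_config.warmup_steps > 0:
                frac = min(1.0, (opt.t + 1) / meta_config.warmup_steps)
                opt.lr = meta_config.learning_rate * frac
            opt.step(state.params, grads_total)
            losses.append(loss_total)
        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if (epoch + 1) % meta_config.val_every == 0 or epoch == meta_config.epochs - 1:
            # fixed validation rng so epochs are compared on the same episodes
            vrng = np.random.default_rng(val_rng_seed)
            val_acc = _quick_eval(state, val_tasks, meta_config, vocab, vrng)
            record["val_acc"] = val_acc
            if val_acc >= best_acc:
                best_acc = val_acc
                best_params = {k: v.copy() for k, v in state.params.items()}
        records.append(record)
        if progress:
            print(f"epoch {epoch}: {record}", flush=True)
    best = ModelState(model_config, best_params or state.params)
    report = pd.DataFrame.from_records(records)
    return best, report, {"vocab": vocab, "val_tasks": val_tasks,
                          "test_tasks": test_tasks, "train_keys": train_keys}


def _quick_eval(state, tasks, meta_config, vocab, rng) -> float:
    episodes = []
    for task in tasks:
        cur = make_task_curriculum(task, meta_config.curriculum, rng)
        pool = all_queries(cur)
        k = min(meta_config.val_queries_per_task, len(pool))
        for qi in rng.choice(len(pool), size=k, replace=False):
            episodes.append(encode_episode(cur, pool[qi], vocab))
    correct = 0
    for start in range(0, len(episodes), 256):
        chunk = episodes[start:start + 256]
        preds = greedy_decode(state, chunk)
        targets = np.stack([e.target for e in chunk])
        correct += int((preds == targets).all(axis=1).sum())
    return correct / len(episodes)


# ---------------------------------------------------------------------------
# frozen-weight few-shot evaluation


def few_shot_eval(
    state: ModelState,
    tasks: Sequence,
    curriculum_condition: CurriculumCondition,
    vocab: Vocabulary,
    rng: np.random.Generator,
    ablation: AblationSpec | None = None,
):
    """Exact-match accuracy of frozen-weight greedy decoding on each task.

    Every item of every task is queried once; accuracies are split into
    study-item and held-out queries.  Returns an
    :class:`iclsim.evaluation.EvalReport`.
    """
    from iclsim.evaluation import EvalReport

    fingerprint = state.params_fingerprint()
    rows = []
    for ti, task in enumerate(tasks):
        cur = make_task_curriculum(task, curriculum_condition, rng)
        episodes = [encode_episode(cur, q, vocab) for q in all_queries(cur)]
        preds = greedy_decode(state, episodes, ablation=ablation, rng=rng)
        targets = np.stack([e.target for e in episodes])
        hit = (preds == targets).all(axis=1)
        for e, h in zip(episodes, hit):
            rows.append({
                "task": ti,
                "split": e.split,
                "group": e.query_group,
                "correct": bool(h),
            })
    assert state.params_fingerprint() == fingerprint, "evaluation mutated params"
    df = pd.DataFrame.from_records(rows)
    return EvalReport.from_frame(
        df, chance=vocab.chance,
        condition={"curriculum": curriculum_condition},
    )


# ---------------------------------------------------------------------------
# task-specific finetuning


def _study_by_group(curriculum) -> dict[int, list]:
    """Study queries keyed by stimulus group (category label or row/column)."""
    if isinstance(curriculum, ct.Curriculum):
        groups: dict[int, list] = {0: [], 1: []}
        for it in curriculum.task.study_items:
            groups[curriculum.task.label_of(it)].append(it)
        return groups
    group_ix = {g: i for i, g in enumerate(curriculum.block_order)}
    groups = {0: [], 1: []}
    for cue in curriculum.study:
        groups[group_ix[curriculum.group_of[cue]]].append(cue)
    return groups


def _first_context_group(curriculum) -> int:
    if isinstance(curriculum, ct.Curriculum):
        return curriculum.task.label_of(curriculum.order[0])
    return 0  # block_order[0] is group 0 by construction


def finetune_task(
    state: ModelState,
    curriculum,
    config: FinetuneConfig,
    vocab: Vocabulary,
    rng: np.random.Generator,
    ablation: AblationSpec | None = None,
):
    """Train on one task's study examples; returns (trajectory, final state).

    The context shown in every episode follows ``config.context_curriculum``
    (the given ``curriculum``); the gradient schedule follows
    ``config.gradient_curriculum``: blocked alternates N-step phases on one
    stimulus group's queries, interleaved draws all study queries each step.
    Each logged step records per-group study accuracy and held-out accuracy
    measured with frozen weights, plus the parameter-update norm.
    """
    if config.freeze_weights:
        raise ContractError("finetune_task called with freeze_weights=True")
    if curriculum.condition != config.context_curriculum:
        raise ContractError(
            f"curriculum condition {curriculum.condition!r} != "
            f"context_curriculum {config.context_curriculum!r}"
        )
    state = state.copy()
    if not config.keep_dropout and state.config.dropout > 0:
        from dataclasses import replace as _replace

        state = ModelState(_replace(state.config, dropout=0.0), state.params)
    opt = Adam(state.params, lr=config.learning_rate)
    drop_rng = np.random.default_rng(rng.integers(2**63))
    eval_rng = np.random.default_rng(rng.integers(2**63))

    groups = _study_by_group(curriculum)
    study = study_queries(curriculum)
    heldout = heldout_queries(curriculum)
    eval_episodes = {
        "study": [encode_episode(curriculum, q, vocab) for q in study],
        "heldout": [encode_episode(curriculum, q, vocab) for q in heldout],
    }
    total_steps = 2 * config.n_block_alternations * config.steps_per_block
    first = _first_context_group(curriculum)

    records = []
    cumulative_loss = 0.0
    for step in range(total_steps):
        phase = step // config.steps_per_block
        if config.gradient_curriculum == "blocked":
            group = first if phase % 2 == 0 else 1 - first
            if config.blocked_batch == "group_only":
                queries = list(groups[group])
            else:
                queries = list(study)
        else:
            group = -1
            queries = list(study)
        episodes = [encode_episode(curriculum, q, vocab) for q in queries]
        batch = make_batch(episodes, ablation=ablation, rng=rng)
        loss, grads = loss_and_grads(state, batch, train=True, drop_rng=drop_rng)
        before = {k: v.copy() for k, v in state.params.items()}
        opt.step(state.params, grads)
        update_norm = float(np.sqrt(sum(
            float(((state.params[k] - before[k]) ** 2).sum()) for k in before
        )))
        cumulative_loss += loss

        record = {
            "step": step, "phase": phase, "group_trained": group,
            "loss": loss, "update_norm": update_norm,
            "cumulative_loss": cumulative_loss,
        }
        if (step + 1) % config.eval_every == 0 or step == total_steps - 1:
            record.update(_trajectory_metrics(
                state, eval_episodes, ablation, eval_rng))
        records.append(record)

    trajectory = pd.DataFrame.from_records(records)
    trajectory.attrs["config"] = config
    trajectory.attrs["condition"] = {
        "context_curriculum": config.context_curriculum,
        "gradient_curriculum": config.gradient_curriculum,
        "task_condition": curriculum.task.condition,
    }
    return trajectory, state


def _trajectory_metrics(state, eval_episodes, ablation, eval_rng) -> dict:
    out = {}
    study = eval_episodes["study"]
    preds = greedy_decode(state, study, ablation=ablation, rng=eval_rng)
    targets = np.stack([e.target for e in study])
    hit = (preds == targets).all(axis=1)
    groups = np.array([e.query_group for e in study])
    out["acc_study"] = float(hit.mean())
    for g in (0, 1):
        sel = groups == g
        out[f"acc_group{g}"] = float(hit[sel].mean()) if sel.any() else np.nan
    held = eval_episodes["heldout"]
    preds = greedy_decode(state, held, ablation=ablation, rng=eval_rng)
    targets = np.stack([e.target for e in held])
    out["acc_test"] = float((preds == targets).all(axis=1).mean())
    return out


def save_trajectory_csv(trajectory: pd.DataFrame, path) -> None:
    """Tidy CSV export: one row per (step, metric)."""
    long = trajectory.melt(id_vars=["step", "phase", "group_trained"],
                           var_name="metric", value_name="value")
    long.to_csv(path, index=False)
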