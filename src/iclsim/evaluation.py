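"""Metrics, the retention protocol, curriculum statistics, and the
flexibility-retention ablation sweep."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from iclsim import category_tasks as ct
from iclsim.encoding import Vocabulary, encode_episode, strip_context
from iclsim.model import AblationSpec, ModelConfig, ModelState, greedy_decode
from iclsim.training import (
    FinetuneConfig,
    MetaTrainConfig,
    few_shot_eval,
    finetune_task,
    make_task_curriculum,
    metalearn,
    study_queries,
)


def exact_match(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Fraction of queries whose answer tokens are all correct."""
    predictions = np.asarray(predictions)
    targets = np.asarray(targets)
    if predictions.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: {predictions.shape} vs {targets.shape}"
        )
    if predictions.size == 0:
        raise ValueError("exact_match is undefined on empty input")
    if predictions.ndim == 1:
        predictions = predictions[:, None]
        targets = targets[:, None]
    return float((predictions == targets).all(axis=1).mean())


@dataclass
class EvalReport:
    """Accuracy summary of one frozen-weight evaluation."""

    accuracy: float
    accuracy_study: float
    accuracy_heldout: float
    per_group: dict[int, float]
    n_queries: int
    chance: float
    condition: dict = field(default_factory=dict)
    frame: pd.DataFrame | None = None

    @classmethod
    def from_frame(cls, df: pd.DataFrame, chance: float,
                   condition: dict | None = None) -> "EvalReport":
        study = df[df.split == "train_query"]
        held = df[df.split == "test_query"]
        per_group = df.groupby("group")["correct"].mean().to_dict()
        return cls(
            accuracy=float(df["correct"].mean()),
            accuracy_study=float(study["correct"].mean()) if len(study) else np.nan,
            accuracy_heldout=float(held["correct"].mean()) if len(held) else np.nan,
            per_group={int(k): float(v) for k, v in per_group.items()},
            n_queries=len(df),
            chance=chance,
            condition=dict(condition or {}),
            frame=df,
        )

    def to_json(self) -> str:
        return json.dumps({
            "accuracy": self.accuracy,
            "accuracy_study": self.accuracy_study,
            "accuracy_heldout": self.accuracy_heldout,
            "per_group": self.per_group,
            "n_queries": self.n_queries,
            "chance": self.chance,
            "condition": self.condition,
        })


def forgetting_index(trajectory: pd.DataFrame) -> dict[int, float]:
    """Per-group accuracy drop from the end of the group's own block to the
    end of the subsequent other-group block (positive = forgetting).

    Averaged over all such adjacent block pairs of a blocked trajectory.
    """
    cond = trajectory.attrs.get("condition", {})
    if cond.get("gradient_curriculum") == "interleaved" or (
        "group_trained" in trajectory and (trajectory["group_trained"] < 0).all()
    ):
        raise ValueError("forgetting_index is undefined for interleaved runs")
    phases = trajectory.dropna(subset=["acc_group0"]).groupby("phase").last()
    if len(phases) < 2:
        raise ValueError("forgetting_index needs at least two blocks")
    drops: dict[int, list[float]] = {}
    phase_ids = list(phases.index)
    for a, b in zip(phase_ids[:-1], phase_ids[1:]):
        g = int(phases.loc[a, "group_trained"])
        col = f"acc_group{g}"
        drops.setdefault(g, []).append(
            float(phases.loc[a, col]) - float(phases.loc[b, col])
        )
    return {g: float(np.mean(v)) for g, v in sorted(drops.items())}


def retention_eval(
    state: ModelState,
    curriculum,
    vocab: Vocabulary,
) -> float:
    """Exact-match on the study items with the context stripped away.

    Probes what finetuning stored in the weights, as opposed to what the
    model reads off the context; parameters are untouched.
    """
    fingerprint = state.params_fingerprint()
    episodes = [
        strip_context(encode_episode(curriculum, q, vocab))
        for q in study_queries(curriculum)
    ]
    preds = greedy_decode(state, episodes)
    targets = np.stack([e.target for e in episodes])
    acc = exact_match(preds, targets)
    assert state.params_fingerprint() == fingerprint
    return acc


# ---------------------------------------------------------------------------
# flexibility-retention tradeoff


DEFAULT_P_GRID = (0.0, 0.2, 0.4, 0.6, 0.8)
STEPS_TO_CRITERION_THRESHOLD = 0.9


def steps_to_criterion(trajectory: pd.DataFrame,
                       threshold: float = STEPS_TO_CRITERION_THRESHOLD) -> float:
    """First step at which study accuracy reaches ``threshold``.

    Returns ``len(trajectory)`` (one past the last step) if never reached,
    so slower-is-larger comparisons remain well defined.
    """
    reached = trajectory.dropna(subset=["acc_study"])
    hits = reached[reached["acc_study"] >= threshold]
    if len(hits) == 0:
        return float(len(trajectory))
    return float(hits["step"].iloc[0])


def tradeoff_sweep(
    state: ModelState,
    eval_tasks: Sequence,
    finetune_config: FinetuneConfig,
    vocab: Vocabulary,
    rng: np.random.Generator,
    p_a_grid: Sequence[float] = DEFAULT_P_GRID,
    n_seeds: int = 5,
) -> pd.DataFrame:
    """Sweep the attention-ablation level ``p_a`` and record, per level and
    seed: metalearned few-shot accuracy under ablation, finetuning speed
    (steps to criterion), cumulative loss, and context-free retention."""
    p_a_grid = sorted(p_a_grid)
    rows = []
    for p_a in p_a_grid:
        ablation = AblationSpec(p_a=p_a) if p_a > 0 else None
        for seed_i in range(n_seeds):
            run_rng = np.random.default_rng(rng.integers(2**63))
            task = eval_tasks[seed_i % len(eval_tasks)]
            # few-shot flexibility is measured across all eval tasks for a
            # stable estimate; finetuning/retention use this seed's task
            report = few_shot_eval(
                state, list(eval_tasks), finetune_config.context_curriculum,
                vocab, run_rng, ablation=ablation,
            )
            curriculum = make_task_curriculum(
                task, finetune_config.context_curriculum, run_rng)
            trajectory, trained = finetune_task(
                state, curriculum, finetune_config, vocab, run_rng,
                ablation=ablation,
            )
            rows.append({
                "p_a": p_a,
                "seed": seed_i,
                "few_shot_accuracy": report.accuracy,
                "steps_to_criterion": steps_to_criterion(trajectory),
                "cumulative_loss": float(trajectory["cumulative_loss"].iloc[-1]),
                "retention_accuracy": retention_eval(trained, curriculum, vocab),
            })
    return pd.DataFrame.from_records(rows)


def sweep_summary(sweep: pd.DataFrame) -> pd.DataFrame:
    """Seed-averaged means per ablation level, sorted by ``p_a``."""
    return (sweep.groupby("p_a")
            [["few_shot_accuracy", "steps_to_criterion",
              "cumulative_loss", "retention_accuracy"]]
            .mean().reset_index().sort_values("p_a"))


# ---------------------------------------------------------------------------
# curriculum statistics


def curriculum_effects_test(
    reports: pd.DataFrame,
    value: str = "accuracy",
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Two-way ANOVA (curriculum x rotation) across per-seed accuracies,
    with a permutation cross-check of the interaction.

    ``reports`` needs columns ``curriculum``, ``rotation`` and ``value``.
    Returns an effects table with F statistics, parametric p-values, effect
    directions, and (for the interaction) a Freedman-Lane permutation p.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for col in ("curriculum", "rotation", value):
        if col not in reports.columns:
            raise ValueError(f"reports is missing column {col!r}")
    counts = reports.groupby(["curriculum", "rotation"]).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("need >= 2 observations in each of the 4 design cells")

    df = reports.rename(columns={value: "y"})
    fit = ols("y ~ C(curriculum) * C(rotation)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    means = df.groupby(["curriculum", "rotation"])["y"].mean()
    blocked_minus_inter = {
        rot: float(means["blocked", rot] - means["interleaved", rot])
        for rot in means.index.get_level_values("rotation").unique()
    }

    perm_p = _interaction_permutation_p(df, n_permutations, rng)

    rows = []
    for effect, row in table.iterrows():
        if effect == "Residual":
            continue
        f_stat, p = float(row["F"]), float(row["PR(>F)"])
        if float(row["sum_sq"]) < 1e-18:  # degenerate: no effect variance
            f_stat, p = 0.0, 1.0
        rec = {
            "effect": effect,
            "F": f_stat,
            "p_parametric": p,
        }
        if ":" in effect:
            rec["p_permutation"] = perm_p
        rows.append(rec)
    out = pd.DataFrame.from_records(rows)
    out.attrs["cell_means"] = means.to_dict()
    out.attrs["blocked_minus_interleaved"] = blocked_minus_inter
    return out


def _interaction_statistic(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """|difference of differences| of cell means for two 2-level factors."""
    m = {}
    for ai in (0, 1):
        for bi in (0, 1):
            m[ai, bi] = y[(a == ai) & (b == bi)].mean()
    return abs((m[0, 0] - m[0, 1]) - (m[1, 0] - m[1, 1]))


def _interaction_permutation_p(df: pd.DataFrame, n_permutations: int,
                               rng: np.random.Generator | None) -> float:
    """Freedman-Lane permutation test of the interaction term: permute the
    residuals of the main-effects-only model and re-add its fitted values."""
    rng = rng or np.random.default_rng(0)
    a = (df["curriculum"].to_numpy() == df["curriculum"].iloc[0]).astype(int)
    b = (df["rotation"].to_numpy() == df["rotation"].iloc[0]).astype(int)
    y = df["y"].to_numpy(dtype=float)

    x = np.column_stack([np.ones_like(y), a, b])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    resid = y - fitted

    observed = _interaction_statistic(y, a, b)
    hits = 1
    for _ in range(n_permutations):
        y_star = fitted + resid[rng.permutation(len(resid))]
        if _interaction_statistic(y_star, a, b) >= observed - 1e-15:
            hits += 1
    return hits / (n_permutations + 1)


def effects_table_to_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def plot_tradeoff(sweep: pd.DataFrame, path=None):
    """Four-panel ablation-sweep figure (few-shot, speed, loss, retention)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = sweep_summary(sweep)
    metrics = [
        ("few_shot_accuracy", "few-shot accuracy"),
        ("steps_to_criterion", "steps to criterion"),
        ("cumulative_loss", "cumulative loss"),
        ("retention_accuracy", "retention accuracy"),
    ]
    fig, axes = plt.subplots(1, 4, figsize=(14, 3))
    for ax, (col, label) in zip(axes, metrics):
        ax.plot(summary["p_a"], summary[col], marker="o")
        ax.set_xlabel("$p_a$")
        ax.set_ylabel(label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
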