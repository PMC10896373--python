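"""Reproducible experiment presets, configuration validation, and the CLI.

Presets tie the stages together: from-scratch finetuning grids (IWL-only),
metalearned few-shot grids (ICL-only), finetuning of metalearned models
(ICL+IWL), and the attention-ablation tradeoff sweep.  Every preset's
outputs are fully determined by (preset, scale, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import click
import numpy as np
import pandas as pd
import yaml

from iclsim import __version__
from iclsim import category_tasks as ct
from iclsim.encoding import build_vocab
from iclsim.evaluation import (
    DEFAULT_P_GRID,
    curriculum_effects_test,
    sweep_summary,
    tradeoff_sweep,
)
from iclsim.model import AblationSpec, ModelConfig, init_model, save_checkpoint
from iclsim.training import (
    FinetuneConfig,
    MetaTrainConfig,
    few_shot_eval,
    finetune_task,
    make_task_curriculum,
    metalearn,
    sample_tasks,
    save_trajectory_csv,
)

Scale = Literal["full", "desk"]

PRESETS = (
    "cat_iwl", "cat_icl", "cat_full",
    "grid_iwl", "grid_icl", "grid_full",
    "tradeoff_sweep", "smoke",
)

# Reference-scale settings (the values used in the original experiments).
FULL_SCALE = {
    "category": {
        "model": dict(n_layers=4, n_heads=8, hidden_size=64,
                      max_sequence_length=128, dropout=0.0),
        "meta": dict(n_train_tasks=12_000, n_val_tasks=100, n_test_tasks=10,
                     epochs=20, learning_rate=1e-4, batch_size=256),
        "finetune": dict(learning_rate=1e-5, steps_per_block=10,
                         n_block_alternations=10),
        "n_seeds": 10,
    },
    "compositional": {
        "model": dict(n_layers=12, n_heads=8, hidden_size=64,
                      max_sequence_length=64, dropout=0.1),
        "meta": dict(n_train_tasks=12_000, n_val_tasks=100, n_test_tasks=10,
                     epochs=500, learning_rate=1e-3, batch_size=256),
        "finetune": dict(learning_rate=1e-4, steps_per_block=10,
                         n_block_alternations=10),
        "n_seeds": 10,
    },
}

# Reduced settings sized for one CPU; chosen so the qualitative phenomena
# (ICL emergence, curriculum effects, forgetting, tradeoff) hold.  The
# category feature pool shrinks from 200 to 30 dimensions: in-context
# retrieval organizes over the token inventory far faster, which is what
# makes desk-scale metalearning tractable without changing the task logic.
DESK_SCALE = {
    "category": {
        "pool_size": 30,
        "model": dict(n_layers=2, n_heads=8, hidden_size=64,
                      max_sequence_length=128, dropout=0.1),
        "meta": dict(n_train_tasks=6000, n_val_tasks=16, n_test_tasks=10,
                     epochs=55, learning_rate=1e-3, batch_size=32,
                     warmup_steps=200, adam_beta2=0.98,
                     val_queries_per_task=8, val_every=5),
        "finetune": dict(learning_rate=1e-3, steps_per_block=10,
                         n_block_alternations=5, eval_every=5),
        "n_seeds": 3,
    },
    "compositional": {
        "model": dict(n_layers=2, n_heads=8, hidden_size=64,
                      max_sequence_length=64, dropout=0.1),
        "meta": dict(n_train_tasks=10_000, n_val_tasks=20, n_test_tasks=10,
                     epochs=100, learning_rate=1e-3, batch_size=32,
                     warmup_steps=200, adam_beta2=0.98,
                     val_queries_per_task=8, val_every=10),
        "finetune": dict(learning_rate=1e-3, steps_per_block=10,
                         n_block_alternations=5, eval_every=5),
        "n_seeds": 3,
    },
}

CONDITIONS = [
    (task_cond, cur)
    for task_cond in ("rule_like", "rotated")
    for cur in ("blocked", "interleaved")
]


def resolve_scale(family: str, scale: Scale) -> dict:
    table = FULL_SCALE if scale == "full" else DESK_SCALE
    return json.loads(json.dumps(table[family]))  # deep copy


# ---------------------------------------------------------------------------
# config validation


_SCHEMA = {
    "family": {"category", "compositional"},
    "model": set(ModelConfig.__dataclass_fields__) - {"d_v"},
    "meta": set(MetaTrainConfig.__dataclass_fields__) - {"family"},
    "finetune": set(FinetuneConfig.__dataclass_fields__) - {"family"},
    "ablation": {"p_a", "mode"},
    "n_seeds": None,
    "pool_size": None,
    "values_per_dim": None,
}


def validate_config(raw: dict) -> dict:
    """Fill defaults and reject unknown keys / inconsistent values.

    An empty config resolves to the full reference-scale category settings
    (e.g. metalearning rate 1e-4).  Raises ``ValueError`` naming every
    offending key.
    """
    if raw is None:
        raw = {}
    bad = [k for k in raw if k not in _SCHEMA]
    for section in ("model", "meta", "finetune", "ablation"):
        sub = raw.get(section) or {}
        if not isinstance(sub, dict):
            bad.append(section)
            continue
        bad.extend(f"{section}.{k}" for k in sub if k not in _SCHEMA[section])
    if bad:
        raise ValueError(f"unknown config keys: {', '.join(sorted(bad))}")

    family = raw.get("family", "category")
    if family not in ("category", "compositional"):
        raise ValueError(f"unknown family {family!r}")
    resolved = resolve_scale(family, "full")
    resolved["family"] = family
    for section in ("model", "meta", "finetune"):
        resolved[section].update(raw.get(section) or {})
    resolved["n_seeds"] = raw.get("n_seeds", resolved["n_seeds"])
    resolved["pool_size"] = raw.get("pool_size", 200)
    resolved["values_per_dim"] = raw.get("values_per_dim", 8)
    if raw.get("ablation"):
        resolved["ablation"] = dict(raw["ablation"])
        AblationSpec(**resolved["ablation"])  # range/mode check
    if resolved["finetune"].get("freeze_weights"):
        raise ValueError("freeze_weights contradicts finetuning")
    # instantiate to trigger dataclass validation
    MetaTrainConfig(family=family, **{
        k: v for k, v in resolved["meta"].items()})
    FinetuneConfig(family=family, **resolved["finetune"])
    return resolved


# ---------------------------------------------------------------------------
# manifest


@dataclass
class ExperimentManifest:
    preset: str
    scale: str
    seed: int
    config: dict
    content_hash: str
    outputs: list[str]
    runtime_s: float
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _content_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    src = Path(__file__).parent
    h = hashlib.sha256(blob)
    for f in sorted(src.glob("*.py")):
        h.update(f.read_bytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage helpers


def _space(settings: dict) -> ct.FeatureSpace:
    return ct.FeatureSpace(
        pool_size=settings.get("pool_size", 200),
        values_per_dim=settings.get("values_per_dim", 8),
    )


def _model_config(settings: dict, family: str, d_v: int, seed: int) -> ModelConfig:
    return ModelConfig(d_v=d_v, seed=seed, **settings["model"])


def run_metalearn(family: str, settings: dict, seed: int, progress=False):
    space = _space(settings) if family == "category" else None
    vocab = build_vocab(family, space)
    mc = _model_config(settings, family, vocab.d_v, seed)
    meta = MetaTrainConfig(family=family, **settings["meta"])
    rng = np.random.default_rng(seed)
    state, report, bundle = metalearn(mc, meta, rng, space=space, vocab=vocab,
                                      progress=progress)
    return state, report, bundle, vocab, space


def finetune_grid(
    family: str,
    settings: dict,
    seed: int,
    state_factory,
    vocab,
    space,
    exclude_keys=None,
):
    """Run the 2x2 (rotation x curriculum) finetuning grid across seeds.

    ``state_factory(seed)`` supplies the starting model (fresh random for
    IWL-only runs, the metalearned checkpoint for ICL+IWL runs).
    Returns (per-run summary frame, trajectories dict).
    """
    rows = []
    trajectories = {}
    for seed_i in range(settings["n_seeds"]):
        run_seed = seed + 1000 * seed_i
        for task_cond, cur_cond in CONDITIONS:
            rng = np.random.default_rng([run_seed, hash((task_cond, cur_cond)) % 2**31])
            tasks, _ = sample_tasks(family, task_cond, 1, rng, space,
                                    exclude=exclude_keys)
            curriculum = make_task_curriculum(tasks[0], cur_cond, rng)
            cfg = FinetuneConfig(
                family=family, **settings["finetune"]
            ).with_condition(cur_cond)
            trajectory, _ = finetune_task(
                state_factory(run_seed), curriculum, cfg, vocab, rng)
            final = trajectory.dropna(subset=["acc_study"]).iloc[-1]
            n_study = {"category": 32, "compositional": 9}[family]
            n_total = {"category": 64, "compositional": 25}[family]
            overall = (
                final["acc_study"] * n_study
                + final["acc_test"] * (n_total - n_study)
            ) / n_total
            rows.append({
                "seed": seed_i,
                "rotation": task_cond,
                "curriculum": cur_cond,
                "accuracy_study": float(final["acc_study"]),
                "accuracy_test": float(final["acc_test"]),
                "accuracy": float(overall),
                "cumulative_loss": float(final["cumulative_loss"]),
            })
            trajectories[(seed_i, task_cond, cur_cond)] = trajectory
    return pd.DataFrame.from_records(rows), trajectories


def fewshot_grid(family, settings, seed, state, vocab, space, exclude_keys,
                 n_tasks=10):
    rows = []
    for task_cond, cur_cond in CONDITIONS:
        rng = np.random.default_rng([seed, hash((task_cond, cur_cond)) % 2**31])
        tasks, _ = sample_tasks(family, task_cond, n_tasks, rng, space,
                                exclude=exclude_keys)
        report = few_shot_eval(state, tasks, cur_cond, vocab, rng)
        rows.append({
            "rotation": task_cond,
            "curriculum": cur_cond,
            "accuracy": report.accuracy,
            "accuracy_study": report.accuracy_study,
            "accuracy_heldout": report.accuracy_heldout,
            "chance": report.chance,
        })
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# presets


def run_preset(name: str, scale: Scale, seed: int, outdir) -> ExperimentManifest:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    family = "compositional" if name.startswith(("grid", "tradeoff")) else "category"
    settings = resolve_scale(family, scale)
    outputs: list[str] = []

    def save_df(df: pd.DataFrame, fname: str):
        path = outdir / fname
        df.to_csv(path, index=False)
        outputs.append(str(path))

    if name == "smoke":
        _run_smoke(seed, outdir, outputs)
    elif name.endswith("_iwl"):
        space = _space(settings) if family == "category" else None
        vocab = build_vocab(family, space)
        mc = _model_config(settings, family, vocab.d_v, seed)
        summary, trajectories = finetune_grid(
            family, settings, seed,
            lambda s: init_model(ModelConfig(**{**mc.to_dict(), "seed": s})),
            vocab, space)
        save_df(summary, "final_accuracy.csv")
        for key, tr in trajectories.items():
            save_trajectory_csv(tr, outdir / f"trajectory_{key[0]}_{key[1]}_{key[2]}.csv")
        effects = curriculum_effects_test(summary, value="accuracy_study")
        save_df(effects, "effects.csv")
    elif name.endswith("_icl"):
        state, report, bundle, vocab, space = run_metalearn(family, settings, seed)
        save_df(report, "metalearn_report.csv")
        save_checkpoint(state, outdir / "checkpoint")
        grid = fewshot_grid(family, settings, seed, state, vocab, space,
                            bundle["train_keys"])
        save_df(grid, "few_shot.csv")
    elif name.endswith("_full"):
        state, report, bundle, vocab, space = run_metalearn(family, settings, seed)
        save_df(report, "metalearn_report.csv")
        summary, trajectories = finetune_grid(
            family, settings, seed, lambda s: state, vocab, space,
            exclude_keys=bundle["train_keys"])
        save_df(summary, "final_accuracy.csv")
        for key, tr in trajectories.items():
            save_trajectory_csv(tr, outdir / f"trajectory_{key[0]}_{key[1]}_{key[2]}.csv")
        effects = curriculum_effects_test(summary, value="accuracy")
        save_df(effects, "effects.csv")
    elif name == "tradeoff_sweep":
        state, report, bundle, vocab, space = run_metalearn(family, settings, seed)
        save_df(report, "metalearn_report.csv")
        rng = np.random.default_rng(seed + 1)
        tasks, _ = sample_tasks(family, "rule_like", 5, rng, space,
                                exclude=bundle["train_keys"])
        cfg = FinetuneConfig(
            family=family, **settings["finetune"]
        ).with_condition("interleaved")
        sweep = tradeoff_sweep(state, tasks, cfg, vocab, rng,
                               p_a_grid=DEFAULT_P_GRID,
                               n_seeds=settings["n_seeds"])
        save_df(sweep, "sweep.csv")
        save_df(sweep_summary(sweep), "sweep_summary.csv")

    config = {"family": family, **settings}
    manifest = ExperimentManifest(
        preset=name, scale=scale, seed=seed, config=config,
        content_hash=_content_hash(config), outputs=sorted(outputs),
        runtime_s=round(time.time() - t0, 2),
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def _run_smoke(seed: int, outdir: Path, outputs: list[str]) -> None:
    """End-to-end self-test across every module at toy scale (< 5 min)."""
    from iclsim import grid_tasks as gt
    from iclsim.encoding import encode_episode
    from iclsim.model import greedy_decode, make_batch

    rng = np.random.default_rng(seed)
    space = ct.FeatureSpace()
    results = {}

    for cond in ("rule_like", "rotated"):
        task = ct.sample_category_task(space, cond, rng)
        assert len(task.items) == 64 and len(task.study_items) == 32
        labels = [task.label_of(it) for it in task.items]
        assert sum(labels) == 32
        gtask = gt.sample_grid_task(cond, rng)
        cur = gt.make_grid_curriculum(gtask, "blocked", rng)
        assert len(cur.study) == 9 and len(cur.test) == 16
    results["task_invariants"] = "ok"

    vocab = build_vocab("compositional")
    gtask = gt.sample_grid_task("rule_like", rng)
    cur = gt.make_grid_curriculum(gtask, "interleaved", rng)
    mc = ModelConfig(d_v=vocab.d_v, n_layers=2, n_heads=4, hidden_size=32,
                     max_sequence_length=64, seed=seed)
    state = init_model(mc)
    eps = [encode_episode(cur, q, vocab) for q in gtask.cues]
    preds = greedy_decode(state, eps)
    assert preds.shape == (25, 2)
    cfg = FinetuneConfig.compositional(
        learning_rate=3e-3, steps_per_block=5, n_block_alternations=2)
    trajectory, trained = finetune_task(state, make_task_curriculum(
        gtask, "blocked", rng), cfg, vocab, rng)
    results["finetune_steps"] = int(trajectory["step"].iloc[-1]) + 1
    (outdir / "smoke.json").write_text(json.dumps(results))
    outputs.append(str(outdir / "smoke.json"))


# ---------------------------------------------------------------------------
# CLI


@click.group()
def main():
    """Curriculum-effects and ICL/IWL-interplay simulations."""


@main.command()
@click.option("--family", type=click.Choice(["category", "compositional"]),
              required=True)
@click.option("--condition", type=click.Choice(["rule_like", "rotated"]),
              default="rule_like")
@click.option("--n", default=10, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def generate(family, condition, n, seed, out):
    """Sample tasks and write them as JSONL."""
    rng = np.random.default_rng(seed)
    tasks, _ = sample_tasks(family, condition, n, rng,
                            ct.FeatureSpace() if family == "category" else None)
    with open(out, "w") as fh:
        for t in tasks:
            fh.write(t.to_json() + "\n")
    click.echo(f"wrote {n} {family}/{condition} tasks to {out}")


@main.command("metalearn")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--scale", type=click.Choice(["full", "desk"]), default="desk")
@click.option("--family", type=click.Choice(["category", "compositional"]),
              default="category")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def metalearn_cmd(config_path, scale, family, seed, out):
    """Metalearn a model and save the best-validation checkpoint."""
    if config_path:
        resolved = validate_config(yaml.safe_load(Path(config_path).read_text()))
        family = resolved["family"]
        settings = resolved
    else:
        settings = resolve_scale(family, scale)
    state, report, bundle, vocab, space = run_metalearn(
        family, settings, seed, progress=True)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    save_checkpoint(state, outdir / "checkpoint")
    report.to_csv(outdir / "metalearn_report.csv", index=False)
    click.echo(f"best val acc: {report['val_acc'].max():.3f}")


@main.command("finetune")
@click.option("--checkpoint", type=click.Path(), required=True,
              help="checkpoint path prefix (from `iclsim metalearn`)")
@click.option("--family", type=click.Choice(["category", "compositional"]),
              required=True)
@click.option("--condition", type=click.Choice(["rule_like", "rotated"]),
              default="rule_like")
@click.option("--curriculum", type=click.Choice(["blocked", "interleaved"]),
              default="blocked")
@click.option("--scale", type=click.Choice(["full", "desk"]), default="desk")
@click.option("--p-a", default=0.0, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def finetune_cmd(checkpoint, family, condition, curriculum, scale, p_a, seed, out):
    """Finetune a checkpoint on one freshly sampled task."""
    from iclsim.model import load_checkpoint

    state = load_checkpoint(checkpoint)
    settings = resolve_scale(family, scale)
    space = _space(settings) if family == "category" else None
    vocab = build_vocab(family, space)
    rng = np.random.default_rng(seed)
    tasks, _ = sample_tasks(family, condition, 1, rng, space)
    cur = make_task_curriculum(tasks[0], curriculum, rng)
    cfg = FinetuneConfig(family=family, **settings["finetune"]
                         ).with_condition(curriculum)
    ablation = AblationSpec(p_a) if p_a > 0 else None
    trajectory, trained = finetune_task(state, cur, cfg, vocab, rng,
                                        ablation=ablation)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    save_trajectory_csv(trajectory, outdir / "trajectory.csv")
    save_checkpoint(trained, outdir / "finetuned")
    final = trajectory.dropna(subset=["acc_study"]).iloc[-1]
    click.echo(f"final study acc {final['acc_study']:.3f}, "
               f"test acc {final['acc_test']:.3f}")


@main.command("eval")
@click.option("--checkpoint", type=click.Path(), required=True)
@click.option("--family", type=click.Choice(["category", "compositional"]),
              required=True)
@click.option("--condition", type=click.Choice(["rule_like", "rotated"]),
              default="rule_like")
@click.option("--curriculum", type=click.Choice(["blocked", "interleaved"]),
              default="blocked")
@click.option("--n-tasks", default=10, show_default=True)
@click.option("--p-a", default=0.0, show_default=True)
@click.option("--seed", default=0, show_default=True)
def eval_cmd(checkpoint, family, condition, curriculum, n_tasks, p_a, seed):
    """Frozen-weight few-shot evaluation on freshly sampled tasks."""
    from iclsim.model import load_checkpoint

    state = load_checkpoint(checkpoint)
    space = ct.FeatureSpace() if family == "category" else None
    vocab = build_vocab(family, space)
    rng = np.random.default_rng(seed)
    tasks, _ = sample_tasks(family, condition, n_tasks, rng, space)
    ablation = AblationSpec(p_a) if p_a > 0 else None
    report = few_shot_eval(state, tasks, curriculum, vocab, rng,
                           ablation=ablation)
    click.echo(report.to_json())


@main.command("sweep")
@click.option("--checkpoint", type=click.Path(), required=True)
@click.option("--family", type=click.Choice(["category", "compositional"]),
              default="compositional")
@click.option("--scale", type=click.Choice(["full", "desk"]), default="desk")
@click.option("--n-seeds", default=5, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def sweep_cmd(checkpoint, family, scale, n_seeds, seed, out):
    """Attention-ablation tradeoff sweep from a metalearned checkpoint."""
    from iclsim.model import load_checkpoint

    state = load_checkpoint(checkpoint)
    settings = resolve_scale(family, scale)
    space = _space(settings) if family == "category" else None
    vocab = build_vocab(family, space)
    rng = np.random.default_rng(seed)
    tasks, _ = sample_tasks(family, "rule_like", n_seeds, rng, space)
    cfg = FinetuneConfig(family=family, **settings["finetune"]
                         ).with_condition("interleaved")
    sweep = tradeoff_sweep(state, tasks, cfg, vocab, rng, n_seeds=n_seeds)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    sweep.to_csv(outdir / "sweep.csv", index=False)
    sweep_summary(sweep).to_csv(outdir / "sweep_summary.csv", index=False)
    click.echo(sweep_summary(sweep).to_string(index=False))


@main.command("run-preset")
@click.argument("name", type=click.Choice(PRESETS))
@click.option("--scale", type=click.Choice(["full", "desk"]), default="desk")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), default="results")
def run_preset_cmd(name, scale, seed, out):
    """Run a named experiment preset end to end."""
    manifest = run_preset(name, scale, seed, Path(out) / name)
    click.echo(json.dumps(asdict(manifest), indent=2)[:2000])


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True),
              required=True)
def validate(config_path):
    """Validate a YAML config and print the resolved settings."""
    resolved = validate_config(yaml.safe_load(Path(config_path).read_text()))
    click.echo(json.dumps(resolved, indent=2, sort_keys=True))


@main.command()
@click.option("--results", "results_path", type=click.Path(exists=True),
              required=True)
@click.option("--value", default="accuracy", show_default=True)
def stats(results_path, value):
    """Two-way ANOVA + permutation check on a finetune-grid summary CSV."""
    df = pd.read_csv(results_path)
    table = curriculum_effects_test(df, value=value)
    click.echo(table.to_string(index=False))


if __name__ == "__main__":
    main()
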