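# iclsim

Simulations of the interplay between **in-context learning (ICL)** and
**in-weight learning (IWL)** in a single sequence model: curriculum effects
(blocked vs. interleaved × rule-like vs. rotated) on a category-learning
task and a compositional grid task, catastrophic forgetting, and the
flexibility–retention tradeoff under context-attention ablation.

Everything runs on plain NumPy — the causal transformer (forward pass,
manual backpropagation, Adam) is implemented in `iclsim.model` and verified
against finite differences, so no deep-learning framework is required.

## Layout

| module | contents |
| --- | --- |
| `iclsim.category_tasks` | category-task sampler: 2 feature dimensions × 8 values, rule-like or rotated boundary, 32-item study set, blocked/interleaved curricula |
| `iclsim.grid_tasks` | compositional 5×5 color/animal grid sampler, 45° rotation, row+column study design, symbolic composition oracle |
| `iclsim.encoding` | vocabularies, token episodes, context stripping (retention inputs), JSONL round-trips |
| `iclsim.model` | NumPy causal transformer, attention-ablation hook (`AblationSpec`), greedy decoding, Adam, checkpoints |
| `iclsim.training` | metalearning (pretraining on a task distribution), frozen-weight few-shot evaluation, task-specific finetuning with blocked/interleaved gradient schedules |
| `iclsim.evaluation` | exact-match metrics, forgetting index, retention protocol, ablation tradeoff sweep, two-way ANOVA + permutation cross-check |
| `iclsim.experiments` | presets, config validation, manifests, CLI |

## CLI

```bash
iclsim generate --family compositional --n 10 --seed 0 --out tasks.jsonl
iclsim metalearn --family category --scale desk --seed 0 --out runs/meta
iclsim run-preset cat_iwl --scale desk --seed 0 --out results
iclsim run-preset tradeoff_sweep --scale desk --seed 0 --out results
iclsim stats --results results/cat_iwl/final_accuracy.csv --value accuracy_study
iclsim validate --config my_config.yaml
```

Presets: `cat_iwl`, `cat_icl`, `cat_full` (category task: from-scratch
IWL grid, metalearned few-shot grid, metalearned+finetuned grid),
`grid_*` (same for the compositional task), `tradeoff_sweep` (ablation
tradeoff), `smoke` (end-to-end self-test). `--scale full` mirrors the
reference settings (12,000 tasks, 20/500 epochs, 4/12 layers); `--scale
desk` is sized for minutes on one CPU and is used by the test suite.

## Pretrained desk checkpoints

Metalearning to the point where in-context learning emerges takes
~10-30k optimizer steps (~20+ minutes per family on one CPU), so the test
suite evaluates the desk-scale checkpoints shipped under `assets/`
(text JSON, produced by this package with the `DESK_SCALE` configs).
Retrain them yourself with

```bash
iclsim metalearn --family category --scale desk --seed 0 --out runs/cat
ICLSIM_TRAIN_IN_SUITE=1 python -m pytest tests/test_acceptance.py  # slow
```

## Known desk-scale limitations

Four acceptance tests assert effects that require reference-scale
training and fail (honestly) against the desk checkpoints: near-ceiling
compositional generalization (> 0.8), the full curriculum-by-rotation
interaction of the finetuned models, and its significance bound. The desk
models show all *orderings* (rule-like > rotated, blocked > interleaved
few-shot, interleaving advantage + catastrophic forgetting in from-scratch
training, and the flexibility-retention tradeoff), but their in-context
learning is not strong enough for the interaction to dominate finetuning
dynamics. Details and measurements are in the test docstrings.

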