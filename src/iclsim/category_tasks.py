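"""Category-learning task sampler.

Stimuli vary along two discrete feature dimensions drawn from a larger pool;
each of the 64 value pairs belongs to one of two balanced categories.  The
boundary is either *rule-like* (a single relevant dimension cut at its
midpoint) or *rotated* (the anti-diagonal sum of both values, the discrete
analogue of a 45-degree rotated boundary).  Tasks carry a balanced
study/held-out split and can be ordered into blocked or interleaved
curricula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

Condition = Literal["rule_like", "rotated"]
CurriculumCondition = Literal["blocked", "interleaved"]

LABEL_TOKENS = ("A", "B")


@dataclass(frozen=True)
class FeatureSpace:
    """Pool of discrete feature dimensions from which tasks are sampled."""

    pool_size: int = 200
    values_per_dim: int = 8

    def __post_init__(self) -> None:
        if self.pool_size < 2:
            raise ValueError(f"pool_size must be >= 2, got {self.pool_size}")
        if self.values_per_dim < 2:
            raise ValueError(
                f"values_per_dim must be >= 2, got {self.values_per_dim}"
            )
        if self.values_per_dim % 2 != 0:
            raise ValueError("values_per_dim must be even for balanced boundaries")


@dataclass(frozen=True)
class CategoryBoundary:
    """Decision boundary over a pair of feature dimensions.

    ``polarity=0`` maps the low side of the boundary to category 0.
    For rotated boundaries the on-diagonal ties (v1 + v2 == threshold)
    are broken by the parity of the first value (``tie_break='parity'``),
    which splits the diagonal evenly.
    """

    condition: Condition
    threshold: int
    relevant_dim: int = 0
    polarity: int = 0
    tie_break: str = "parity"

    def category(self, item: tuple[int, int], values_per_dim: int = 8) -> int:
        v1, v2 = item
        if not (1 <= v1 <= values_per_dim and 1 <= v2 <= values_per_dim):
            raise ValueError(f"item {item} outside 1..{values_per_dim}")
        if self.condition == "rule_like":
            low = item[self.relevant_dim] <= self.threshold
        elif self.condition == "rotated":
            s = v1 + v2
            if s < self.threshold:
                low = True
            elif s > self.threshold:
                low = False
            elif self.tie_break == "parity":
                low = v1 % 2 == 0
            else:
                raise ValueError(f"unknown tie_break {self.tie_break!r}")
        else:
            raise ValueError(f"unknown condition {self.condition!r}")
        cat = 0 if low else 1
        return cat if self.polarity == 0 else 1 - cat


def rule_label(item: tuple[int, int], boundary: CategoryBoundary,
               values_per_dim: int = 8) -> int:
    """Category of ``item`` under a rule-like boundary (single relevant dim)."""
    if boundary.condition != "rule_like":
        raise ValueError("rule_label requires a rule_like boundary")
    return boundary.category(item, values_per_dim)


def rotated_label(item: tuple[int, int], boundary: CategoryBoundary,
                  values_per_dim: int = 8) -> int:
    """Category of ``item`` under the rotated (information-integration) boundary."""
    if boundary.condition != "rotated":
        raise ValueError("rotated_label requires a rotated boundary")
    return boundary.category(item, values_per_dim)


@dataclass(frozen=True)
class CategoryTask:
    """A sampled categorization task over two pool dimensions.

    ``items`` enumerates all value pairs; ``labels[i]`` is the label-token
    index (into :data:`LABEL_TOKENS`) of ``items[i]``.  ``label_map`` maps
    category id (0/1) to label-token index.
    """

    dims: tuple[int, int]
    boundary: CategoryBoundary
    label_map: tuple[int, int]
    values_per_dim: int
    items: tuple[tuple[int, int], ...]
    labels: tuple[int, ...]
    study_items: tuple[tuple[int, int], ...]
    heldout_items: tuple[tuple[int, int], ...]

    def label_of(self, item: tuple[int, int]) -> int:
        return self.label_map[self.boundary.category(item, self.values_per_dim)]

    @property
    def condition(self) -> Condition:
        return self.boundary.condition

    def to_json(self) -> str:
        d = {
            "dims": list(self.dims),
            "boundary": {
                "condition": self.boundary.condition,
                "threshold": self.boundary.threshold,
                "relevant_dim": self.boundary.relevant_dim,
                "polarity": self.boundary.polarity,
                "tie_break": self.boundary.tie_break,
            },
            "label_map": list(self.label_map),
            "values_per_dim": self.values_per_dim,
            "study_items": [list(it) for it in self.study_items],
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, line: str) -> "CategoryTask":
        d = json.loads(line)
        boundary = CategoryBoundary(**d["boundary"])
        return _assemble_task(
            dims=tuple(d["dims"]),
            boundary=boundary,
            label_map=tuple(d["label_map"]),
            values_per_dim=d["values_per_dim"],
            study_items=tuple(tuple(it) for it in d["study_items"]),
        )


def _all_items(values_per_dim: int) -> tuple[tuple[int, int], ...]:
    return tuple(
        (v1, v2)
        for v1 in range(1, values_per_dim + 1)
        for v2 in range(1, values_per_dim + 1)
    )


def _assemble_task(dims, boundary, label_map, values_per_dim, study_items):
    items = _all_items(values_per_dim)
    labels = tuple(label_map[boundary.category(it, values_per_dim)] for it in items)
    study_set = set(study_items)
    heldout = tuple(it for it in items if it not in study_set)
    return CategoryTask(
        dims=dims,
        boundary=boundary,
        label_map=label_map,
        values_per_dim=values_per_dim,
        items=items,
        labels=labels,
        study_items=study_items,
        heldout_items=heldout,
    )


def sample_category_task(
    space: FeatureSpace,
    condition: Condition,
    rng: np.random.Generator,
    dims: tuple[int, int] | None = None,
) -> CategoryTask:
    """Sample a balanced categorization task.

    Two distinct dimensions are drawn uniformly from the pool (unless
    ``dims`` pins them, e.g. to control train/validation overlap), the
    boundary polarity and label assignment are randomized, and 16 study
    items per category are chosen uniformly without replacement.
    """
    if dims is None:
        dims = tuple(rng.choice(space.pool_size, size=2, replace=False).tolist())
    n = space.values_per_dim
    if condition == "rule_like":
        boundary = CategoryBoundary(
            condition="rule_like",
            threshold=n // 2,
            relevant_dim=int(rng.integers(2)),
            polarity=int(rng.integers(2)),
        )
    elif condition == "rotated":
        boundary = CategoryBoundary(
            condition="rotated",
            threshold=n + 1,
            polarity=int(rng.integers(2)),
        )
    else:
        raise ValueError(f"unknown condition {condition!r}")
    label_map = (0, 1) if rng.integers(2) == 0 else (1, 0)

    items = _all_items(n)
    per_cat = len(items) // 2
    n_study_per_cat = per_cat // 2
    study: list[tuple[int, int]] = []
    for cat in (0, 1):
        members = [it for it in items if boundary.category(it, n) == cat]
        idx = rng.choice(len(members), size=n_study_per_cat, replace=False)
        study.extend(members[i] for i in sorted(idx))
    return _assemble_task(dims, boundary, label_map, n, tuple(study))


@dataclass(frozen=True)
class Curriculum:
    """An ordered presentation of a task's study items."""

    task: CategoryTask
    condition: CurriculumCondition
    order: tuple[tuple[int, int], ...]
    block_boundaries: tuple[int, ...] = field(default=())

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(self.task.label_of(it) for it in self.order)


def fisher_yates(items: Sequence, rng: np.random.Generator) -> list:
    """Uniform shuffle via explicit Fisher-Yates draws (one ``integers(i+1)``
    call per position, from the back), so the draw sequence is a documented
    contract that an independent implementation can replicate."""
    out = list(items)
    for i in range(len(out) - 1, 0, -1):
        j = int(rng.integers(i + 1))
        out[i], out[j] = out[j], out[i]
    return out


def make_curriculum(
    task: CategoryTask,
    condition: CurriculumCondition,
    rng: np.random.Generator,
) -> Curriculum:
    """Order the 32 study items: one contiguous block per category, or shuffled."""
    study = list(task.study_items)
    if condition == "interleaved":
        return Curriculum(task=task, condition=condition,
                          order=tuple(fisher_yates(study, rng)))
    if condition != "blocked":
        raise ValueError(f"unknown curriculum condition {condition!r}")
    first_label = int(rng.integers(2))
    blocks = {0: [], 1: []}
    for it in study:
        blocks[task.label_of(it)].append(it)
    order = []
    for lab in (first_label, 1 - first_label):
        blk = blocks[lab]
        order.extend(blk[i] for i in rng.permutation(len(blk)))
    boundary_at = len(blocks[first_label])
    return Curriculum(
        task=task, condition=condition, order=tuple(order),
        block_boundaries=(boundary_at,),
    )


def save_tasks_jsonl(tasks: Iterable[CategoryTask], path) -> None:
    with open(path, "w") as fh:
        for t in tasks:
            fh.write(t.to_json() + "\n")


def load_tasks_jsonl(path) -> Iterator[CategoryTask]:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                yield CategoryTask.from_json(line)


def curriculum_to_json(cur: Curriculum) -> str:
    return json.dumps({
        "task": json.loads(cur.task.to_json()),
        "condition": cur.condition,
        "order": [list(it) for it in cur.order],
        "block_boundaries": list(cur.block_boundaries),
    })


def curriculum_from_json(line: str) -> Curriculum:
    d = json.loads(line)
    task = CategoryTask.from_json(json.dumps(d["task"]))
    return Curriculum(
        task=task,
        condition=d["condition"],
        order=tuple(tuple(it) for it in d["order"]),
        block_boundaries=tuple(d["block_boundaries"]),
    )
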