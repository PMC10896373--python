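"""Compositional grid task sampler.

Each task maps the 25 color/animal cue combinations onto a 5x5 integer
coordinate grid.  In the rule-like condition one feature determines x and
the other determines y; the rotated condition applies a 45-degree rotation
with integer rescaling, so both features jointly determine both output
coordinates.  Study curricula always cover one full row plus one full
column (9 unique cues), leaving 16 cues for the generalization test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator, Literal

import numpy as np

COLORS = ("red", "blue", "green", "yellow", "purple")
ANIMALS = ("alligator", "elephant", "giraffe", "penguin", "zebra")
GRID_SIZE = 5

Condition = Literal["rule_like", "rotated"]
CurriculumCondition = Literal["blocked", "interleaved"]
Cue = tuple[str, str]


def rotate_grid(locations: dict[Cue, tuple[int, int]]) -> dict[Cue, tuple[int, int]]:
    """45-degree rotation with integer rescaling: (x, y) -> (x - y + 4, x + y).

    The offset keeps every coordinate a non-negative integer; pairwise
    Euclidean distances are scaled by sqrt(2).
    """
    coords = set(locations.values())
    expected = {(x, y) for x in range(GRID_SIZE) for y in range(GRID_SIZE)}
    if coords != expected:
        raise ValueError("rotate_grid expects a full 0-based 5x5 grid")
    return {
        cue: (x - y + GRID_SIZE - 1, x + y) for cue, (x, y) in locations.items()
    }


def unrotate_grid(locations: dict[Cue, tuple[int, int]]) -> dict[Cue, tuple[int, int]]:
    """Inverse of :func:`rotate_grid`."""
    out = {}
    for cue, (u, v) in locations.items():
        x2 = u + v - (GRID_SIZE - 1)
        y2 = v - u + (GRID_SIZE - 1)
        if x2 % 2 or y2 % 2:
            raise ValueError(f"{(u, v)} is not in the image of the rotation")
        out[cue] = (x2 // 2, y2 // 2)
    return out


@dataclass(frozen=True)
class GridTask:
    """A sampled cue -> location mapping over the 5x5 grid."""

    color_order: tuple[str, ...]
    animal_order: tuple[str, ...]
    color_is_x: bool
    rotated: bool
    locations: dict[Cue, tuple[int, int]]

    @property
    def condition(self) -> Condition:
        return "rotated" if self.rotated else "rule_like"

    @property
    def cues(self) -> tuple[Cue, ...]:
        return tuple((c, a) for c in COLORS for a in ANIMALS)

    def to_json(self) -> str:
        return json.dumps({
            "color_order": list(self.color_order),
            "animal_order": list(self.animal_order),
            "color_is_x": self.color_is_x,
            "rotated": self.rotated,
        })

    @classmethod
    def from_json(cls, line: str) -> "GridTask":
        d = json.loads(line)
        return _assemble_grid(
            tuple(d["color_order"]), tuple(d["animal_order"]),
            d["color_is_x"], d["rotated"],
        )


def _assemble_grid(color_order, animal_order, color_is_x, rotated) -> GridTask:
    locations: dict[Cue, tuple[int, int]] = {}
    for ci, color in enumerate(color_order):
        for ai, animal in enumerate(animal_order):
            locations[(color, animal)] = (ci, ai) if color_is_x else (ai, ci)
    if rotated:
        locations = rotate_grid(locations)
    return GridTask(
        color_order=tuple(color_order),
        animal_order=tuple(animal_order),
        color_is_x=color_is_x,
        rotated=rotated,
        locations=locations,
    )


def sample_grid_task(condition: Condition, rng: np.random.Generator) -> GridTask:
    """Shuffle both feature orders, randomize the axis assignment, and
    (optionally) rotate the resulting grid."""
    if condition not in ("rule_like", "rotated"):
        raise ValueError(f"unknown condition {condition!r}")
    color_order = tuple(np.array(COLORS)[rng.permutation(GRID_SIZE)].tolist())
    animal_order = tuple(np.array(ANIMALS)[rng.permutation(GRID_SIZE)].tolist())
    color_is_x = bool(rng.integers(2))
    return _assemble_grid(color_order, animal_order, color_is_x,
                          condition == "rotated")


@dataclass(frozen=True)
class GridCurriculum:
    """Row-plus-column study design over one grid task.

    ``study`` is the ordered presentation of the 9 unique study cues; the
    row/column intersection cue appears once, inside the first block in the
    blocked condition.  ``group_of`` tags each study cue with the block it
    belongs to ('row' or 'column'; the intersection joins the first block).
    """

    task: GridTask
    condition: CurriculumCondition
    row_animal: str
    column_color: str
    block_order: tuple[str, str]
    study: tuple[Cue, ...]
    group_of: dict[Cue, str]

    @property
    def test(self) -> tuple[Cue, ...]:
        studied = set(self.study)
        return tuple(c for c in self.task.cues if c not in studied)

    @property
    def groups(self) -> tuple[str, str]:
        return self.block_order


def make_grid_curriculum(
    task: GridTask,
    condition: CurriculumCondition,
    rng: np.random.Generator,
) -> GridCurriculum:
    """Choose one full row and one full column of cues and order them.

    In the blocked condition one complete feature group (5 cues, including
    the intersection) precedes the other group's remaining 4 cues; in the
    interleaved condition the same 9 cues are uniformly shuffled.
    """
    row_animal = ANIMALS[int(rng.integers(GRID_SIZE))]
    column_color = COLORS[int(rng.integers(GRID_SIZE))]
    row = [(c, row_animal) for c in COLORS]  # varies color, fixed animal
    column = [(column_color, a) for a in ANIMALS]  # fixed color, varies animal
    intersection = (column_color, row_animal)

    row_first = bool(rng.integers(2))
    block_order = ("row", "column") if row_first else ("column", "row")
    first, second = (row, column) if row_first else (column, row)
    second = [cue for cue in second if cue != intersection]

    group_of = {cue: block_order[0] for cue in first}
    group_of.update({cue: block_order[1] for cue in second})

    first = [first[i] for i in rng.permutation(len(first))]
    second = [second[i] for i in rng.permutation(len(second))]
    study = first + second
    if condition == "interleaved":
        study = [study[i] for i in rng.permutation(len(study))]
    elif condition != "blocked":
        raise ValueError(f"unknown curriculum condition {condition!r}")

    return GridCurriculum(
        task=task,
        condition=condition,
        row_animal=row_animal,
        column_color=column_color,
        block_order=block_order,
        study=tuple(study),
        group_of=group_of,
    )


def compositional_answer(
    study: Iterable[tuple[Cue, tuple[int, int]]],
    query: Cue,
) -> tuple[int, int]:
    """Symbolic oracle: compose the query location from study examples.

    Infers which axis each feature controls from the study set (all cues
    sharing a color must share one coordinate), then combines the
    color-matched coordinate with the animal-matched coordinate.  Raises if
    the study set is inconsistent with a per-feature coordinate rule (e.g.
    a rotated task) or if the query's features are not covered.
    """
    study = list(study)
    qc, qa = query
    color_matches = [(cue, loc) for cue, loc in study if cue[0] == qc]
    animal_matches = [(cue, loc) for cue, loc in study if cue[1] == qa]
    if not color_matches or not animal_matches:
        raise ValueError(f"query {query} not covered by the study set")

    for color_is_x in (True, False):
        cx = 0 if color_is_x else 1
        ax = 1 - cx
        by_color: dict[str, int] = {}
        by_animal: dict[str, int] = {}
        ok = True
        for (c, a), loc in study:
            if by_color.setdefault(c, loc[cx]) != loc[cx]:
                ok = False
                break
            if by_animal.setdefault(a, loc[ax]) != loc[ax]:
                ok = False
                break
        if ok:
            answer = [0, 0]
            answer[cx] = by_color[qc]
            answer[ax] = by_animal[qa]
            return tuple(answer)
    raise ValueError(
        "study set admits no per-feature coordinate rule (rotated task?)"
    )


def save_grid_tasks_jsonl(tasks: Iterable[GridTask], path) -> None:
    with open(path, "w") as fh:
        for t in tasks:
            fh.write(t.to_json() + "\n")


def load_grid_tasks_jsonl(path) -> Iterator[GridTask]:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                yield GridTask.from_json(line)


def render_curriculum(cur: GridCurriculum) -> str:
    """Human-readable rendering of a study sequence plus test cues."""
    lines = ["# study"]
    for color, animal in cur.study:
        x, y = cur.task.locations[(color, animal)]
        lines.append(f"{color} {animal} -> x={x} y={y}")
    lines.append("# test")
    for color, animal in cur.test:
        lines.append(f"{color} {animal} -> ?")
    return "\n".join(lines)
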