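"""Token-level episode encoding.

An episode is the unit consumed by the sequence model: an ordered run of
study examples, a query-marker token, the query's feature tokens, and the
withheld answer tokens.  Category episodes use 3 tokens per study example
(two feature values + label) and a 1-token answer; grid episodes use 4
tokens per study example (color, animal, x, y) and a 2-token answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from iclsim.category_tasks import LABEL_TOKENS, Curriculum, FeatureSpace
from iclsim.grid_tasks import ANIMALS, COLORS, GRID_SIZE, Cue, GridCurriculum

QUERY_TOKEN = "<q>"
PAD_TOKEN = "<pad>"


class Vocabulary:
    """Dense token <-> id table partitioned into disjoint token classes."""

    def __init__(self, classes: dict[str, Sequence[str]]):
        self.classes = {name: tuple(toks) for name, toks in classes.items()}
        self.tokens: list[str] = []
        seen: set[str] = set()
        for name, toks in self.classes.items():
            for t in toks:
                if t in seen:
                    raise ValueError(f"token {t!r} appears in two classes")
                seen.add(t)
                self.tokens.append(t)
        self.id_of = {t: i for i, t in enumerate(self.tokens)}

    @property
    def d_v(self) -> int:
        return len(self.tokens)

    @property
    def chance(self) -> float:
        return 1.0 / self.d_v

    def __getitem__(self, token: str) -> int:
        try:
            return self.id_of[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    def decode(self, token_id: int) -> str:
        return self.tokens[token_id]

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self[t] for t in tokens], dtype=np.int64)

    def class_of(self, token: str) -> str:
        for name, toks in self.classes.items():
            if token in toks:
                return name
        raise KeyError(token)


def build_vocab(task_family: Literal["category", "compositional"],
                space: FeatureSpace | None = None) -> Vocabulary:
    """Deterministic vocabulary for a task family.

    The category vocabulary covers every (dimension, value) pair in the
    pool, so held-out metalearning tasks never introduce new tokens.  Grid
    coordinate tokens cover both the unrotated (0..4) and rotated (0..8)
    ranges and are shared between the x and y roles.
    """
    if task_family == "category":
        space = space or FeatureSpace()
        feat = [
            f"d{d}v{v}"
            for d in range(space.pool_size)
            for v in range(1, space.values_per_dim + 1)
        ]
        return Vocabulary({
            "feature": feat,
            "label": list(LABEL_TOKENS),
            "structural": [QUERY_TOKEN, PAD_TOKEN],
        })
    if task_family == "compositional":
        coords = [f"c{i}" for i in range(2 * GRID_SIZE - 1)]
        return Vocabulary({
            "color": list(COLORS),
            "animal": list(ANIMALS),
            "coordinate": coords,
            "structural": [QUERY_TOKEN, PAD_TOKEN],
        })
    raise ValueError(f"unknown task family {task_family!r}")


@dataclass(frozen=True)
class Episode:
    """Context + query token ids and the withheld answer token ids.

    ``positions`` carries explicit position ids so that stripping the
    context preserves the query's positional identity.  ``example_spans``
    delimits each study example inside ``tokens`` (used by the attention
    ablation); ``target_positions`` continue the position sequence past the
    query for teacher forcing.
    """

    tokens: np.ndarray
    positions: np.ndarray
    target: np.ndarray
    target_positions: np.ndarray
    context_len: int
    example_spans: tuple[tuple[int, int], ...]
    example_groups: tuple[int, ...]
    query_group: int
    split: Literal["train_query", "test_query"]
    family: Literal["category", "compositional"]

    def __post_init__(self):
        if len(self.tokens) != len(self.positions):
            raise ValueError("tokens and positions must align")
        if len(self.target) != len(self.target_positions):
            raise ValueError("target and target_positions must align")


def encode_episode(
    curriculum: Curriculum | GridCurriculum,
    query,
    vocab: Vocabulary,
) -> Episode:
    """Encode one (curriculum, query) pair as a token episode."""
    if isinstance(curriculum, Curriculum):
        return _encode_category(curriculum, query, vocab)
    return _encode_grid(curriculum, query, vocab)


def _encode_category(cur: Curriculum, query: tuple[int, int],
                     vocab: Vocabulary) -> Episode:
    task = cur.task
    d1, d2 = task.dims
    toks: list[int] = []
    spans: list[tuple[int, int]] = []
    groups: list[int] = []
    for item in cur.order:
        start = len(toks)
        toks.append(vocab[f"d{d1}v{item[0]}"])
        toks.append(vocab[f"d{d2}v{item[1]}"])
        toks.append(vocab[LABEL_TOKENS[task.label_of(item)]])
        spans.append((start, len(toks)))
        groups.append(task.label_of(item))
    context_len = len(toks)
    toks.append(vocab[QUERY_TOKEN])
    toks.append(vocab[f"d{d1}v{query[0]}"])
    toks.append(vocab[f"d{d2}v{query[1]}"])
    target = np.array([vocab[LABEL_TOKENS[task.label_of(query)]]], dtype=np.int64)
    n = len(toks)
    return Episode(
        tokens=np.array(toks, dtype=np.int64),
        positions=np.arange(n, dtype=np.int64),
        target=target,
        target_positions=np.arange(n, n + 1, dtype=np.int64),
        context_len=context_len,
        example_spans=tuple(spans),
        example_groups=tuple(groups),
        query_group=task.label_of(query),
        split="train_query" if query in task.study_items else "test_query",
        family="category",
    )


def _encode_grid(cur: GridCurriculum, query: Cue, vocab: Vocabulary) -> Episode:
    task = cur.task
    toks: list[int] = []
    spans: list[tuple[int, int]] = []
    groups: list[int] = []
    group_ix = {g: i for i, g in enumerate(cur.block_order)}
    for cue in cur.study:
        start = len(toks)
        x, y = task.locations[cue]
        toks.extend([vocab[cue[0]], vocab[cue[1]], vocab[f"c{x}"], vocab[f"c{y}"]])
        spans.append((start, len(toks)))
        groups.append(group_ix[cur.group_of[cue]])
    context_len = len(toks)
    toks.append(vocab[QUERY_TOKEN])
    toks.extend([vocab[query[0]], vocab[query[1]]])
    qx, qy = task.locations[query]
    target = np.array([vocab[f"c{qx}"], vocab[f"c{qy}"]], dtype=np.int64)
    n = len(toks)
    qgroup = group_ix.get(cur.group_of.get(query, cur.block_order[0]), 0)
    return Episode(
        tokens=np.array(toks, dtype=np.int64),
        positions=np.arange(n, dtype=np.int64),
        target=target,
        target_positions=np.arange(n, n + 2, dtype=np.int64),
        context_len=context_len,
        example_spans=tuple(spans),
        example_groups=tuple(groups),
        query_group=qgroup,
        split="train_query" if query in cur.study else "test_query",
        family="compositional",
    )


def decode_episode(episode: Episode, vocab: Vocabulary) -> dict:
    """Inverse of :func:`encode_episode` back to token strings."""
    toks = [vocab.decode(int(t)) for t in episode.tokens]
    return {
        "context": [
            toks[s:e] for s, e in episode.example_spans
        ],
        "query": toks[episode.context_len:],
        "target": [vocab.decode(int(t)) for t in episode.target],
    }


def strip_context(episode: Episode) -> Episode:
    """Remove the study context, keeping the query's tokens, positions and
    target unchanged (the retention-test input).  Idempotent."""
    c = episode.context_len
    return replace(
        episode,
        tokens=episode.tokens[c:],
        positions=episode.positions[c:],
        context_len=0,
        example_spans=(),
        example_groups=(),
    )


def episode_to_json(episode: Episode) -> str:
    return json.dumps({
        "tokens": episode.tokens.tolist(),
        "positions": episode.positions.tolist(),
        "target": episode.target.tolist(),
        "target_positions": episode.target_positions.tolist(),
        "context_len": episode.context_len,
        "example_spans": [list(s) for s in episode.example_spans],
        "example_groups": list(episode.example_groups),
        "query_group": episode.query_group,
        "split": episode.split,
        "family": episode.family,
    })


def episode_from_json(line: str) -> Episode:
    d = json.loads(line)
    return Episode(
        tokens=np.array(d["tokens"], dtype=np.int64),
        positions=np.array(d["positions"], dtype=np.int64),
        target=np.array(d["target"], dtype=np.int64),
        target_positions=np.array(d["target_positions"], dtype=np.int64),
        context_len=d["context_len"],
        example_spans=tuple(tuple(s) for s in d["example_spans"]),
        example_groups=tuple(d["example_groups"]),
        query_group=d["query_group"],
        split=d["split"],
        family=d["family"],
    )
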