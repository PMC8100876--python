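"""Shared fixtures and random-annotation helpers."""

from __future__ import annotations

import numpy as np
import pytest

from famgraph.types import (
    FAMILY_MEMBER,
    LIVING_STATUS,
    OBSERVATION,
    Entity,
    Relation,
    Token,
)

WORDS = [
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lam", "mu", "nu", "xi", "omicron", "pi",
]


def random_tokens(rng: np.random.Generator, n: int) -> list[Token]:
    return Token.sequence([WORDS[int(rng.integers(len(WORDS)))] for _ in range(n)])


def random_annotations(
    rng: np.random.Generator, n_tokens: int = 12, with_sides: bool = False
) -> tuple[list[Token], list[Entity], list[Relation]]:
    """A random valid annotation set: non-overlapping entities, relations
    from family members to observation/living-status entities, each
    dependent attached at most once."""
    tokens = random_tokens(rng, n_tokens)
    entities: list[Entity] = []
    pos = 0
    while pos < n_tokens:
        if rng.random() < 0.45:
            length = int(rng.integers(1, min(3, n_tokens - pos) + 1))
            etype = [FAMILY_MEMBER, OBSERVATION, LIVING_STATUS][
                int(rng.choice(3, p=[0.4, 0.4, 0.2]))
            ]
            kw = {}
            if etype == FAMILY_MEMBER and with_sides:
                kw["side"] = ["NA", "Maternal", "Paternal"][int(rng.integers(3))]
            entities.append(Entity(0, pos, pos + length - 1, etype, **kw))
            pos += length
        pos += 1
    fms = [e for e in entities if e.is_family_member()]
    relations = []
    for e in entities:
        if not e.is_family_member() and fms and rng.random() < 0.7:
            relations.append(Relation(fms[int(rng.integers(len(fms)))], e))
    return tokens, entities, relations


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
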