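"""Shared fixtures: brute-force inference oracles and random small models.

The oracle enumerates the full joint over every node of a latent tree and
computes record likelihoods / latent posteriors by summation — independent
of the package's message-passing code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hlcm.cohort import MISSING, Cohort, SymptomCatalog
from hlcm.model import LATENT, OBSERVED, LatentTreeModel


def joint_table(model: LatentTreeModel) -> tuple[list[str], np.ndarray]:
    """Full joint P(all nodes) by enumeration; returns (node order, table)."""
    order = model.preorder()
    cards = [model.card[i] for i in order]
    table = np.zeros(cards)
    for states in itertools.product(*(range(c) for c in cards)):
        s = dict(zip(order, states))
        p = model.cpts[model.root][s[model.root]]
        for i in order:
            par = model.parent[i]
            if par is not None:
                p *= model.cpts[i][s[par], s[i]]
        table[states] = p
    return order, table


def oracle_record_prob(model: LatentTreeModel, record: dict[str, int]) -> float:
    """P(observed leaves = record) by joint enumeration."""
    order, table = joint_table(model)
    total = 0.0
    for states in itertools.product(*(range(model.card[i]) for i in order)):
        s = dict(zip(order, states))
        if all(s[k] == v for k, v in record.items() if v != MISSING):
            total += table[states]
    return total


def oracle_posteriors(model: LatentTreeModel,
                      record: dict[str, int]) -> dict[str, np.ndarray]:
    """P(latent = s | record) by Bayes on the enumerated joint."""
    order, table = joint_table(model)
    post = {y: np.zeros(model.card[y]) for y in model.latents}
    for states in itertools.product(*(range(model.card[i]) for i in order)):
        s = dict(zip(order, states))
        if all(s[k] == v for k, v in record.items() if v != MISSING):
            for y in model.latents:
                post[y][s[y]] += table[states]
    z = oracle_record_prob(model, record)
    return {y: p / z for y, p in post.items()}


def random_small_model(rng: np.random.Generator, max_latents: int = 3,
                       max_leaves: int = 6) -> LatentTreeModel:
    """Random latent tree with <= 3 latents and <= 6 leaves, random CPTs."""
    n_lat = int(rng.integers(1, max_latents + 1))
    n_leaf = int(rng.integers(2, max_leaves + 1))
    latents = [f"Y{i}" for i in range(n_lat)]
    leaves = [f"x{i}" for i in range(n_leaf)]
    kind = {**{y: LATENT for y in latents}, **{x: OBSERVED for x in leaves}}
    card = {y: int(rng.integers(2, 4)) for y in latents}
    card.update({x: 2 for x in leaves})
    parent: dict[str, str | None] = {latents[0]: None}
    for i, y in enumerate(latents[1:], start=1):
        parent[y] = latents[int(rng.integers(0, i))]
    for x in leaves:
        parent[x] = latents[int(rng.integers(0, n_lat))]
    cpts: dict[str, np.ndarray] = {}
    for i in kind:
        shape = (card[i],) if parent[i] is None else (card[parent[i]], card[i])
        t = rng.uniform(0.05, 1.0, size=shape)
        cpts[i] = t / t.sum(axis=-1, keepdims=True)
    return LatentTreeModel(kind, card, parent, cpts)


def random_record(rng: np.random.Generator, model: LatentTreeModel,
                  p_missing: float = 0.2) -> dict[str, int]:
    rec = {}
    for x in model.leaves:
        u = rng.random()
        rec[x] = MISSING if u < p_missing else int(rng.integers(0, 2))
    return rec


def cohort_from_records(model: LatentTreeModel,
                        records: list[dict[str, int]]) -> Cohort:
    leaves = model.leaves
    rows = np.array([[r.get(l, MISSING) for l in leaves] for r in records],
                    dtype=np.int8)
    return Cohort(SymptomCatalog.from_ids(leaves), rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
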