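"""BIC-guided double hill-climbing over latent tree structures.

The search runs on two levels, mirroring the cheap/expensive split of
double hill climbing: every neighbour of the incumbent structure (one
application of a node-introduction, node-deletion, state-introduction,
state-deletion, or node-relocation operator) is screened with a short EM
run, and only the best-screened candidate is refit at the full EM budget
before it can replace the incumbent.  The climb stops the first time the
full-budget BIC fails to rise.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort
from .model import (FitConfig, LATENT, LatentTreeModel, OBSERVED, bic_score,
                    em_fit, flat_latent_class_model, model_dimension,
                    node_marginals)

OPERATORS = ("NI", "ND", "SI", "SD", "NR")

log = logging.getLogger("hlcm.search")


@dataclass
class SearchConfig:
    """Budgets for the two search levels.

    Screening (level 1) scores every candidate with ``screen_iters`` EM
    iterations and ``screen_restarts`` starts (the first start is warm from
    the incumbent's parameters); the winner (level 2) is refit with the full
    budget before acceptance.  ``max_card`` caps latent cardinalities (the
    default keeps all latents binary).
    """

    operators: tuple[str, ...] = OPERATORS
    max_steps: int = 100
    screen_iters: int = 20
    screen_restarts: int = 2
    full_iters: int = 500
    full_restarts: int = 4
    prescreen_iters: int = 3
    prescreen_keep: int = 48
    tol: float = 1e-6
    pseudocount: float = 0.5
    seed: int = 0
    max_card: int = 2

    def __post_init__(self) -> None:
        bad = set(self.operators) - set(OPERATORS)
        if bad:
            raise ValueError(f"unknown operators {sorted(bad)}")
        if not self.operators:
            raise ValueError("at least one operator must be enabled")
        if min(self.max_steps, self.screen_iters, self.screen_restarts,
               self.full_iters, self.full_restarts, self.prescreen_iters,
               self.prescreen_keep) < 1:
            raise ValueError("all budgets must be >= 1")


@dataclass(frozen=True)
class TraceStep:
    step: int
    operator: str
    candidates: int
    bic: float


@dataclass
class SearchTrace:
    steps: list[TraceStep] = field(default_factory=list)
    final_bic: float = float("-inf")
    final_model: str = ""

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("step\toperator\tcandidates\tbic\n")
            for s in self.steps:
                fh.write(f"{s.step}\t{s.operator}\t{s.candidates}\t{s.bic:.6f}\n")


# ---------------------------------------------------------------------------
# Structure signatures (isomorphism-invariant, leaf-labelled)
# ---------------------------------------------------------------------------

def structure_signature(model: LatentTreeModel, node: str | None = None) -> str:
    """Canonical string for the rooted structure: latent ids anonymized,
    leaves kept by id, children sorted.  Equal signatures = isomorphic."""
    node = node if node is not None else model.root
    if model.kind[node] == OBSERVED:
        return f"L[{node}]"
    kids = sorted(structure_signature(model, c) for c in model.children[node])
    return f"Y{model.card[node]}({','.join(kids)})"


# ---------------------------------------------------------------------------
# Candidate initialization (deterministic warm start)
# ---------------------------------------------------------------------------

def _base_dist(old: LatentTreeModel, old_marg, node: str, card: int) -> np.ndarray:
    if node in old.kind:
        b = np.asarray(old_marg[node], dtype=float)
        if b.size > card:
            b = b[:card]
        elif b.size < card:
            b = np.concatenate([b, np.full(card - b.size, 0.1)])
        b = np.maximum(b, 0.02)
        return b / b.sum()
    return np.full(card, 1.0 / card)


def _init_cpts(kind, card, parent, old: LatentTreeModel) -> dict[str, np.ndarray]:
    """Warm-start CPTs: copied where the local structure is unchanged,
    otherwise rebuilt from old node marginals with a deterministic tilt
    across parent states to break symmetry."""
    old_marg = node_marginals(old)
    cpts: dict[str, np.ndarray] = {}
    for node in kind:
        par = parent[node]
        if (node in old.kind and par == old.parent.get(node)
                and card[node] == old.card[node]
                and (par is None or card[par] == old.card.get(par))):
            cpts[node] = old.cpts[node].copy()
            continue
        b = _base_dist(old, old_marg, node, card[node])
        if par is None:
            cpts[node] = b
            continue
        cp = card[par]
        tilt = np.linspace(-1.0, 1.0, cp)[:, None] * np.linspace(-0.3, 0.3, card[node])[None, :]
        t = np.clip(b[None, :] * (1.0 + tilt), 0.01, None)
        cpts[node] = t / t.sum(axis=1, keepdims=True)
    return cpts


def _fresh_id(existing: set[str]) -> str:
    k = 0
    while f"Z{k}" in existing:
        k += 1
    return f"Z{k}"


def _make(kind, card, parent, old) -> LatentTreeModel:
    return LatentTreeModel(dict(kind), dict(card), dict(parent),
                           _init_cpts(kind, card, parent, old))


def _card_regular(kind, card, parent, children, node) -> bool:
    """Cardinality-regularity guard: a latent's cardinality must not exceed
    the product of its neighbours' cardinalities divided by the largest."""
    neigh = list(children[node])
    if parent[node] is not None:
        neigh.append(parent[node])
    cards = [card[x] for x in neigh]
    prod = int(np.prod(cards, dtype=np.int64))
    return card[node] <= max(2, prod // max(cards))


def _subtree(children, node) -> set[str]:
    out, stack = set(), [node]
    while stack:
        i = stack.pop()
        out.add(i)
        stack.extend(children[i])
    return out


def neighbor_candidates(model: LatentTreeModel,
                        operators: tuple[str, ...] = OPERATORS,
                        max_card: int = 2) -> list[tuple[str, LatentTreeModel]]:
    """All valid one-operator neighbours, structure-deduplicated.

    Returns (operator, candidate) pairs sorted by structure signature so the
    enumeration order does not depend on node ids or column order.
    """
    kind, card, parent, children = model.kind, model.card, model.parent, model.children
    out: dict[str, tuple[str, LatentTreeModel]] = {}

    def offer(op: str, k, c, p) -> None:
        cand = _make(k, c, p, model)
        # regularity: root latent with >= 2 children, every latent >= 2 children
        if any(kind2 == LATENT and len(cand.children[i]) < 2
               for i, kind2 in cand.kind.items()):
            return
        sig = structure_signature(cand)
        if sig != structure_signature(model) and sig not in out:
            out[sig] = (op, cand)

    if "NI" in operators:
        for y in model.latents:
            kids = children[y]
            if len(kids) < 3:
                continue
            for a_i in range(len(kids)):
                for b_i in range(a_i + 1, len(kids)):
                    a, b = kids[a_i], kids[b_i]
                    z = _fresh_id(set(kind))
                    k = {**kind, z: LATENT}
                    c = {**card, z: 2}
                    p = {**parent, z: y, a: z, b: z}
                    offer("NI", k, c, p)
    if "ND" in operators:
        for y in model.latents:
            if parent[y] is None:
                continue
            k = {i: v for i, v in kind.items() if i != y}
            c = {i: v for i, v in card.items() if i != y}
            p = {i: (parent[y] if v == y else v)
                 for i, v in parent.items() if i != y}
            offer("ND", k, c, p)
    if "SI" in operators:
        for y in model.latents:
            if card[y] + 1 > max_card:
                continue
            c = {**card, y: card[y] + 1}
            if _card_regular(kind, c, parent, children, y):
                offer("SI", dict(kind), c, dict(parent))
    if "SD" in operators:
        for y in model.latents:
            if card[y] - 1 < 2:
                continue
            offer("SD", dict(kind), {**card, y: card[y] - 1}, dict(parent))
    if "NR" in operators:
        for x in model.kind:
            if parent[x] is None:
                continue
            sub = _subtree(children, x)
            for t in model.latents:
                if t in sub or t == parent[x]:
                    continue
                offer("NR", dict(kind), dict(card), {**parent, x: t})

    return [out[sig] for sig in sorted(out)]


# ---------------------------------------------------------------------------
# The climb
# ---------------------------------------------------------------------------

def _cand_seed(master: int, step: int, sig: str) -> int:
    return (master * 1_000_003 + step * 9_176 + zlib.crc32(sig.encode())) % (2 ** 31)


def dhc_search(cohort: Cohort,
               config: SearchConfig) -> tuple[LatentTreeModel, SearchTrace]:
    """Greedy BIC ascent from the single-latent model; deterministic given
    the seed and invariant to cohort column order."""
    if cohort.n < 1:
        raise ValueError("search needs at least one record")
    if len(cohort.catalog) < 2:
        raise ValueError("search needs at least two symptom columns")

    full = lambda seed: FitConfig(config.full_iters, config.tol,
                                  config.full_restarts, config.pseudocount, seed)
    screen = lambda seed: FitConfig(config.screen_iters, config.tol,
                                    config.screen_restarts, config.pseudocount,
                                    seed)

    init = flat_latent_class_model(sorted(cohort.catalog.ids), 2)
    incumbent = em_fit(init, cohort, full(config.seed % (2 ** 31)))
    inc_bic = bic_score(incumbent, cohort, incumbent.metadata["loglik"])
    trace = SearchTrace()
    trace.steps.append(TraceStep(0, "INIT", 1, inc_bic))

    prescreen = lambda seed: FitConfig(config.prescreen_iters, config.tol, 1,
                                       config.pseudocount, seed)

    for step in range(1, config.max_steps + 1):
        cands = neighbor_candidates(incumbent, config.operators, config.max_card)
        if not cands:
            break
        n_neighbourhood = len(cands)
        with warnings.catch_warnings():
            # budgeted screening fits are not expected to converge
            warnings.filterwarnings("ignore", message="EM did not converge")
            if len(cands) > config.prescreen_keep:
                # cheap first pass: a few warm-started EM iterations rank the
                # neighbourhood; only the most promising go to real screening
                ranked = []
                for op, cand in cands:
                    sig = structure_signature(cand)
                    coarse = em_fit(
                        cand, cohort,
                        prescreen(_cand_seed(config.seed, step, "pre:" + sig)),
                        warm_start=True)
                    ranked.append((bic_score(coarse, cohort,
                                             coarse.metadata["loglik"]),
                                   sig, op, cand))
                ranked.sort(key=lambda t: (-t[0], t[1]))
                cands = [(op, cand) for _, _, op, cand in
                         ranked[:config.prescreen_keep]]
            scored = []
            for op, cand in cands:
                sig = structure_signature(cand)
                fitted = em_fit(cand, cohort,
                                screen(_cand_seed(config.seed, step, sig)),
                                warm_start=True)
                b = bic_score(fitted, cohort, fitted.metadata["loglik"])
                scored.append((b, -model_dimension(fitted),
                               -len(fitted.latents), sig, op, fitted))
        scored.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
        b_screen, _, _, sig, op, winner = scored[0]
        refit = em_fit(winner, cohort,
                       full(_cand_seed(config.seed, step, "refit:" + sig)),
                       warm_start=True)
        cand_bic = bic_score(refit, cohort, refit.metadata["loglik"])
        if cand_bic <= inc_bic:
            break                      # the BIC falls instead of rises: stop
        incumbent, inc_bic = refit, cand_bic
        trace.steps.append(TraceStep(step, op, n_neighbourhood, inc_bic))
        log.info("step %d: %s accepted (%d neighbours), BIC %.2f, %d latents",
                 step, op, n_neighbourhood, inc_bic, len(incumbent.latents))

    trace.final_bic = inc_bic
    trace.final_model = structure_signature(incumbent)
    incumbent.metadata.update({"bic": float(inc_bic), "search_seed": config.seed,
                               "n_records": cohort.n})
    return incumbent, trace
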