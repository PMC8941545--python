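"""Hierarchical latent class (latent tree) models over binary symptoms.

The model is a rooted tree: every internal node is a discrete latent
variable (cardinality >= 2), every leaf an observed binary symptom.  The
root carries a marginal distribution, every other node a conditional
probability table (CPT) given its parent.  Exact inference is a single
upward/downward sum-product sweep per record; parameters are estimated by
(MAP-)EM with Dirichlet smoothing, and model quality is scored by the
Bayesian information criterion

    BIC(m | D) = log P(D | m, theta_hat) - (d / 2) * ln N,

natural log, ``d`` the standard parameter count — higher (less negative)
is better.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import MISSING, Cohort

LATENT = "latent"
OBSERVED = "observed"

SCHEMA = "hlcm-model/1"


class ZeroProbabilityEvidence(ValueError):
    """Evidence with probability zero under the model."""


# ---------------------------------------------------------------------------
# Model structure
# ---------------------------------------------------------------------------

@dataclass
class LatentTreeModel:
    """Rooted latent tree with CPTs.

    ``parent`` maps each node to its parent id (root maps to ``None``);
    ``cpts`` holds, for the root, a vector of length ``card(root)`` and, for
    every other node, an array of shape ``(card(parent), card(node))`` whose
    rows sum to one.
    """

    kind: dict[str, str]
    card: dict[str, int]
    parent: dict[str, str | None]
    cpts: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cpts = {k: np.asarray(v, dtype=float) for k, v in self.cpts.items()}
        self._rebuild()

    def _rebuild(self) -> None:
        self.children: dict[str, list[str]] = {i: [] for i in self.kind}
        roots = []
        for node, par in self.parent.items():
            if par is None:
                roots.append(node)
            else:
                self.children[par].append(node)
        if len(roots) != 1:
            raise ValueError(f"model must have exactly one root, found {roots}")
        self.root = roots[0]
        for i in self.children:
            self.children[i].sort()

    # -- structure queries ---------------------------------------------------

    @property
    def leaves(self) -> list[str]:
        return sorted(i for i, k in self.kind.items() if k == OBSERVED)

    @property
    def latents(self) -> list[str]:
        return sorted(i for i, k in self.kind.items() if k == LATENT)

    def preorder(self) -> list[str]:
        order, stack = [], [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self.children[i]))
        return order

    def postorder(self) -> list[str]:
        return list(reversed(self.preorder()))

    def copy(self) -> "LatentTreeModel":
        return LatentTreeModel(
            dict(self.kind), dict(self.card), dict(self.parent),
            {k: v.copy() for k, v in self.cpts.items()}, dict(self.metadata))

    def validate(self) -> list[str]:
        """Return structural/parametric invariant violations."""
        problems: list[str] = []
        for i, k in self.kind.items():
            if k == OBSERVED:
                if self.children[i]:
                    problems.append(f"observed node {i!r} is not a leaf")
                if self.card[i] != 2:
                    problems.append(f"observed node {i!r} must be binary")
            else:
                if not self.children[i]:
                    problems.append(f"latent node {i!r} has no children")
                if self.card[i] < 2:
                    problems.append(f"latent node {i!r} has cardinality < 2")
        if self.kind[self.root] != LATENT:
            problems.append("root must be latent")
        elif len(self.children[self.root]) < 2:
            problems.append("root must have at least two children "
                            "(nontrivial rooted tree)")
        for i, table in self.cpts.items():
            expected = ((self.card[i],) if self.parent[i] is None
                        else (self.card[self.parent[i]], self.card[i]))
            if table.shape != expected:
                problems.append(f"CPT for {i!r} has shape {table.shape}, "
                                f"expected {expected}")
                continue
            if (table < -1e-12).any() or (table > 1 + 1e-12).any():
                problems.append(f"CPT for {i!r} has entries outside [0, 1]")
            sums = table.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                problems.append(f"CPT rows for {i!r} do not sum to 1")
        missing = set(self.kind) - set(self.cpts)
        if missing:
            problems.append(f"nodes without CPTs: {sorted(missing)}")
        return problems

    # -- state relabelling ---------------------------------------------------

    def permute_states(self, node: str, perm: Sequence[int]) -> "LatentTreeModel":
        """Relabel a latent node's states; the joint distribution over the
        observed leaves is unchanged."""
        perm = list(perm)
        if sorted(perm) != list(range(self.card[node])):
            raise ValueError(f"invalid permutation {perm} for node {node!r}")
        out = self.copy()
        if self.parent[node] is None:
            out.cpts[node] = self.cpts[node][perm]
        else:
            out.cpts[node] = self.cpts[node][:, perm]
        for c in self.children[node]:
            out.cpts[c] = self.cpts[c][perm, :]
        return out

    # -- serialization -------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "schema": SCHEMA,
            "nodes": [{"id": i, "kind": self.kind[i], "cardinality": self.card[i]}
                      for i in sorted(self.kind)],
            "edges": [[self.parent[i], i] for i in sorted(self.kind)
                      if self.parent[i] is not None],
            "root": self.root,
            "cpts": {i: self.cpts[i].tolist() for i in sorted(self.cpts)},
            "metadata": self.metadata,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_json(cls, doc: dict) -> "LatentTreeModel":
        if doc.get("schema") != SCHEMA:
            raise ValueError(f"unsupported model schema {doc.get('schema')!r}")
        for key in ("nodes", "edges", "cpts"):
            if key not in doc:
                raise ValueError(f"model document missing {key!r}")
        kind = {n["id"]: n["kind"] for n in doc["nodes"]}
        card = {n["id"]: int(n["cardinality"]) for n in doc["nodes"]}
        parent: dict[str, str | None] = {i: None for i in kind}
        for par, child in doc["edges"]:
            parent[child] = par
        cpts = {i: np.asarray(t, dtype=float) for i, t in doc["cpts"].items()}
        return cls(kind, card, parent, cpts, dict(doc.get("metadata", {})))

    @classmethod
    def load(cls, path: str | Path) -> "LatentTreeModel":
        return cls.from_json(json.loads(Path(path).read_text(encoding="utf-8")))


def flat_latent_class_model(leaves: Iterable[str], n_classes: int = 2,
                            latent_id: str = "Y0") -> LatentTreeModel:
    """The canonical LCA start: one latent over all leaves, uniform CPTs."""
    leaves = list(leaves)
    kind = {latent_id: LATENT, **{l: OBSERVED for l in leaves}}
    card = {latent_id: n_classes, **{l: 2 for l in leaves}}
    parent: dict[str, str | None] = {latent_id: None,
                                     **{l: latent_id for l in leaves}}
    cpts = {latent_id: np.full(n_classes, 1.0 / n_classes)}
    for l in leaves:
        cpts[l] = np.full((n_classes, 2), 0.5)
    return LatentTreeModel(kind, card, parent, cpts)


# ---------------------------------------------------------------------------
# Exact inference (scaled sum-product on the tree)
# ---------------------------------------------------------------------------

def _leaf_matrix(model: LatentTreeModel, cohort: Cohort) -> np.ndarray:
    """Records aligned to model leaves; leaves absent from the cohort are
    treated as unobserved everywhere."""
    extra = set(cohort.catalog.ids) - set(model.leaves)
    if extra:
        raise ValueError(f"cohort columns not in model: {sorted(extra)}")
    X = np.full((cohort.n, len(model.leaves)), MISSING, dtype=np.int8)
    for j, leaf in enumerate(model.leaves):
        if leaf in cohort.catalog.ids:
            X[:, j] = cohort.records[:, cohort.catalog.index(leaf)]
    return X


def _upward(model: LatentTreeModel, X: np.ndarray):
    """Scaled subtree-evidence messages.

    Returns ``beta[i]`` of shape (n, card_i) = scaled P(evidence below i | i),
    ``kappa[i]`` the per-child factors used for downward exclusion, and the
    per-record accumulated log scale.
    """
    n = X.shape[0]
    col = {leaf: j for j, leaf in enumerate(model.leaves)}
    beta: dict[str, np.ndarray] = {}
    kappa: dict[str, list[np.ndarray]] = {}
    logscale = np.zeros(n)
    for i in model.postorder():
        c_i = model.card[i]
        if model.kind[i] == OBSERVED:
            v = X[:, col[i]]
            b = np.ones((n, c_i))
            obs = v != MISSING
            b[obs] = 0.0
            b[obs, v[obs].astype(int)] = 1.0
        else:
            b = np.ones((n, c_i))
            ks = []
            for c in model.children[i]:
                k = beta[c] @ model.cpts[c].T        # (n, card_i)
                ks.append(k)
                b = b * k
            kappa[i] = ks
            m = b.max(axis=1)
            scale = np.where(m > 0, m, 1.0)
            b = b / scale[:, None]
            with np.errstate(divide="ignore"):
                logscale = logscale + np.where(m > 0, np.log(scale), -np.inf)
        beta[i] = b
    return beta, kappa, logscale


def _exclusion_products(ks: list[np.ndarray]) -> list[np.ndarray]:
    """For factors k_1..k_m return prod_{d != c} k_d without division."""
    m = len(ks)
    if m == 1:
        return [np.ones_like(ks[0])]
    prefix = [None] * m
    suffix = [None] * m
    acc = np.ones_like(ks[0])
    for c in range(m):
        prefix[c] = acc
        acc = acc * ks[c]
    acc = np.ones_like(ks[0])
    for c in range(m - 1, -1, -1):
        suffix[c] = acc
        acc = acc * ks[c]
    return [prefix[c] * suffix[c] for c in range(m)]


def _downward(model: LatentTreeModel, beta, kappa):
    """Scaled above-evidence messages ``alpha[i]`` (n, card_i)."""
    n = next(iter(beta.values())).shape[0]
    alpha: dict[str, np.ndarray] = {}
    alpha[model.root] = np.broadcast_to(model.cpts[model.root], (n, model.card[model.root]))
    for i in model.preorder():
        if model.kind[i] == OBSERVED or not model.children[i]:
            continue
        excl = _exclusion_products(kappa[i])
        for c, e in zip(model.children[i], excl):
            a = (alpha[i] * e) @ model.cpts[c]       # (n, card_c)
            s = a.sum(axis=1, keepdims=True)
            alpha[c] = a / np.where(s > 0, s, 1.0)
    return alpha


def log_likelihood(model: LatentTreeModel, cohort: Cohort,
                   per_record: bool = False):
    """Natural-log likelihood of the observed leaves under the model.

    Missing cells and leaves absent from the cohort are marginalized out.
    Records with probability zero contribute ``-inf`` and are named in a
    warning.
    """
    X = _leaf_matrix(model, cohort)
    beta, _, logscale = _upward(model, X)
    lik = beta[model.root] @ model.cpts[model.root]
    with np.errstate(divide="ignore"):
        ll = np.where(lik > 0, np.log(np.maximum(lik, 1e-300)), -np.inf) + logscale
    zero = np.nonzero(~np.isfinite(ll))[0]
    if zero.size:
        warnings.warn(f"records with probability zero under the model: "
                      f"{zero[:10].tolist()}{'...' if zero.size > 10 else ''}")
    total = float(ll.sum()) if np.isfinite(ll).all() else float("-inf")
    return (total, ll) if per_record else total


def posterior_marginals_batch(model: LatentTreeModel,
                              cohort: Cohort) -> dict[str, np.ndarray]:
    """Exact P(Y = s | record) for every latent Y; arrays of shape (n, card)."""
    X = _leaf_matrix(model, cohort)
    beta, kappa, _ = _upward(model, X)
    alpha = _downward(model, beta, kappa)
    out: dict[str, np.ndarray] = {}
    for y in model.latents:
        p = alpha[y] * beta[y]
        s = p.sum(axis=1, keepdims=True)
        bad = np.nonzero(s[:, 0] <= 0)[0]
        if bad.size:
            raise ZeroProbabilityEvidence(
                f"evidence has probability zero for record(s) {bad[:10].tolist()}")
        out[y] = p / s
    return out


def posterior_marginals(model: LatentTreeModel,
                        record: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Posterior state distribution of every latent given a partial record."""
    unknown = set(record) - set(model.leaves)
    if unknown:
        raise ValueError(f"record keys not model leaves: {sorted(unknown)}")
    from .cohort import Cohort as _C, SymptomCatalog
    leaves = model.leaves
    row = np.full((1, len(leaves)), MISSING, dtype=np.int8)
    for k, v in record.items():
        row[0, leaves.index(k)] = v
    cohort = _C(SymptomCatalog.from_ids(leaves), row)
    return {y: p[0] for y, p in posterior_marginals_batch(model, cohort).items()}


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def model_dimension(model: LatentTreeModel) -> int:
    """Standard (free-) parameter count of the tree."""
    d = 0
    for i in model.kind:
        if model.parent[i] is None:
            d += model.card[i] - 1
        else:
            d += (model.card[i] - 1) * model.card[model.parent[i]]
    return d


def bic_score(model: LatentTreeModel, cohort: Cohort,
              loglik: float | None = None) -> float:
    """BIC = logL - (d/2) ln N; higher is better."""
    if cohort.n < 1:
        raise ValueError("BIC needs at least one record")
    if loglik is None:
        loglik = log_likelihood(model, cohort)
    return loglik - 0.5 * model_dimension(model) * np.log(cohort.n)


def node_marginals(model: LatentTreeModel) -> dict[str, np.ndarray]:
    """Marginal distribution of every node under no evidence."""
    marg = {model.root: model.cpts[model.root].copy()}
    for i in model.preorder():
        for c in model.children[i]:
            marg[c] = marg[i] @ model.cpts[c]
    return marg


# ---------------------------------------------------------------------------
# EM parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """EM settings: iteration cap, relative-change tolerance on the
    (smoothed) objective, random restarts, Dirichlet pseudocount, seed."""

    max_iters: int = 500
    tol: float = 1e-6
    restarts: int = 8
    pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iters < 1 or self.tol <= 0 or self.restarts < 1 \
                or self.pseudocount < 0:
            raise ValueError("invalid FitConfig")


def _random_cpts(model: LatentTreeModel, rng: np.random.Generator) -> None:
    """In-place random init: cells uniform in (0.1, 0.9), rows normalized."""
    for i in model.kind:
        shape = model.cpts[i].shape
        t = rng.uniform(0.1, 0.9, size=shape)
        model.cpts[i] = t / t.sum(axis=-1, keepdims=True)


def _e_step(model: LatentTreeModel, X: np.ndarray, w: np.ndarray):
    """Expected sufficient statistics and the data log-likelihood.

    Pairwise parent-child expected counts are accumulated without forming
    the (n, card_p, card_c) tensor:  counts_c = cpt_c * (A~.T @ B) with
    A = alpha * excl (above-evidence at the parent), B = beta_c, and A~
    row-scaled by weight / normalizer.
    """
    beta, kappa, logscale = _upward(model, X)
    lik = beta[model.root] @ model.cpts[model.root]
    good = lik > 0
    with np.errstate(divide="ignore"):
        ll = float((w * (np.where(good, np.log(np.maximum(lik, 1e-300)), -np.inf)
                         + logscale)).sum()) if good.all() else float("-inf")
    counts: dict[str, np.ndarray] = {}
    n = X.shape[0]
    alpha: dict[str, np.ndarray] = {
        model.root: np.broadcast_to(model.cpts[model.root],
                                    (n, model.card[model.root]))}
    post_root = alpha[model.root] * beta[model.root]
    post_root = post_root / post_root.sum(axis=1, keepdims=True)
    counts[model.root] = w @ post_root
    for i in model.preorder():
        if not model.children[i]:
            continue
        excl = _exclusion_products(kappa[i])
        for c, e in zip(model.children[i], excl):
            A = alpha[i] * e
            B = beta[c]
            cpt = model.cpts[c]
            z = ((B @ cpt.T) * A).sum(axis=1)
            ws = w / np.where(z > 0, z, 1.0)
            counts[c] = cpt * ((A * ws[:, None]).T @ B)
            if model.children[c]:
                a = A @ cpt
                s = a.sum(axis=1, keepdims=True)
                alpha[c] = a / np.where(s > 0, s, 1.0)
    return counts, ll


def _m_step(model: LatentTreeModel, counts: dict[str, np.ndarray],
            pc: float) -> None:
    for i in model.kind:
        c = counts[i] + pc
        model.cpts[i] = c / c.sum(axis=-1, keepdims=True)


def _log_prior(model: LatentTreeModel, pc: float) -> float:
    if pc == 0:
        return 0.0
    return pc * sum(float(np.log(np.maximum(t, 1e-300)).sum())
                    for t in model.cpts.values())


def em_fit(structure: LatentTreeModel, cohort: Cohort, config: FitConfig,
           warm_start: bool = False) -> LatentTreeModel:
    """Fit CPTs by EM on a fixed topology; best of ``restarts`` inits.

    With a positive pseudocount this is MAP-EM under a Dirichlet(1 + pc)
    prior per CPT row; the penalized objective (logL + pc * sum log theta)
    is nondecreasing every iteration.  With ``warm_start`` the structure's
    own CPTs seed the first restart.  The returned model's ``metadata``
    records loglik, iterations, and a convergence flag.
    """
    if cohort.n < 1:
        raise ValueError("EM needs at least one record")
    key = tuple(structure.leaves)
    cache = getattr(cohort, "_pattern_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(cohort, "_pattern_cache", cache)
    if key in cache:
        U, w = cache[key]
    else:
        X = _leaf_matrix(structure, cohort)
        U, cnt = np.unique(X, axis=0, return_counts=True)
        w = cnt.astype(float)
        cache[key] = (U, w)
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.restarts)
    best: LatentTreeModel | None = None
    best_obj = -np.inf
    for r in range(config.restarts):
        model = structure.copy()
        if not (warm_start and r == 0):
            _random_cpts(model, np.random.default_rng(child_seeds[r]))
        obj_prev = -np.inf
        ll = -np.inf
        converged = False
        it = 0
        ll_trace: list[float] = []
        for it in range(1, config.max_iters + 1):
            counts, ll = _e_step(model, U, w)
            ll_trace.append(float(ll))
            obj = ll + _log_prior(model, config.pseudocount)
            _m_step(model, counts, config.pseudocount)
            if np.isfinite(obj) and np.isfinite(obj_prev):
                if abs(obj - obj_prev) <= config.tol * (abs(obj_prev) + 1e-12):
                    converged = True
                    obj_prev = obj
                    break
            obj_prev = obj
        # objective/loglik of the final parameters
        _, ll = _e_step(model, U, w)
        ll_trace.append(float(ll))
        obj = ll + _log_prior(model, config.pseudocount)
        if obj > best_obj:
            best_obj = obj
            model.metadata = dict(structure.metadata)
            model.metadata.update({
                "loglik": float(ll), "em_iterations": it, "converged": converged,
                "restart": r, "seed": config.seed, "loglik_trace": ll_trace,
            })
            best = model
    if best is not None and not best.metadata.get("converged", False):
        warnings.warn("EM did not converge within max_iters; "
                      "returning best parameters found")
    assert best is not None
    return best
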