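"""Synthetic binary-symptom cohorts from latent-class generators.

The study's patient-level data are access-restricted, so every stage of the
pipeline is exercised on synthetic cohorts instead.  The generator draws,
per patient, a binary state for each latent pattern variable and then each
symptom independently given its block's state, using the published
class-conditional probability tables as the default parameters.  Latent
priors are not published; they are recovered by matching each block's
implied symptom marginals to the published cohort-wide frequencies
(solve m = p*p1 + (1-p)*p0 for p, averaged over the block).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import Cohort, SymptomCatalog
from .model import LATENT, OBSERVED, LatentTreeModel

# ---------------------------------------------------------------------------
# Published reference tables (the study cohort, n = 587)
# ---------------------------------------------------------------------------

REFERENCE_N = 587

#: Symptom presence counts in the reference cohort, in published order.
REFERENCE_SYMPTOM_COUNTS: dict[str, int] = {
    "fatigue": 190,
    "waist_knee_soreness": 160,
    "difficulty_falling_asleep": 132,
    "easy_waking": 109,
    "irritability": 91,
    "spontaneous_sweating": 84,
    "loose_stool": 71,
    "fear_of_chills": 62,
    "nocturia": 59,
    "epigastric_distention": 56,
    "limb_numbness": 45,
    "night_sweats": 42,
    "edema": 35,
    "shortness_of_breath": 27,
    "dry_itchy_painful_eyes": 21,
    "thirst_with_liking_for_fluids": 172,
    "dizziness": 136,
    "palpitation": 130,
    "chest_distress": 101,
    "dry_stool": 89,
    "bitter_taste": 76,
    "loss_of_appetite": 64,
    "tinnitus_deafness": 60,
    "blurred_vision": 57,
    "itchy_skin": 50,
    "anxiety": 43,
    "abdominal_distention": 37,
    "fear_of_heat": 28,
    "hiccup_belching": 24,
    "sore_mouth_tongue": 20,
}

#: Reference demographics: (count, denominator) pairs.
REFERENCE_DEMOGRAPHICS: dict[str, tuple[int, int]] = {
    "male": (257, REFERENCE_N),
    "female": (330, REFERENCE_N),
    "age_ge_50": (520, REFERENCE_N),
}

#: Published class-conditional tables: latent id -> list of
#: (symptom id, P(X=1|Y=S1), P(X=1|Y=S0)).
REFERENCE_BLOCKS: dict[str, list[tuple[str, float, float]]] = {
    "Y0": [  # qi-yin deficiency pattern
        ("irritability", 0.36, 0.05),
        ("dizziness", 0.43, 0.13),
        ("waist_knee_soreness", 0.47, 0.17),
        ("spontaneous_sweating", 0.29, 0.07),
        ("blurred_vision", 0.22, 0.04),
        ("difficulty_falling_asleep", 0.38, 0.15),
        ("limb_numbness", 0.17, 0.03),
        ("tinnitus_deafness", 0.20, 0.05),
        ("fear_of_heat", 0.12, 0.01),
        ("night_sweats", 0.13, 0.04),
        ("dry_stool", 0.23, 0.11),
    ],
    "Y1": [  # yin deficiency pattern
        ("bitter_taste", 0.50, 0.00),
        ("thirst_with_liking_for_fluids", 0.67, 0.16),
        ("dry_itchy_painful_eyes", 0.10, 0.01),
    ],
    "Y2": [  # qi stagnation pattern
        ("palpitation", 0.51, 0.03),
        ("chest_distress", 0.36, 0.05),
        ("hiccup_belching", 0.10, 0.00),
        ("epigastric_distention", 0.18, 0.04),
        ("anxiety", 0.13, 0.04),
        ("abdominal_distention", 0.09, 0.05),
    ],
    "Y3": [  # qi deficiency pattern
        ("loss_of_appetite", 0.78, 0.07),
        ("fatigue", 0.92, 0.29),
        ("easy_waking", 0.72, 0.16),
    ],
}

TOPOLOGIES = ("independent", "star", "chain")


# ---------------------------------------------------------------------------
# Generator spec
# ---------------------------------------------------------------------------

@dataclass
class LatentBlock:
    latent: str
    prior: float                                  # P(Y = S1)
    rows: list[tuple[str, float, float]]          # (symptom, p1, p0)


@dataclass
class GeneratorSpec:
    """Full description of a synthetic cohort: latent blocks, marginal-only
    symptoms, inter-latent topology, size, and seed."""

    blocks: list[LatentBlock]
    marginal_only: dict[str, float] = field(default_factory=dict)
    topology: str = "independent"
    coupling: dict[str, list[list[float]]] = field(default_factory=dict)
    n: int = REFERENCE_N
    seed: int = 0
    catalog_order: list[str] | None = None

    def validate(self) -> list[str]:
        problems: list[str] = []
        if self.topology not in TOPOLOGIES:
            problems.append(f"unknown topology {self.topology!r}")
        if self.n < 0:
            problems.append("n must be >= 0")
        seen: set[str] = set()
        for b in self.blocks:
            if not 0 <= b.prior <= 1:
                problems.append(f"{b.latent}: prior {b.prior} outside [0,1]")
            for sid, p1, p0 in b.rows:
                if sid in seen:
                    problems.append(f"duplicate symptom id {sid!r}")
                seen.add(sid)
                if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
                    problems.append(f"{sid}: CPD entries outside [0,1]")
        for sid, m in self.marginal_only.items():
            if sid in seen:
                problems.append(f"duplicate symptom id {sid!r}")
            seen.add(sid)
            if not 0 <= m <= 1:
                problems.append(f"{sid}: marginal outside [0,1]")
        if self.topology in ("star", "chain"):
            for b in self.blocks[1:]:
                t = np.asarray(self.coupling.get(b.latent, []), dtype=float)
                if t.shape != (2, 2) or not np.allclose(t.sum(axis=1), 1.0):
                    problems.append(f"{b.latent}: coupling must be a 2x2 "
                                    "row-stochastic table")
        return problems

    @property
    def symptom_ids(self) -> list[str]:
        if self.catalog_order is not None:
            return list(self.catalog_order)
        ids = [sid for b in self.blocks for sid, _, _ in b.rows]
        ids += list(self.marginal_only)
        return ids

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "blocks": [{"latent": b.latent, "prior": b.prior,
                        "rows": [list(r) for r in b.rows]} for b in self.blocks],
            "marginal_only": dict(self.marginal_only),
            "topology": self.topology,
            "coupling": {k: [list(r) for r in v] for k, v in self.coupling.items()},
            "n": self.n,
            "seed": self.seed,
            "catalog_order": self.catalog_order,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "GeneratorSpec":
        blocks = [LatentBlock(b["latent"], float(b["prior"]),
                              [(r[0], float(r[1]), float(r[2])) for r in b["rows"]])
                  for b in doc["blocks"]]
        return cls(blocks,
                   dict(doc.get("marginal_only", {})),
                   doc.get("topology", "independent"),
                   {k: [[float(x) for x in r] for r in v]
                    for k, v in doc.get("coupling", {}).items()},
                   int(doc.get("n", REFERENCE_N)),
                   int(doc.get("seed", 0)),
                   doc.get("catalog_order"))

    def save(self, path: str | Path) -> None:
        text = (yaml.safe_dump(self.to_dict(), sort_keys=False)
                if str(path).endswith((".yaml", ".yml"))
                else json.dumps(self.to_dict(), indent=1))
        Path(path).write_text(text, encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorSpec":
        text = Path(path).read_text(encoding="utf-8")
        doc = (yaml.safe_load(text) if str(path).endswith((".yaml", ".yml"))
               else json.loads(text))
        return cls.from_dict(doc)


# ---------------------------------------------------------------------------
# Default spec from the published tables
# ---------------------------------------------------------------------------

def derive_priors(blocks: dict[str, list[tuple[str, float, float]]],
                  marginals: dict[str, float]) -> dict[str, float]:
    """Marginal-matched latent priors.

    For each block symptom with class-conditionals p1 != p0 and cohort
    marginal m, solve ``m = p*p1 + (1-p)*p0``; the block prior is the mean
    of the per-symptom solutions (each clipped to [0, 1]), clipped to
    [0.01, 0.99].
    """
    priors: dict[str, float] = {}
    for latent, rows in blocks.items():
        sols = []
        for sid, p1, p0 in rows:
            if p1 == p0:
                continue
            m = marginals[sid]
            sols.append(min(1.0, max(0.0, (m - p0) / (p1 - p0))))
        if not sols:
            raise ValueError(f"{latent}: all class-conditionals equal, "
                             "prior underdetermined")
        priors[latent] = min(0.99, max(0.01, float(np.mean(sols))))
    return priors


def default_study_spec(n: int = REFERENCE_N, seed: int = 0,
                       topology: str = "independent") -> GeneratorSpec:
    """The published study conditions as a generator: four binary latent
    pattern variables with the printed class-conditional tables, plus
    marginal-only Bernoulli symptoms for the seven variables that appear in
    no table, marginal-matched priors, and the published catalog order."""
    marginals = {s: c / REFERENCE_N for s, c in REFERENCE_SYMPTOM_COUNTS.items()}
    priors = derive_priors(REFERENCE_BLOCKS, marginals)
    blocks = [LatentBlock(y, priors[y], list(rows))
              for y, rows in REFERENCE_BLOCKS.items()]
    tabled = {sid for rows in REFERENCE_BLOCKS.values() for sid, _, _ in rows}
    marginal_only = {s: m for s, m in marginals.items() if s not in tabled}
    return GeneratorSpec(blocks, marginal_only, topology, {}, n, seed,
                         catalog_order=list(REFERENCE_SYMPTOM_COUNTS))


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_latents(spec: GeneratorSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    states: dict[str, np.ndarray] = {}
    if spec.topology == "independent" or len(spec.blocks) == 1:
        for b in spec.blocks:
            states[b.latent] = (rng.random(spec.n) < b.prior).astype(np.int8)
        return states
    first = spec.blocks[0]
    states[first.latent] = (rng.random(spec.n) < first.prior).astype(np.int8)
    prev = states[first.latent]
    for b in spec.blocks[1:]:
        table = np.asarray(spec.coupling[b.latent], dtype=float)
        p1_given_parent = table[:, 1]
        p = p1_given_parent[prev]
        s = (rng.random(spec.n) < p).astype(np.int8)
        states[b.latent] = s
        if spec.topology == "chain":
            prev = s
    return states


def generate(spec: GeneratorSpec) -> Cohort:
    """Sample a cohort from the generator; deterministic given the seed."""
    problems = spec.validate()
    if problems:
        raise ValueError("invalid generator spec: " + "; ".join(problems))
    rng = np.random.default_rng(spec.seed)
    ids = spec.symptom_ids
    catalog = SymptomCatalog.from_ids(ids)
    records = np.zeros((spec.n, len(ids)), dtype=np.int8)
    states = _sample_latents(spec, rng)
    col = {sid: j for j, sid in enumerate(ids)}
    for b in spec.blocks:
        s = states[b.latent]
        for sid, p1, p0 in b.rows:
            p = np.where(s == 1, p1, p0)
            records[:, col[sid]] = rng.random(spec.n) < p
    for sid, m in spec.marginal_only.items():
        records[:, col[sid]] = rng.random(spec.n) < m
    return Cohort(catalog, records)


def spec_to_model(spec: GeneratorSpec) -> LatentTreeModel:
    """The generator as a latent tree: the first latent is the root, the
    other latents its children (coupling rows, or identical rows when the
    topology is independent — a chain topology is reparented to a star with
    the marginally-equivalent tables only when couplings are absent), block
    symptoms hang under their latent, marginal-only symptoms under the root
    with state-independent rows."""
    if spec.topology == "chain" and spec.coupling:
        raise ValueError("chain coupling has no exact star tree; "
                         "use topology='independent' or 'star'")
    root = spec.blocks[0].latent
    kind = {root: LATENT}
    card = {root: 2}
    parent: dict[str, str | None] = {root: None}
    cpts: dict[str, np.ndarray] = {
        root: np.array([1 - spec.blocks[0].prior, spec.blocks[0].prior])}
    for b in spec.blocks[1:]:
        kind[b.latent] = LATENT
        card[b.latent] = 2
        parent[b.latent] = root
        if spec.topology == "star" and b.latent in spec.coupling:
            cpts[b.latent] = np.asarray(spec.coupling[b.latent], dtype=float)
        else:
            cpts[b.latent] = np.array([[1 - b.prior, b.prior]] * 2)
    for b in spec.blocks:
        for sid, p1, p0 in b.rows:
            kind[sid] = OBSERVED
            card[sid] = 2
            parent[sid] = b.latent
            cpts[sid] = np.array([[1 - p0, p0], [1 - p1, p1]])
    for sid, m in spec.marginal_only.items():
        kind[sid] = OBSERVED
        card[sid] = 2
        parent[sid] = root
        cpts[sid] = np.array([[1 - m, m], [1 - m, m]])
    return LatentTreeModel(kind, card, parent, cpts)
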