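"""Interpretation of a fitted latent tree: what each pattern variable means.

Each latent variable is read through (i) its mutual information with every
symptom, summarized as a cumulative information-coverage curve cut at 95%,
(ii) its class-conditional probability table P(X=1 | Y=S1) vs P(X=1 | Y=S0)
over the symptoms it covers, and (iii) per-patient posterior (soft) and
thresholded (hard) assignments to each pattern.  States are first
relabelled canonically so that S1 is always the higher-symptom-burden
class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .model import (LatentTreeModel, node_marginals, posterior_marginals_batch)
from .screening import round_half_up


# ---------------------------------------------------------------------------
# Exact pairwise distributions on the tree
# ---------------------------------------------------------------------------

def _path(model: LatentTreeModel, a: str, b: str) -> list[str]:
    """Node sequence a..b along the unique tree path."""
    anc_a = [a]
    while model.parent[anc_a[-1]] is not None:
        anc_a.append(model.parent[anc_a[-1]])
    anc_b = [b]
    while model.parent[anc_b[-1]] is not None:
        anc_b.append(model.parent[anc_b[-1]])
    set_a = set(anc_a)
    lca = next(x for x in anc_b if x in set_a)
    up = anc_a[:anc_a.index(lca) + 1]
    down = anc_b[:anc_b.index(lca)]
    return up + list(reversed(down))


def conditional_given(model: LatentTreeModel, source: str, target: str,
                      marg: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Exact P(target | source) as a (card_source, card_target) matrix,
    marginalizing every node on the tree path between them."""
    if source == target:
        raise ValueError(f"source and target are the same node {source!r}")
    marg = marg if marg is not None else node_marginals(model)
    path = _path(model, source, target)
    M = np.eye(model.card[source])
    for u, v in zip(path, path[1:]):
        if model.parent[v] == u:          # downward edge: rows u -> cols v
            step = model.cpts[v]
        else:                             # upward edge: Bayes-invert CPT of u
            mu, mv = marg[u], marg[v]
            step = (model.cpts[u].T * mv[None, :]) / np.where(mu > 0, mu, 1.0)[:, None]
            step = step / np.maximum(step.sum(axis=1, keepdims=True), 1e-300)
        M = M @ step
    return M


def mutual_information(model: LatentTreeModel, latent: str,
                       observable: str) -> float:
    """I(Y; X) in bits, computed exactly from the model distribution."""
    if latent == observable:
        raise ValueError("latent and observable must differ")
    if latent not in model.latents:
        raise ValueError(f"{latent!r} is not a latent node")
    if observable not in model.leaves:
        raise ValueError(f"{observable!r} is not an observed leaf")
    marg = node_marginals(model)
    cond = conditional_given(model, latent, observable, marg)
    py = marg[latent]
    joint = py[:, None] * cond                      # P(y, x)
    px = joint.sum(axis=0)
    denom = py[:, None] * px[None, :]
    mask = joint > 0
    return float((joint[mask] * np.log2(joint[mask] / denom[mask])).sum())


# ---------------------------------------------------------------------------
# Coverage curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageRow:
    symptom: str
    mi_bits: float
    cum_coverage: float


@dataclass(frozen=True)
class CoverageCurve:
    latent: str
    rows: tuple[CoverageRow, ...]
    threshold: float

    @property
    def covered(self) -> tuple[str, ...]:
        """Minimal prefix of symptoms reaching the coverage threshold."""
        out = []
        for row in self.rows:
            out.append(row.symptom)
            if row.cum_coverage >= self.threshold - 1e-12:
                break
        return tuple(out)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("rank\tsymptom\tmi_bits\tcum_coverage\n")
            for r, row in enumerate(self.rows, start=1):
                fh.write(f"{r}\t{row.symptom}\t{row.mi_bits:.6f}"
                         f"\t{row.cum_coverage:.6f}\n")


def coverage_curve(model: LatentTreeModel, latent: str,
                   threshold: float = 0.95,
                   normalize: str = "total_mi") -> CoverageCurve:
    """Symptoms ranked by I(Y; X), with cumulative information coverage;
    the covered set is the shortest prefix reaching the threshold.

    ``normalize`` picks the denominator: the latent's total mutual
    information over all leaves (default; the curve ends at 1), or the
    latent's entropy H(Y) in bits (the curve ends at the fraction of the
    latent's uncertainty the symptoms resolve, typically < 1).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    mis = sorted(((mutual_information(model, latent, x), x)
                  for x in model.leaves),
                 key=lambda t: (-t[0], t[1]))
    if sum(m for m, _ in mis) <= 0:
        raise ValueError(f"latent {latent!r} carries no information "
                         "about any observable")
    if normalize == "total_mi":
        total = sum(m for m, _ in mis)
    elif normalize == "entropy":
        py = node_marginals(model)[latent]
        nz = py[py > 0]
        total = float(-(nz * np.log2(nz)).sum())
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    rows, cum = [], 0.0
    for m, x in mis:
        cum += m / total
        # redundant leaves can push summed MI past H(Y) under entropy
        # normalization; only the total-MI curve is capped at 1
        rows.append(CoverageRow(x, m, min(cum, 1.0) if normalize == "total_mi"
                                else cum))
    return CoverageCurve(latent, tuple(rows), threshold)


# ---------------------------------------------------------------------------
# Class-conditional probability tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CPDRow:
    symptom: str
    p_s1: float      # P(X = 1 | Y = S1)
    p_s0: float      # P(X = 1 | Y = S0)


@dataclass(frozen=True)
class CPDTable:
    latent: str
    rows: tuple[CPDRow, ...]

    def __getitem__(self, symptom: str) -> CPDRow:
        for row in self.rows:
            if row.symptom == symptom:
                return row
        raise KeyError(symptom)

    def to_tsv(self, path: str | Path) -> None:
        """Printed-table layout: probabilities rounded half-up, 2 decimals."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("symptom\tP_S1\tP_S0\n")
            for row in self.rows:
                fh.write(f"{row.symptom}\t{round_half_up(row.p_s1):.2f}"
                         f"\t{round_half_up(row.p_s0):.2f}\n")


def class_conditional_table(model: LatentTreeModel, latent: str,
                            leaves: list[str] | None = None) -> CPDTable:
    """P(X=1 | Y=S1) and P(X=1 | Y=S0) for each requested leaf (all leaves
    by default), exact under the model; state index 1 is taken as S1."""
    if latent not in model.latents:
        raise ValueError(f"{latent!r} is not a latent node")
    marg = node_marginals(model)
    rows = []
    for x in (leaves if leaves is not None else model.leaves):
        cond = conditional_given(model, latent, x, marg)
        rows.append(CPDRow(x, float(cond[1, 1]), float(cond[0, 1])))
    return CPDTable(latent, tuple(rows))


# ---------------------------------------------------------------------------
# Canonical state labels and pattern assignment
# ---------------------------------------------------------------------------

def canonical_state_labels(model: LatentTreeModel,
                           threshold: float = 0.95) -> LatentTreeModel:
    """Relabel every binary latent so state 1 (S1) is the class with the
    larger mean symptom-presence probability over the latent's covered
    leaves.  The model distribution is unchanged; idempotent."""
    out = model.copy()
    for y in model.latents:
        if model.card[y] != 2:
            raise ValueError(f"canonical labels need binary latents; "
                             f"{y!r} has cardinality {model.card[y]}")
        try:
            leaves = list(coverage_curve(out, y, threshold).covered)
        except ValueError:
            leaves = out.leaves                 # uninformative latent
        table = class_conditional_table(out, y, leaves)
        m1 = float(np.mean([r.p_s1 for r in table.rows]))
        m0 = float(np.mean([r.p_s0 for r in table.rows]))
        if m1 == m0:
            warnings.warn(f"latent {y!r}: exact tie in mean class-conditional "
                          "probabilities; keeping input state order")
        elif m0 > m1:
            out = out.permute_states(y, [1, 0])
    return out


def assign_patterns(model: LatentTreeModel, cohort: Cohort) -> pd.DataFrame:
    """Soft and hard per-patient pattern assignment.

    Returns a tidy frame (patient, latent, posterior_s1, hard_label) where
    ``posterior_s1`` is the exact posterior of the high-burden state and the
    hard label is S1 only when that posterior exceeds 0.5 (ties go to S0).
    """
    post = posterior_marginals_batch(model, cohort)
    frames = []
    for y in model.latents:
        p1 = post[y][:, 1]
        frames.append(pd.DataFrame({
            "patient": np.arange(cohort.n),
            "latent": y,
            "posterior_s1": p1,
            "hard_label": np.where(p1 > 0.5, "S1", "S0"),
        }))
    return pd.concat(frames, ignore_index=True)


def write_assignments(assignments: pd.DataFrame, path: str | Path) -> None:
    assignments.to_csv(path, sep="\t", index=False, float_format="%.6f")
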