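"""Symptom frequency analysis and expert-guided variable selection.

Before a latent structure model is learned, the questionnaire's symptom set
is screened down to the variables worth modelling: each symptom's observed
frequency in the cohort is combined with a panel-of-experts diagnosticity
score, and the top ``k`` symptoms under a mean-of-ranks rule are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np

from .cohort import MISSING, Cohort


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention of printed frequency tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencyRow:
    symptom: str
    count: int
    n: int          # non-missing denominator for this symptom

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.count / self.n) if self.n else 0.0


@dataclass(frozen=True)
class FrequencyTable:
    rows: tuple[FrequencyRow, ...]

    def __getitem__(self, symptom: str) -> FrequencyRow:
        for row in self.rows:
            if row.symptom == symptom:
                return row
        raise KeyError(symptom)

    def counts(self) -> dict[str, int]:
        return {r.symptom: r.count for r in self.rows}

    def to_tsv(self, path: str | Path) -> None:
        """Report in the printed-table layout: ``symptom<TAB>count (percent%)``."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("symptom\tcount (percent)\n")
            for r in self.rows:
                fh.write(f"{r.symptom}\t{r.count} ({r.percent:.2f}%)\n")


#: Expert diagnosticity scores: symptom id -> mean panel score (higher = more
#: diagnostic).  Symptoms absent from the mapping are treated as score 0.
ExpertScores = Mapping[str, float]


def read_expert_scores(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV (symptom id, mean score)."""
    scores: dict[str, float] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            sid, value = line.split("\t")[:2]
            scores[sid] = float(value)
    return scores


def symptom_frequencies(cohort: Cohort) -> FrequencyTable:
    """Per-symptom presence counts and percentages over non-missing answers."""
    if cohort.n == 0:
        raise ValueError("empty cohort: frequencies need at least one record")
    rows = []
    for j, sid in enumerate(cohort.catalog.ids):
        col = cohort.records[:, j]
        nonmiss = int((col != MISSING).sum())
        rows.append(FrequencyRow(sid, int((col == 1).sum()), nonmiss))
    return FrequencyTable(tuple(rows))


def _descending_ranks(values: dict[str, float]) -> dict[str, float]:
    # average rank over ties, rank 1 = largest value
    items = sorted(values.items(), key=lambda kv: -kv[1])
    ranks: dict[str, float] = {}
    i = 0
    while i < len(items):
        j = i
        while j < len(items) and items[j][1] == items[i][1]:
            j += 1
        avg = (i + 1 + j) / 2.0  # mean of ranks i+1 .. j
        for k in range(i, j):
            ranks[items[k][0]] = avg
        i = j
    return ranks


def select_variables(freq: FrequencyTable, scores: ExpertScores, k: int) -> list[str]:
    """Top-``k`` symptoms by the mean of frequency rank and expert-score rank.

    Both rankings are descending (rank 1 = highest).  The combined key is
    ``(rank_f + rank_s) / 2``; ties are broken by higher frequency, then by
    symptom id.  Symptoms missing from ``scores`` score 0.
    """
    symptoms = [r.symptom for r in freq.rows]
    if not 1 <= k <= len(symptoms):
        raise ValueError(f"k={k} outside 1..{len(symptoms)}")
    fvals = {r.symptom: r.count / r.n if r.n else 0.0 for r in freq.rows}
    svals = {s: float(scores.get(s, 0.0)) for s in symptoms}
    rank_f = _descending_ranks(fvals)
    rank_s = _descending_ranks(svals)
    key = lambda s: ((rank_f[s] + rank_s[s]) / 2.0, -fvals[s], s)
    return sorted(symptoms, key=key)[:k]
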