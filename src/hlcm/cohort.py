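"""Binary symptom cohorts: the canonical patient x symptom matrix.

A cohort is an ``n x k`` matrix of inquiry answers over a fixed symptom
catalog.  Answers are coded ``1`` (symptom present / "yes"), ``0`` (absent /
"no"), or missing.  The on-disk form is a delimited text file whose header
row names the symptoms; cells hold ``1``/``0``/``NA`` canonically, with
yes/no synonyms tolerated on input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Sentinel used in the integer record matrix for a missing answer.
MISSING: int = -1

#: Default cell-token coding, applied case-insensitively after stripping.
DEFAULT_CODING: Mapping[str, int] = {
    "1": 1, "yes": 1, "y": 1,
    "0": 0, "no": 0, "n": 0,
    "": MISSING, "na": MISSING,
}

_DELIMS = {"csv": ",", "tsv": "\t"}


class CohortFormatError(ValueError):
    """Malformed cohort file (bad header, duplicate column, ragged row)."""


class CohortCodingError(ValueError):
    """A cell token outside the declared coding, located by row and column."""


@dataclass(frozen=True)
class SymptomCatalog:
    """Ordered list of symptom (id, label) pairs; order is significant."""

    symptoms: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.symptoms]
        if any(not s for s in ids):
            raise ValueError("symptom ids must be non-empty")
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate symptom ids: {dupes}")

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "SymptomCatalog":
        return cls(tuple((i, i) for i in ids))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.symptoms)

    def index(self, symptom_id: str) -> int:
        return self.ids.index(symptom_id)

    def __len__(self) -> int:
        return len(self.symptoms)

    def label(self, symptom_id: str) -> str:
        return dict(self.symptoms)[symptom_id]


@dataclass
class Cohort:
    """An ``n x k`` answer matrix over a symptom catalog.

    ``records`` holds int8 values in {0, 1, MISSING}; rows are patients in
    input order, columns follow the catalog order.
    """

    catalog: SymptomCatalog
    records: np.ndarray = field(default_factory=lambda: np.empty((0, 0), np.int8))

    def __post_init__(self) -> None:
        self.records = np.asarray(self.records, dtype=np.int8)
        if self.records.size == 0:
            self.records = self.records.reshape(0, len(self.catalog))
        if self.records.ndim != 2:
            raise ValueError("records must be a 2-D matrix")

    @property
    def n(self) -> int:
        return self.records.shape[0]

    def column(self, symptom_id: str) -> np.ndarray:
        return self.records[:, self.catalog.index(symptom_id)]

    def subset(self, ids: Sequence[str]) -> "Cohort":
        """New cohort restricted to (and reordered by) the given symptom ids."""
        idx = [self.catalog.index(i) for i in ids]
        cat = SymptomCatalog(tuple(self.catalog.symptoms[j] for j in idx))
        return Cohort(cat, self.records[:, idx].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (self.catalog == other.catalog
                and self.records.shape == other.records.shape
                and bool(np.array_equal(self.records, other.records)))


def read_cohort(path: str | Path, dialect: str = "tsv",
                coding: Mapping[str, int] | None = None) -> Cohort:
    """Parse a delimited cohort file into a :class:`Cohort`.

    The first row names symptoms; every cell is decoded through ``coding``
    (case-insensitive, whitespace-stripped).  Unknown tokens raise
    :class:`CohortCodingError` naming the 1-based data row and the column id.
    """
    coding = {k.lower(): v for k, v in (coding or DEFAULT_CODING).items()}
    delim = _DELIMS[dialect]
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFormatError(f"{path}: empty file, header row required")
        header = [h.strip() for h in header]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise CohortFormatError(f"{path}: duplicate column(s) {dupes}")
        rows: list[list[int]] = []
        for r, raw in enumerate(reader, start=1):
            if len(raw) != len(header):
                raise CohortFormatError(
                    f"{path}: row {r} has {len(raw)} cells, expected {len(header)}")
            out = []
            for c, cell in enumerate(raw):
                token = cell.strip().lower()
                if token not in coding:
                    raise CohortCodingError(
                        f"{path}: unknown token {cell!r} at row {r}, "
                        f"column {header[c]!r}")
                out.append(coding[token])
            rows.append(out)
    records = np.array(rows, dtype=np.int8).reshape(len(rows), len(header))
    return Cohort(SymptomCatalog.from_ids(header), records)


def write_cohort(cohort: Cohort, path: str | Path, dialect: str = "tsv") -> None:
    """Write a cohort in canonical coding (1 / 0 / NA), UTF-8, header first."""
    delim = _DELIMS[dialect]
    token = {1: "1", 0: "0", MISSING: "NA"}
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(cohort.catalog.ids)
        for row in cohort.records:
            writer.writerow([token[int(v)] for v in row])


def validate_cohort(cohort: Cohort) -> list[str]:
    """Return human-readable invariant violations (empty list iff valid)."""
    problems: list[str] = []
    ids = [s for s, _ in cohort.catalog.symptoms]
    for dup in sorted({s for s in ids if ids.count(s) > 1}):
        problems.append(f"duplicate symptom id {dup!r} in catalog")
    k = len(cohort.catalog)
    if cohort.records.shape[1] != k:
        problems.append(
            f"record matrix has {cohort.records.shape[1]} columns, "
            f"catalog has {k}")
        return problems
    bad = ~np.isin(cohort.records, (0, 1, MISSING))
    for r, c in zip(*np.nonzero(bad)):
        problems.append(
            f"invalid value {int(cohort.records[r, c])} at row {r}, "
            f"column {ids[c]!r}")
    if k > 0:
        all_missing = (cohort.records == MISSING).all(axis=1)
        for r in np.nonzero(all_missing)[0]:
            problems.append(f"row {int(r)} has no non-missing answer")
    return problems


def read_catalog(path: str | Path) -> SymptomCatalog:
    """Read a two-column TSV (id, label) symptom catalog."""
    entries = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            entries.append((parts[0], parts[1] if len(parts) > 1 else parts[0]))
    return SymptomCatalog(tuple(entries))


def write_catalog(catalog: SymptomCatalog, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for sid, label in catalog.symptoms:
            fh.write(f"{sid}\t{label}\n")
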