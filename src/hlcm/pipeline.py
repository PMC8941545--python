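"""End-to-end orchestration: load -> screen -> learn -> interpret -> report.

A single master seed fans out to per-stage seeds (stage ``i`` gets
``SeedSequence(master).generate_state(4)[i] % 2**31``), so each stage is
independently reproducible and a rerun with the same config reproduces
every numeric output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import read_cohort, validate_cohort
from .interpret import (assign_patterns, canonical_state_labels,
                        class_conditional_table, coverage_curve,
                        write_assignments)
from .screening import read_expert_scores, select_variables, symptom_frequencies
from .search import SearchConfig, dhc_search

log = logging.getLogger("hlcm")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    cohort: str
    outdir: str = "hlcm_out"
    expert_scores: str | None = None
    label_map: dict[str, str] = field(default_factory=dict)
    k: int = 30
    coverage_threshold: float = 0.95
    seed: int = 0
    dialect: str = "tsv"
    search: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**doc)


def stage_seeds(master: int) -> dict[str, int]:
    state = np.random.SeedSequence(master).generate_state(4)
    names = ("screen", "search", "interpret", "spare")
    return {n: int(s) % (2 ** 31) for n, s in zip(names, state)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)

    def stage(name):
        log.info("stage %s", name)
        return name

    name = stage("load")
    try:
        cohort = read_cohort(config.cohort, dialect=config.dialect)
        problems = validate_cohort(cohort)
        if problems:
            raise ValueError("; ".join(problems[:5]))
        if config.k > len(cohort.catalog):
            raise ValueError(f"k={config.k} exceeds catalog size "
                             f"{len(cohort.catalog)}")
    except Exception as e:
        raise PipelineError(f"stage {name}: {e}") from e

    name = stage("screen")
    try:
        freq = symptom_frequencies(cohort)
        freq.to_tsv(out / "frequencies.tsv")
        scores = (read_expert_scores(config.expert_scores)
                  if config.expert_scores else {})
        selected = select_variables(freq, scores, config.k)
        (out / "selected_symptoms.txt").write_text(
            "\n".join(selected) + "\n", encoding="utf-8")
        modeling = cohort.subset(selected)
    except Exception as e:
        raise PipelineError(f"stage {name}: {e}") from e

    name = stage("learn")
    try:
        scfg = SearchConfig(seed=seeds["search"], **config.search)
        model, trace = dhc_search(modeling, scfg)
        trace.to_tsv(out / "trace.tsv")
        log.info("learned %d latents, BIC %.2f", len(model.latents),
                 trace.final_bic)
    except Exception as e:
        raise PipelineError(f"stage {name}: {e}") from e

    name = stage("interpret")
    try:
        model = canonical_state_labels(model, config.coverage_threshold)
        model.metadata["version"] = __version__
        model.save(out / "model.json")
        covered: dict[str, list[str]] = {}
        for y in model.latents:
            curve = coverage_curve(model, y, config.coverage_threshold)
            curve.to_tsv(out / f"coverage_{y}.tsv")
            covered[y] = list(curve.covered)
            table = class_conditional_table(model, y, covered[y])
            table.to_tsv(out / f"cpd_{y}.tsv")
        assignments = assign_patterns(model, modeling)
        write_assignments(assignments, out / "assignments.tsv")
    except Exception as e:
        raise PipelineError(f"stage {name}: {e}") from e

    report = {
        "version": __version__,
        "n": cohort.n,
        "k_selected": len(selected),
        "selected": selected,
        "latent_count": len(model.latents),
        "final_bic": float(trace.final_bic),
        "search_steps": len(trace.steps) - 1,
        "covered": covered,
        "labels": {y: config.label_map.get(y, y) for y in model.latents},
        "seeds": {"master": config.seed, **seeds},
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True),
                                     encoding="utf-8")
    return report
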