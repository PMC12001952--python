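"""End-to-end orchestration: atoms -> algorithms -> filters -> cohorts.

This is the library face of the pipeline; the CLI and the examples are thin
wrappers around :func:`run_pipeline`.  Every configurable default actually
used (code sets, thresholds, exclusion scope) is logged, so an analysis can
be audited from its log alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import vocab
from .atoms import AtomResult, compute_all_atoms
from .engine import (
    AlgorithmSpec,
    CohortResult,
    apply_age_filter,
    apply_older_age_exclusion,
    evaluate,
    qualifying_dates,
    AGE_BOUNDS,
)
from .model import AnalysisWindow, CodeSet, CodedRecordTables, age_at

log = logging.getLogger("casefinder")

__all__ = ["PipelineSettings", "build_cohort", "run_pipeline",
           "eligible_population", "cohorts_to_frames"]


@dataclass(frozen=True)
class PipelineSettings:
    """Every tunable the cohort-building stages consult."""

    psychosis_codeset: CodeSet = vocab.PSYCHOSIS_ICD10
    cluster_codeset: CodeSet = vocab.PSYCHOSIS_CLUSTERS
    honos_item_map: Mapping[str, int] = field(
        default_factory=lambda: dict(vocab.HONOS_ITEM_MAP)
    )
    honos_threshold: int = vocab.HONOS_THRESHOLD
    include_secondary_dx: bool = False
    exclusion_codesets: tuple[CodeSet, ...] = (
        vocab.DEMENTIA_ICD10,
        vocab.PSYCHOTIC_DEPRESSION_ICD10,
    )
    older_exclusion_band: tuple[int, int] = (55, 65)
    #: apply the 55-65 exclusion to every cohort member, not only those with
    #: first-episode evidence
    strict_older_exclusion: bool = False

    def log_provenance(self) -> None:
        log.info("psychosis code set: %s (%s)",
                 sorted(map(str, self.psychosis_codeset.codes)),
                 self.psychosis_codeset.match_mode)
        log.info("psychosis clusters: %s", sorted(self.cluster_codeset.codes))
        log.info("HoNOS item map %s, threshold >= %d",
                 dict(self.honos_item_map), self.honos_threshold)
        log.info("older-age exclusion: ages %d-%d, code sets %s, strict=%s",
                 *self.older_exclusion_band,
                 [c.name for c in self.exclusion_codesets],
                 self.strict_older_exclusion)


def build_cohort(
    spec: AlgorithmSpec,
    atoms: Mapping[str, AtomResult],
    tables: CodedRecordTables,
    window: AnalysisWindow,
    settings: PipelineSettings = PipelineSettings(),
) -> CohortResult:
    """Evaluate one algorithm and apply the age and older-age exclusions."""
    raw = evaluate(spec, atoms, window)
    qd = qualifying_dates(spec, atoms, raw)
    filtered = apply_age_filter(raw, tables.patients, spec.mode, qd)
    first_episode = atoms["FEP"].patients | atoms["R01"].patients
    return apply_older_age_exclusion(
        filtered,
        tables.patients,
        tables.diagnoses,
        settings.exclusion_codesets,
        window=window,
        qual_dates=qd,
        age_band=settings.older_exclusion_band,
        first_episode_members=first_episode,
        strict=settings.strict_older_exclusion,
    )


def run_pipeline(
    tables: CodedRecordTables,
    specs: Sequence[AlgorithmSpec],
    window: AnalysisWindow,
    settings: PipelineSettings = PipelineSettings(),
) -> list[CohortResult]:
    """Atoms, algorithm evaluation and filters for one window."""
    settings.log_provenance()
    atoms = compute_all_atoms(
        tables, window,
        psychosis_codeset=settings.psychosis_codeset,
        cluster_codeset=settings.cluster_codeset,
        honos_item_map=settings.honos_item_map,
        honos_threshold=settings.honos_threshold,
        include_secondary_dx=settings.include_secondary_dx,
    )
    for label, res in atoms.items():
        log.info("atom %s: %d patient(s) in %s", label, len(res), window.label)
    cohorts = []
    for spec in specs:
        cohort = build_cohort(spec, atoms, tables, window, settings)
        log.info("algorithm %s (%s, %s): %d patient(s)",
                 spec.id, spec.expression_text, spec.mode, cohort.count)
        cohorts.append(cohort)
    return cohorts


def eligible_population(
    tables: CodedRecordTables, window: AnalysisWindow, mode: str = "prevalent"
) -> frozenset[str]:
    """Post-age-filter patient universe used as the metrics denominator.

    Ages are taken at the window start; the same band applies as the cohort
    age filter for the given mode.
    """
    lo, hi = AGE_BOUNDS[mode]
    out = set()
    for pid, birth in zip(
        tables.patients["patient_id"].astype(str), tables.patients["birth_date"]
    ):
        if pd.isna(birth):
            continue
        a = age_at(birth.date(), window.start)
        if lo <= a <= hi:
            out.add(pid)
    return frozenset(out)


def cohorts_to_frames(
    cohorts: Sequence[CohortResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (algorithm_id, window, patient_id) rows plus a count summary."""
    rows = [
        {"algorithm_id": c.algorithm_id, "window": c.window.label, "patient_id": p}
        for c in cohorts
        for p in sorted(c.patients)
    ]
    members = pd.DataFrame(rows, columns=["algorithm_id", "window", "patient_id"])
    summary = pd.DataFrame(
        [{"algorithm_id": c.algorithm_id, "window": c.window.label,
          "count": c.count} for c in cohorts],
        columns=["algorithm_id", "window", "count"],
    ).sort_values(["algorithm_id", "window"]).reset_index(drop=True)
    return members, summary
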