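"""Criteria atoms: one data element evaluated to a per-window patient set.

Each of the six MHSDS data elements usable for psychosis case finding is
evaluated independently to an :class:`AtomResult` — the set of patients with
at least one in-window qualifying record — under one of eight atom labels:

========  ==========================================================
label     qualifying record
========  ==========================================================
DX        primary diagnosis matching the psychosis code set
R01       referral with reason code 01 ((suspected) first episode)
R02       referral with reason code 02 (ongoing/recurrent psychosis)
R18       referral with reason code 18 (in crisis)
CLUSTER   assignment to a psychosis mental-health cluster
HONOS     hallucinations/delusions item scored >= threshold
FEP       first-episode-psychosis flag
EIP       early-intervention-in-psychosis team flag
========  ==========================================================

A psychosis-indicating record always wins contradictions: a patient assigned
both a psychosis and a non-psychosis cluster in the window is in the CLUSTER
atom.  Alongside the set, each result carries the earliest qualifying date
per patient, which downstream age filters use as the "at diagnosis" date.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import pandas as pd

from .model import AnalysisWindow, CodeSet, CodedRecordTables, HONOS_MISSING
from . import vocab

__all__ = [
    "ATOM_LABELS",
    "INDEPENDENT_ATOMS",
    "JOINT_ONLY_ATOMS",
    "AtomResult",
    "atom_primary_diagnosis",
    "atom_referral",
    "atom_cluster",
    "atom_honos",
    "atom_flag",
    "compute_all_atoms",
]

ATOM_LABELS = ("DX", "R01", "R02", "R18", "CLUSTER", "HONOS", "FEP", "EIP")

#: Elements judged usable on their own to ascertain cases.
INDEPENDENT_ATOMS = frozenset({"DX", "R02", "FEP", "EIP"})

#: Elements that must be combined (AND) with others before contributing.
JOINT_ONLY_ATOMS = frozenset({"CLUSTER", "HONOS", "R01", "R18"})


@dataclass(frozen=True)
class AtomResult:
    """Patients satisfying one data-element criterion within a window."""

    atom: str
    window: AnalysisWindow
    patients: frozenset[str]
    #: earliest in-window qualifying date per patient
    first_dates: Mapping[str, date] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.atom not in ATOM_LABELS:
            raise ValueError(f"unknown atom label {self.atom!r}")

    def __len__(self) -> int:
        return len(self.patients)


def _result(atom: str, window: AnalysisWindow, df: pd.DataFrame,
            date_col: str) -> AtomResult:
    """Collapse qualifying rows to a patient set with earliest dates."""
    if df.empty:
        return AtomResult(atom, window, frozenset())
    firsts = df.groupby(df["patient_id"].astype(str))[date_col].min()
    return AtomResult(
        atom,
        window,
        frozenset(firsts.index),
        {pid: ts.date() for pid, ts in firsts.items()},
    )


def atom_primary_diagnosis(
    diagnoses: pd.DataFrame,
    codeset: CodeSet = vocab.PSYCHOSIS_ICD10,
    window: AnalysisWindow | None = None,
    *,
    include_secondary: bool = False,
) -> AtomResult:
    """DX: at least one in-window primary diagnosis in the psychosis code set.

    Only ``rank="primary"`` records count by default — the main condition
    treated or investigated during the episode of care; set
    ``include_secondary`` for sensitivity analyses.
    """
    keep = diagnoses["rank"].eq("primary")
    if include_secondary:
        keep = keep | diagnoses["rank"].eq("secondary")
    keep = keep & window.mask(diagnoses["record_date"])
    keep = keep & codeset.mask(diagnoses["code"])
    return _result("DX", window, diagnoses.loc[keep], "record_date")


def atom_referral(
    referrals: pd.DataFrame,
    code: str,
    window: AnalysisWindow,
    *,
    reason_vocabulary: frozenset[str] = vocab.REFERRAL_REASONS,
) -> AtomResult:
    """R01/R02/R18: at least one in-window referral with the given reason code."""
    if code not in reason_vocabulary:
        raise ValueError(f"reason code {code!r} not in the referral vocabulary")
    if code not in ("01", "02", "18"):
        raise ValueError(f"reason code {code!r} is not a psychosis-relevant code")
    keep = referrals["reason_code"].eq(code) & window.mask(referrals["referral_date"])
    return _result(f"R{code}", window, referrals.loc[keep], "referral_date")


def atom_cluster(
    assignments: pd.DataFrame,
    codeset: CodeSet = vocab.PSYCHOSIS_CLUSTERS,
    window: AnalysisWindow | None = None,
) -> AtomResult:
    """CLUSTER: at least one in-window psychosis-cluster assignment.

    Other, non-psychosis assignments for the same patient are irrelevant: the
    psychosis-indicating record wins contradictions.
    """
    keep = codeset.mask(assignments["cluster_code"]) & window.mask(
        assignments["assignment_date"]
    )
    return _result("CLUSTER", window, assignments.loc[keep], "assignment_date")


def atom_honos(
    assessments: pd.DataFrame,
    item_map: Mapping[str, int] = vocab.HONOS_ITEM_MAP,
    threshold: int = vocab.HONOS_THRESHOLD,
    window: AnalysisWindow | None = None,
) -> AtomResult:
    """HONOS: hallucinations/delusions item scored at or above ``threshold``.

    The item number is version-dependent (item 6, 7 or 8); every version
    present in the data must appear in ``item_map``.  The missing-score
    sentinel never qualifies, whatever the threshold.
    """
    if not 0 <= threshold <= 4:
        raise ValueError(f"threshold {threshold} outside the 0-4 score range")
    in_win = assessments.loc[window.mask(assessments["assessment_date"])]
    unknown = set(in_win["version"].unique()) - set(item_map)
    if unknown:
        raise ValueError(f"HoNOS version(s) {sorted(unknown)} absent from item map")
    target_item = in_win["version"].map(dict(item_map))
    keep = (
        in_win["item_id"].eq(target_item)
        & in_win["score"].ne(HONOS_MISSING)
        & in_win["score"].ge(threshold)
    )
    return _result("HONOS", window, in_win.loc[keep.fillna(False)], "assessment_date")


def atom_flag(
    flags: pd.DataFrame, flag_type: str, window: AnalysisWindow
) -> AtomResult:
    """FEP/EIP: at least one in-window administrative flag of the given type."""
    if flag_type not in ("FEP", "EIP"):
        raise ValueError(f"unknown flag type {flag_type!r}")
    keep = flags["flag_type"].eq(flag_type) & window.mask(flags["flag_date"])
    return _result(flag_type, window, flags.loc[keep], "flag_date")


def compute_all_atoms(
    tables: CodedRecordTables,
    window: AnalysisWindow,
    *,
    psychosis_codeset: CodeSet = vocab.PSYCHOSIS_ICD10,
    cluster_codeset: CodeSet = vocab.PSYCHOSIS_CLUSTERS,
    honos_item_map: Mapping[str, int] = vocab.HONOS_ITEM_MAP,
    honos_threshold: int = vocab.HONOS_THRESHOLD,
    include_secondary_dx: bool = False,
) -> dict[str, AtomResult]:
    """Evaluate all eight atoms over one window."""
    return {
        "DX": atom_primary_diagnosis(
            tables.diagnoses, psychosis_codeset, window,
            include_secondary=include_secondary_dx,
        ),
        "R01": atom_referral(tables.referrals, "01", window),
        "R02": atom_referral(tables.referrals, "02", window),
        "R18": atom_referral(tables.referrals, "18", window),
        "CLUSTER": atom_cluster(tables.clusters, cluster_codeset, window),
        "HONOS": atom_honos(tables.honos, honos_item_map, honos_threshold, window),
        "FEP": atom_flag(tables.flags, "FEP", window),
        "EIP": atom_flag(tables.flags, "EIP", window),
    }
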