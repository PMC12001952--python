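"""Shared fixtures and independent brute-force oracles.

The oracles re-derive every result by per-row / per-patient Python loops,
deliberately avoiding the package's vectorised set-algebra paths, so that
engine results can be checked against a second, independent computation.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from casefinder.engine import And, Leaf, Or
from casefinder.model import AnalysisWindow, CodedRecordTables
from casefinder import vocab

WINDOW = AnalysisWindow("2018-2019", date(2018, 4, 1), date(2019, 4, 1))

PSYCHOSIS_PREFIXES = ("F20", "F21", "F22", "F23", "F24", "F25", "F28", "F29")


# ---------------------------------------------------------------------------
# Table construction helpers


def make_tables(
    patients=(), diagnoses=(), referrals=(), clusters=(), honos=(), flags=()
) -> CodedRecordTables:
    """Build a table set from row tuples; missing tables stay empty."""

    def frame(rows, cols, date_col):
        if not rows:
            empty = getattr(CodedRecordTables.empty(), _name)
            return empty
        df = pd.DataFrame(list(rows), columns=cols)
        df[date_col] = pd.to_datetime(df[date_col])
        return df

    _name = "patients"
    p = frame(patients, ["patient_id", "birth_date", "sex"], "birth_date")
    _name = "diagnoses"
    d = frame(diagnoses, ["patient_id", "record_date", "scheme", "code", "rank"],
              "record_date")
    _name = "referrals"
    r = frame(referrals, ["patient_id", "referral_date", "reason_code"],
              "referral_date")
    _name = "clusters"
    c = frame(clusters, ["patient_id", "assignment_date", "cluster_code"],
              "assignment_date")
    _name = "honos"
    h = frame(honos, ["patient_id", "assessment_date", "version", "item_id",
                      "score"], "assessment_date")
    _name = "flags"
    f = frame(flags, ["patient_id", "flag_type", "flag_date"], "flag_date")
    return CodedRecordTables(patients=p, diagnoses=d, referrals=r, clusters=c,
                             honos=h, flags=f)


def random_fixture(rng: np.random.Generator, n_patients: int,
                   window: AnalysisWindow = WINDOW) -> CodedRecordTables:
    """A random small table set, built independently of the package's
    synthetic generator: rows fall in and out of window, codes mix
    qualifying and non-qualifying values, HoNOS rows mix versions, items,
    scores and the missing sentinel."""
    pids = [f"P{i:04d}" for i in range(n_patients)]

    def rand_date():
        # spans a year either side of the window
        lo = window.start - timedelta(days=365)
        span = (window.end - window.start).days + 730
        return lo + timedelta(days=int(rng.integers(0, span)))

    patients = [(p, date(int(rng.integers(1935, 2010)), int(rng.integers(1, 13)),
                         int(rng.integers(1, 29))), "1") for p in pids]
    dx_codes = ["F20.0", "F25.1", "F29", "F31.9", "F32.9", "F41.1", "F00.1",
                "F32.3", "G30.9"]
    diagnoses = [
        (rng.choice(pids), rand_date(), "ICD10", str(rng.choice(dx_codes)),
         str(rng.choice(["primary", "secondary"])))
        for _ in range(int(rng.integers(0, 3 * n_patients)))
    ]
    referrals = [
        (rng.choice(pids), rand_date(),
         str(rng.choice(["01", "02", "18", "03", "07", "12"])))
        for _ in range(int(rng.integers(0, 2 * n_patients)))
    ]
    clusters = [
        (rng.choice(pids), rand_date(), int(rng.integers(1, 22)))
        for _ in range(int(rng.integers(0, 2 * n_patients)))
    ]
    versions = list(vocab.HONOS_ITEM_MAP)
    honos = []
    for _ in range(int(rng.integers(0, 2 * n_patients))):
        v = str(rng.choice(versions))
        honos.append((
            rng.choice(pids), rand_date(), v,
            int(rng.choice([vocab.HONOS_ITEM_MAP[v], 1, 2, 3])),
            int(rng.choice([0, 1, 2, 3, 4, 9])),
        ))
    flags = [
        (rng.choice(pids), str(rng.choice(["FEP", "EIP"])), rand_date())
        for _ in range(int(rng.integers(0, n_patients)))
    ]
    return make_tables(patients, diagnoses, referrals, clusters, honos, flags)


# ---------------------------------------------------------------------------
# Brute-force oracles (row-by-row Python loops)


def brute_atom(tables: CodedRecordTables, atom: str,
               window: AnalysisWindow) -> set[str]:
    """Naive one-pass filter for one atom under the default configuration."""
    hit: set[str] = set()
    if atom == "DX":
        for _, row in tables.diagnoses.iterrows():
            if (row["rank"] == "primary"
                    and window.contains(row["record_date"].date())
                    and str(row["code"]).startswith(PSYCHOSIS_PREFIXES)):
                hit.add(str(row["patient_id"]))
    elif atom in ("R01", "R02", "R18"):
        code = atom[1:]
        for _, row in tables.referrals.iterrows():
            if (row["reason_code"] == code
                    and window.contains(row["referral_date"].date())):
                hit.add(str(row["patient_id"]))
    elif atom == "CLUSTER":
        for _, row in tables.clusters.iterrows():
            if (10 <= int(row["cluster_code"]) <= 17
                    and window.contains(row["assignment_date"].date())):
                hit.add(str(row["patient_id"]))
    elif atom == "HONOS":
        for _, row in tables.honos.iterrows():
            if (window.contains(row["assessment_date"].date())
                    and int(row["item_id"]) == vocab.HONOS_ITEM_MAP[row["version"]]
                    and int(row["score"]) != 9
                    and int(row["score"]) >= 3):
                hit.add(str(row["patient_id"]))
    elif atom in ("FEP", "EIP"):
        for _, row in tables.flags.iterrows():
            if (row["flag_type"] == atom
                    and window.contains(row["flag_date"].date())):
                hit.add(str(row["patient_id"]))
    else:
        raise ValueError(atom)
    return hit


def brute_eval_patient(node, pid: str, atom_sets: dict[str, set[str]]) -> bool:
    """Truth-table evaluation of an expression for one patient."""
    if isinstance(node, Leaf):
        return pid in atom_sets[node.label]
    if isinstance(node, Or):
        return any(brute_eval_patient(c, pid, atom_sets) for c in node.children)
    if isinstance(node, And):
        return all(brute_eval_patient(c, pid, atom_sets) for c in node.children)
    raise TypeError(node)


def brute_eval(node, patient_ids, atom_sets: dict[str, set[str]]) -> set[str]:
    return {p for p in patient_ids if brute_eval_patient(node, p, atom_sets)}


@pytest.fixture
def window() -> AnalysisWindow:
    return WINDOW
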