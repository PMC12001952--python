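"""Data model for MHSDS-like coded record tables.

The Mental Health Services Data Set (MHSDS) covers all NHS-funded secondary
mental healthcare in England.  This module models the six coded data elements
usable for psychosis case finding — primary diagnoses (ICD-10), reasons for
referral, mental-health cluster assignments, HoNOS item scores, and the
first-episode-psychosis (FEP) and early-intervention-in-psychosis (EIP)
administrative flags — as a set of linked per-patient tables, plus the
vocabulary/code-set machinery and schema validation used by every downstream
stage.

Tables are held as pandas DataFrames inside :class:`CodedRecordTables` and
round-trip losslessly through per-table CSV files (ISO-8601 dates, codes as
strings so zero-padded referral reasons like ``"01"`` survive).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AnalysisWindow",
    "CodeSet",
    "CodedRecordTables",
    "ValidationIssue",
    "ValidationReport",
    "Vocabularies",
    "age_at",
    "financial_year",
    "read_tables",
    "write_tables",
    "validate_tables",
    "TABLE_COLUMNS",
    "DATE_COLUMNS",
    "HONOS_MISSING",
]

# ICD-10: letter + two digits, optional dotted subdivision (e.g. F20, F20.0).
_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,2})?$")

#: HoNOS "not known" sentinel; a missing score never satisfies any threshold.
HONOS_MISSING = 9

TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id", "birth_date", "sex"],
    "diagnoses": ["patient_id", "record_date", "scheme", "code", "rank"],
    "referrals": ["patient_id", "referral_date", "reason_code"],
    "clusters": ["patient_id", "assignment_date", "cluster_code"],
    "honos": ["patient_id", "assessment_date", "version", "item_id", "score"],
    "flags": ["patient_id", "flag_type", "flag_date"],
}

DATE_COLUMNS: dict[str, str] = {
    "patients": "birth_date",
    "diagnoses": "record_date",
    "referrals": "referral_date",
    "clusters": "assignment_date",
    "honos": "assessment_date",
    "flags": "flag_date",
}

_INT_COLUMNS: dict[str, list[str]] = {
    "clusters": ["cluster_code"],
    "honos": ["item_id", "score"],
}


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open date interval [start, end); a record is in-window iff
    ``start <= record date < end``."""

    label: str
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"window {self.label!r}: start {self.start} must precede end {self.end}"
            )

    def contains(self, d: date) -> bool:
        return self.start <= d < self.end

    def mask(self, dates: pd.Series) -> pd.Series:
        """Boolean in-window mask for a datetime64 Series."""
        return (dates >= pd.Timestamp(self.start)) & (dates < pd.Timestamp(self.end))


def financial_year(start_year: int) -> AnalysisWindow:
    """NHS financial year: 1 April of ``start_year`` to 31 March of the next."""
    return AnalysisWindow(
        label=f"{start_year}-{start_year + 1}",
        start=date(start_year, 4, 1),
        end=date(start_year + 1, 4, 1),
    )


@dataclass(frozen=True)
class CodeSet:
    """A named, finite set of codes with exact or prefix matching.

    Prefix mode is used for ICD-10 chapters ("F20" covers F20.0, F20.9, ...);
    within a prefix set no code may be a prefix of another, so membership is
    unambiguous.
    """

    name: str
    codes: frozenset
    match_mode: str = "exact"  # "exact" | "prefix"

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", frozenset(self.codes))
        if not self.codes:
            raise ValueError(f"code set {self.name!r} is empty")
        if self.match_mode not in ("exact", "prefix"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if self.match_mode == "prefix":
            as_str = sorted(str(c) for c in self.codes)
            for a, b in zip(as_str, as_str[1:]):
                if b.startswith(a):
                    raise ValueError(
                        f"code set {self.name!r}: {a!r} is a prefix of {b!r}; "
                        "prefix matching would be ambiguous"
                    )

    def matches(self, code) -> bool:
        if self.match_mode == "exact":
            return code in self.codes
        s = str(code)
        return any(s.startswith(str(c)) for c in self.codes)

    def mask(self, codes: pd.Series) -> pd.Series:
        """Vectorised membership mask."""
        if self.match_mode == "exact":
            return codes.isin(self.codes)
        prefixes = tuple(str(c) for c in self.codes)
        return codes.astype(str).str.startswith(prefixes)


@dataclass(frozen=True)
class Vocabularies:
    """Configured coded vocabularies the tables are validated against."""

    referral_reasons: frozenset[str]
    cluster_codes: frozenset[int]
    honos_versions: frozenset[str]
    honos_max_item: Mapping[str, int]
    flag_types: frozenset[str] = frozenset({"FEP", "EIP"})
    diagnosis_ranks: frozenset[str] = frozenset({"primary", "secondary"})
    diagnosis_schemes: frozenset[str] = frozenset({"ICD10"})


@dataclass
class CodedRecordTables:
    """The linked per-patient tables (one DataFrame per MHSDS-like table)."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    referrals: pd.DataFrame
    clusters: pd.DataFrame
    honos: pd.DataFrame
    flags: pd.DataFrame

    def __iter__(self):
        for name in TABLE_COLUMNS:
            yield name, getattr(self, name)

    @classmethod
    def empty(cls) -> "CodedRecordTables":
        frames = {}
        for name, cols in TABLE_COLUMNS.items():
            df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
            df[DATE_COLUMNS[name]] = pd.Series(dtype="datetime64[ns]")
            for c in _INT_COLUMNS.get(name, []):
                df[c] = pd.Series(dtype="int64")
            frames[name] = df[cols]
        return cls(**frames)

    def patient_ids(self) -> frozenset[str]:
        return frozenset(self.patients["patient_id"].astype(str))


@dataclass(frozen=True)
class ValidationIssue:
    table: str
    row: int | None
    field: str | None
    kind: str
    message: str


@dataclass
class ValidationReport:
    row_counts: dict[str, int] = field(default_factory=dict)
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def count(self, kind: str) -> int:
        return sum(1 for i in self.issues if i.kind == kind)

    def summary(self) -> str:
        lines = [f"{t}: {n} rows" for t, n in self.row_counts.items()]
        lines.append(f"{len(self.issues)} issue(s)")
        lines += [
            f"  [{i.kind}] {i.table} row {i.row} field {i.field}: {i.message}"
            for i in self.issues
        ]
        return "\n".join(lines)


def age_at(birth_date: date, on: date) -> int:
    """Completed years of age on ``on`` (floor of elapsed whole years).

    Raises ``ValueError`` if ``on`` precedes ``birth_date`` — a record dated
    before birth signals a corrupt linkage, never a negative age.
    """
    if on < birth_date:
        raise ValueError(f"date {on} precedes birth date {birth_date}")
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


# ---------------------------------------------------------------------------
# CSV I/O


def read_tables(directory: str | Path) -> CodedRecordTables:
    """Read the six per-table CSV files from ``directory``.

    Codes are read as strings (preserving leading zeros); dates are parsed to
    datetime64 with unparseable values kept as NaT for ``validate_tables`` to
    itemise — rows are never silently dropped.
    """
    directory = Path(directory)
    frames = {}
    for name, cols in TABLE_COLUMNS.items():
        path = directory / f"{name}.csv"
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        df = df[cols]
        dcol = DATE_COLUMNS[name]
        df[dcol] = pd.to_datetime(df[dcol], format="%Y-%m-%d", errors="coerce")
        for c in _INT_COLUMNS.get(name, []):
            df[c] = pd.to_numeric(df[c], errors="coerce").astype("Int64")
        frames[name] = df
    return CodedRecordTables(**frames)


def write_tables(tables: CodedRecordTables, directory: str | Path) -> None:
    """Write one CSV per table (UTF-8, header row, ISO-8601 dates)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in tables:
        out = df.copy()
        dcol = DATE_COLUMNS[name]
        out[dcol] = pd.to_datetime(out[dcol]).dt.strftime("%Y-%m-%d")
        out.to_csv(directory / f"{name}.csv", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Validation


def _add(report: ValidationReport, table: str, rows: Iterable[int], field_: str,
         kind: str, message: str) -> None:
    for r in rows:
        report.issues.append(ValidationIssue(table, int(r), field_, kind, message))


def validate_tables(tables: CodedRecordTables, vocab: Vocabularies) -> ValidationReport:
    """Schema / vocabulary / referential-integrity validation.

    The report is free of issues iff every table invariant holds: unique
    patient identifiers, every record linked to a known patient, codes drawn
    from the configured vocabularies, ICD-10 syntax, HoNOS scores in 0-4 or
    the explicit missing sentinel, and no record dated before the patient's
    birth.
    """
    report = ValidationReport()
    for name, df in tables:
        report.row_counts[name] = len(df)

    known = set(tables.patients["patient_id"].astype(str))

    dup = tables.patients["patient_id"].duplicated(keep=False)
    _add(report, "patients", tables.patients.index[dup], "patient_id",
         "duplicate-id", "patient_id occurs more than once")

    birth_by_id = tables.patients.set_index(
        tables.patients["patient_id"].astype(str)
    )["birth_date"]
    birth_by_id = birth_by_id[~birth_by_id.index.duplicated()]

    for name, df in tables:
        dcol = DATE_COLUMNS[name]
        bad_date = df[dcol].isna() & (len(df) > 0)
        _add(report, name, df.index[bad_date], dcol,
             "malformed-date", "unparseable or missing date (expected YYYY-MM-DD)")

        if name == "patients":
            continue

        orphan = ~df["patient_id"].astype(str).isin(known)
        _add(report, name, df.index[orphan], "patient_id",
             "referential-integrity", "patient_id absent from patient table")

        # record dated before the linked patient's birth -> negative age
        linked = df.loc[~orphan & ~bad_date]
        if len(linked):
            births = linked["patient_id"].astype(str).map(birth_by_id)
            neg = linked[dcol] < births
            _add(report, name, linked.index[neg.fillna(False)], dcol,
                 "negative-age", "record predates the patient's birth date")

    d = tables.diagnoses
    if len(d):
        _add(report, "diagnoses", d.index[~d["scheme"].isin(vocab.diagnosis_schemes)],
             "scheme", "vocabulary", f"scheme not in {sorted(vocab.diagnosis_schemes)}")
        _add(report, "diagnoses", d.index[~d["rank"].isin(vocab.diagnosis_ranks)],
             "rank", "vocabulary", f"rank not in {sorted(vocab.diagnosis_ranks)}")
        bad_code = ~d["code"].astype(str).str.match(_ICD10_RE)
        _add(report, "diagnoses", d.index[bad_code], "code",
             "malformed-code", "code does not match ICD-10 syntax")

    r = tables.referrals
    if len(r):
        _add(report, "referrals",
             r.index[~r["reason_code"].isin(vocab.referral_reasons)],
             "reason_code", "vocabulary", "reason_code outside configured vocabulary")

    c = tables.clusters
    if len(c):
        bad = ~c["cluster_code"].isin(list(vocab.cluster_codes))
        _add(report, "clusters", c.index[bad], "cluster_code",
             "vocabulary", "cluster_code outside configured vocabulary")

    h = tables.honos
    if len(h):
        bad_ver = ~h["version"].isin(vocab.honos_versions)
        _add(report, "honos", h.index[bad_ver], "version",
             "vocabulary", "unknown HoNOS version")
        valid_scores = set(range(5)) | {HONOS_MISSING}
        bad_score = ~h["score"].isin(list(valid_scores))
        _add(report, "honos", h.index[bad_score], "score",
             "range", f"score not in 0-4 or missing sentinel {HONOS_MISSING}")
        ok_ver = h.loc[~bad_ver]
        if len(ok_ver):
            max_item = ok_ver["version"].map(dict(vocab.honos_max_item))
            bad_item = (ok_ver["item_id"] < 1) | (ok_ver["item_id"] > max_item)
            _add(report, "honos", ok_ver.index[bad_item.fillna(True)], "item_id",
                 "range", "item_id inconsistent with HoNOS version")

    f = tables.flags
    if len(f):
        _add(report, "flags", f.index[~f["flag_type"].isin(vocab.flag_types)],
             "flag_type", "vocabulary", f"flag_type not in {sorted(vocab.flag_types)}")

    report.issues.sort(key=lambda i: (i.table, i.row if i.row is not None else -1, i.kind))
    return report
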