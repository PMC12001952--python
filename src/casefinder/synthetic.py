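"""Seeded generator of MHSDS-like table sets with latent ground truth.

The real MHSDS is access-restricted, so every pipeline stage is exercised on
synthetic data instead.  Each simulated patient carries a latent true
psychosis status (prevalence ``true_prevalence``); conditionally on that
status the six coded data elements are recorded independently, each with its
own sensitivity ``P(element recorded | true case)`` and false-positive rate
``P(element recorded | non-case)``.  False positives are meaningful clinical
noise, not random strings: a non-case can still score >= 3 on the HoNOS
hallucinations/delusions item (personality disorder and PTSD can present
with psychotic symptoms), be assigned a psychosis-adjacent cluster, or carry
a miscoded referral.

Deterministic by construction: one global seed feeds a hierarchical
per-table stream (``numpy.random.SeedSequence`` spawn keys), so the same
seed yields byte-identical CSV output and adding a table later would not
perturb the earlier ones.

An optional shared latent severity scalar (``shared_severity_rho``) induces
positive dependence between elements through a Gaussian copula, for
robustness checks; the default noise model is conditional independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .atoms import ATOM_LABELS
from .model import AnalysisWindow, CodedRecordTables, HONOS_MISSING, financial_year
from . import vocab

__all__ = [
    "AtomNoise",
    "GeneratorConfig",
    "DEFAULT_ATOM_NOISE",
    "DEFAULT_AGE_BANDS",
    "generate",
    "expected_atom_count",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class AtomNoise:
    """Recording probabilities for one data element."""

    sens: float  # P(recorded | true case)
    fpr: float   # P(recorded | non-case)

    def __post_init__(self) -> None:
        for name, v in (("sens", self.sens), ("fpr", self.fpr)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


#: Illustrative defaults.  Diagnostic coding in the MHSDS is incomplete
#: (coding is not mandatory), so even the primary-diagnosis element misses
#: many true cases; crisis referrals (R18) and HoNOS/cluster elements carry
#: appreciable false-positive rates because they are not diagnosis-specific.
DEFAULT_ATOM_NOISE: Mapping[str, AtomNoise] = {
    "DX": AtomNoise(0.55, 0.0005),
    "R01": AtomNoise(0.10, 0.0002),
    "R02": AtomNoise(0.45, 0.0005),
    "R18": AtomNoise(0.10, 0.0020),
    "CLUSTER": AtomNoise(0.60, 0.0020),
    "HONOS": AtomNoise(0.50, 0.0020),
    "FEP": AtomNoise(0.12, 0.0001),
    "EIP": AtomNoise(0.10, 0.0001),
}

#: (low age, high age, weight) bands spanning a secondary mental-health
#: service population, including under-14s and over-65s so the age filters
#: and the 55-65 dementia exclusion have material to act on.
DEFAULT_AGE_BANDS: tuple[tuple[int, int, float], ...] = (
    (0, 13, 0.06),
    (14, 17, 0.08),
    (18, 34, 0.28),
    (35, 54, 0.28),
    (55, 65, 0.14),
    (66, 90, 0.13),
    (91, 105, 0.03),
)

_PSYCHOSIS_CODES = ("F20.0", "F20.9", "F22.0", "F23.0", "F25.0", "F25.1", "F29")
_BACKGROUND_DX = ("F32.0", "F32.9", "F41.1", "F41.9", "F60.3",
                  "F10.2", "F43.1", "F31.9", "F84.0", "F90.0")
_COMORBID_EXCLUSION_CODES = ("F00.1", "F01.9", "F03", "G30.9", "F32.3", "F33.3")
_BACKGROUND_REFERRALS = ("03", "04", "05", "06", "07", "08", "12")
_NON_PSYCHOSIS_CLUSTERS = (1, 2, 3, 4, 5, 6, 7, 8, 18, 19, 20, 21)
_HONOS_VERSIONS = ("working-age", "65+", "ABI", "CA-CR", "LD")
_HONOS_VERSION_W = (0.70, 0.15, 0.05, 0.07, 0.03)

# background recording rates, independent of case status: non-qualifying
# rows that give every table realistic bulk
_BG_DX_PROB = 0.35
_BG_REFERRAL_PROB = 0.40
_BG_CLUSTER_PROB = 0.45
_BG_HONOS_PROB = 0.50
_HONOS_MISSING_PROB = 0.10


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic MHSDS-like data set."""

    n_patients: int = 50_000
    true_prevalence: float = 0.003
    window: AnalysisWindow = field(default_factory=lambda: financial_year(2018))
    age_bands: tuple[tuple[int, int, float], ...] = DEFAULT_AGE_BANDS
    atom_noise: Mapping[str, AtomNoise] = field(
        default_factory=lambda: dict(DEFAULT_ATOM_NOISE)
    )
    comorbid_dementia_prob: float = 0.05
    shared_severity_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.true_prevalence <= 1.0:
            raise ValueError("true_prevalence outside [0, 1]")
        if not 0.0 <= self.comorbid_dementia_prob <= 1.0:
            raise ValueError("comorbid_dementia_prob outside [0, 1]")
        if not 0.0 <= self.shared_severity_rho < 1.0:
            raise ValueError("shared_severity_rho outside [0, 1)")
        missing = set(ATOM_LABELS) - set(self.atom_noise)
        if missing:
            raise ValueError(f"atom_noise missing entries for {sorted(missing)}")
        for lo, hi, w in self.age_bands:
            if not (0 <= lo <= hi <= 105) or w < 0:
                raise ValueError(f"invalid age band ({lo}, {hi}, {w})")
        if self.age_bands and not math.isclose(
            sum(w for *_, w in self.age_bands), 1.0, abs_tol=1e-9
        ):
            raise ValueError("age band weights must sum to 1")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def expected_atom_count(config: GeneratorConfig, atom: str) -> tuple[float, float]:
    """Closed-form expected count and SD of one atom under the generator.

    Marginally each patient records the element with probability
    ``q = p*sens + (1-p)*fpr`` independently of the others, so the count is
    Binomial(N, q): mean ``N*q``, SD ``sqrt(N*q*(1-q))``.  This is the exact
    unconditional SD (case status is itself random); it assumes the default
    independent noise model (``shared_severity_rho = 0``).
    """
    if atom not in ATOM_LABELS:
        raise ValueError(f"unknown atom label {atom!r}")
    noise = config.atom_noise[atom]
    p = config.true_prevalence
    q = p * noise.sens + (1.0 - p) * noise.fpr
    n = config.n_patients
    return n * q, math.sqrt(n * q * (1.0 - q))


# ---------------------------------------------------------------------------
# Generation


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("case", "indicators", "patients", "diagnoses", "referrals",
             "clusters", "honos", "flags", "comorbid")
    children = np.random.SeedSequence(seed).spawn(16)  # spare keys reserved
    return {n: np.random.default_rng(children[i]) for i, n in enumerate(names)}


def _birth_dates(window: AnalysisWindow, ages: np.ndarray,
                 rng: np.random.Generator) -> pd.Series:
    """Birth dates giving exactly the requested completed age at window start."""
    start = pd.Timestamp(window.start)
    anniversaries = {
        int(a): start - pd.DateOffset(years=int(a)) for a in np.unique(ages)
    }
    anniv = pd.Series([anniversaries[int(a)] for a in ages])
    # up to 364 extra days keeps the age at window start unchanged
    offset = rng.integers(0, 365, size=len(ages))
    return anniv - pd.to_timedelta(offset, unit="D")


def _dates_in(window: AnalysisWindow, n: int, rng: np.random.Generator) -> pd.Series:
    days = (window.end - window.start).days
    return pd.Timestamp(window.start) + pd.to_timedelta(
        rng.integers(0, days, size=n), unit="D"
    )


def generate(config: GeneratorConfig) -> tuple[CodedRecordTables, pd.DataFrame]:
    """Generate one linked table set plus its ground truth.

    Returns ``(tables, truth)`` where ``truth`` has one row per patient with
    ``is_true_case`` and ``is_incident`` (first episode inside the window —
    a true case whose recorded evidence includes first-episode markers).
    ``n_patients = 0`` yields valid empty tables.
    """
    n = config.n_patients
    if n == 0:
        truth = pd.DataFrame(
            {"patient_id": pd.Series(dtype=object),
             "is_true_case": pd.Series(dtype=bool),
             "is_incident": pd.Series(dtype=bool)}
        )
        return CodedRecordTables.empty(), truth

    rngs = _spawn_rngs(config.seed)
    window = config.window
    pids = np.array([f"P{i:07d}" for i in range(n)], dtype=object)

    # latent case status (common-random-numbers: monotone in prevalence)
    is_case = rngs["case"].uniform(size=n) < config.true_prevalence

    # element indicators via a Gaussian copula; rho=0 is independence
    rho = config.shared_severity_rho
    shared = rngs["indicators"].standard_normal(n)
    eps = rngs["indicators"].standard_normal((n, len(ATOM_LABELS)))
    z = math.sqrt(rho) * shared[:, None] + math.sqrt(1.0 - rho) * eps
    indicator: dict[str, np.ndarray] = {}
    for j, atom in enumerate(ATOM_LABELS):
        noise = config.atom_noise[atom]
        p_vec = np.where(is_case, noise.sens, noise.fpr)
        with np.errstate(divide="ignore"):
            thresh = ndtri(p_vec)
        indicator[atom] = z[:, j] < thresh

    # ----- patients -----
    bands = config.age_bands
    band_idx = rngs["patients"].choice(
        len(bands), size=n, p=[w for *_, w in bands]
    )
    lows = np.array([b[0] for b in bands])
    highs = np.array([b[1] for b in bands])
    ages = rngs["patients"].integers(lows[band_idx], highs[band_idx] + 1)
    birth = _birth_dates(window, ages, rngs["patients"])
    sex = rngs["patients"].choice(np.array(["1", "2"], dtype=object), size=n)
    patients = pd.DataFrame(
        {"patient_id": pids, "birth_date": birth.values, "sex": sex}
    )

    # ----- diagnoses -----
    rng = rngs["diagnoses"]
    parts = []
    dx_idx = np.flatnonzero(indicator["DX"])
    if len(dx_idx):
        parts.append(pd.DataFrame({
            "patient_id": pids[dx_idx],
            "record_date": _dates_in(window, len(dx_idx), rng).values,
            "scheme": "ICD10",
            "code": rng.choice(np.array(_PSYCHOSIS_CODES, dtype=object),
                               size=len(dx_idx)),
            "rank": "primary",
        }))
    bg_idx = np.flatnonzero(rng.uniform(size=n) < _BG_DX_PROB)
    if len(bg_idx):
        parts.append(pd.DataFrame({
            "patient_id": pids[bg_idx],
            "record_date": _dates_in(window, len(bg_idx), rng).values,
            "scheme": "ICD10",
            "code": rng.choice(np.array(_BACKGROUND_DX, dtype=object),
                               size=len(bg_idx)),
            "rank": "primary",
        }))
    # concurrent dementia / psychotic-depression coding among cases aged
    # 55-65, so the older-age exclusion rule has cases to act on
    rng_c = rngs["comorbid"]
    com_elig = is_case & (ages >= 55) & (ages <= 65)
    com_idx = np.flatnonzero(
        com_elig & (rng_c.uniform(size=n) < config.comorbid_dementia_prob)
    )
    if len(com_idx):
        parts.append(pd.DataFrame({
            "patient_id": pids[com_idx],
            "record_date": _dates_in(window, len(com_idx), rng_c).values,
            "scheme": "ICD10",
            "code": rng_c.choice(np.array(_COMORBID_EXCLUSION_CODES, dtype=object),
                                 size=len(com_idx)),
            "rank": "secondary",
        }))
    diagnoses = _concat(parts, "diagnoses")

    # ----- referrals -----
    rng = rngs["referrals"]
    parts = []
    for code, atom in (("01", "R01"), ("02", "R02"), ("18", "R18")):
        idx = np.flatnonzero(indicator[atom])
        if len(idx):
            parts.append(pd.DataFrame({
                "patient_id": pids[idx],
                "referral_date": _dates_in(window, len(idx), rng).values,
                "reason_code": code,
            }))
    bg_idx = np.flatnonzero(rng.uniform(size=n) < _BG_REFERRAL_PROB)
    if len(bg_idx):
        parts.append(pd.DataFrame({
            "patient_id": pids[bg_idx],
            "referral_date": _dates_in(window, len(bg_idx), rng).values,
            "reason_code": rng.choice(
                np.array(_BACKGROUND_REFERRALS, dtype=object), size=len(bg_idx)
            ),
        }))
    referrals = _concat(parts, "referrals")

    # ----- clusters -----
    rng = rngs["clusters"]
    parts = []
    idx = np.flatnonzero(indicator["CLUSTER"])
    if len(idx):
        parts.append(pd.DataFrame({
            "patient_id": pids[idx],
            "assignment_date": _dates_in(window, len(idx), rng).values,
            "cluster_code": rng.choice(np.arange(10, 18), size=len(idx)),
        }))
    bg_idx = np.flatnonzero(rng.uniform(size=n) < _BG_CLUSTER_PROB)
    if len(bg_idx):
        parts.append(pd.DataFrame({
            "patient_id": pids[bg_idx],
            "assignment_date": _dates_in(window, len(bg_idx), rng).values,
            "cluster_code": rng.choice(np.array(_NON_PSYCHOSIS_CLUSTERS),
                                       size=len(bg_idx)),
        }))
    clusters = _concat(parts, "clusters")

    # ----- HoNOS -----
    rng = rngs["honos"]
    item_map = vocab.HONOS_ITEM_MAP
    parts = []
    idx = np.flatnonzero(indicator["HONOS"])
    if len(idx):
        version = rng.choice(np.array(_HONOS_VERSIONS, dtype=object),
                             size=len(idx), p=_HONOS_VERSION_W)
        parts.append(pd.DataFrame({
            "patient_id": pids[idx],
            "assessment_date": _dates_in(window, len(idx), rng).values,
            "version": version,
            "item_id": pd.Series(version).map(item_map).to_numpy(),
            "score": rng.integers(3, 5, size=len(idx)),  # qualifying: 3 or 4
        }))
    bg_idx = np.flatnonzero(rng.uniform(size=n) < _BG_HONOS_PROB)
    if len(bg_idx):
        version = rng.choice(np.array(_HONOS_VERSIONS, dtype=object),
                             size=len(bg_idx), p=_HONOS_VERSION_W)
        score = rng.integers(0, 3, size=len(bg_idx))
        miss = rng.uniform(size=len(bg_idx)) < _HONOS_MISSING_PROB
        score = np.where(miss, HONOS_MISSING, score)
        parts.append(pd.DataFrame({
            "patient_id": pids[bg_idx],
            "assessment_date": _dates_in(window, len(bg_idx), rng).values,
            "version": version,
            "item_id": pd.Series(version).map(item_map).to_numpy(),
            "score": score,
        }))
    honos = _concat(parts, "honos")

    # ----- flags -----
    rng = rngs["flags"]
    parts = []
    for flag in ("FEP", "EIP"):
        idx = np.flatnonzero(indicator[flag])
        if len(idx):
            parts.append(pd.DataFrame({
                "patient_id": pids[idx],
                "flag_type": flag,
                "flag_date": _dates_in(window, len(idx), rng).values,
            }))
    flags = _concat(parts, "flags")

    tables = CodedRecordTables(
        patients=patients, diagnoses=diagnoses, referrals=referrals,
        clusters=clusters, honos=honos, flags=flags,
    )
    truth = pd.DataFrame({
        "patient_id": pids,
        "is_true_case": is_case,
        "is_incident": is_case & (indicator["R01"] | indicator["FEP"]),
    })
    return tables, truth


def _concat(parts: Sequence[pd.DataFrame], table: str) -> pd.DataFrame:
    from .model import TABLE_COLUMNS, DATE_COLUMNS

    if not parts:
        return getattr(CodedRecordTables.empty(), table)
    df = pd.concat(parts, ignore_index=True)
    df = df.sort_values(
        ["patient_id", DATE_COLUMNS[table]], kind="stable"
    ).reset_index(drop=True)
    return df[TABLE_COLUMNS[table]]


# ---------------------------------------------------------------------------
# Truth I/O


def write_truth(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    out["is_true_case"] = out["is_true_case"].astype(int)
    out["is_incident"] = out["is_incident"].astype(int)
    out.to_csv(path, index=False, lineterminator="\n")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["is_true_case"] = df["is_true_case"].astype(bool)
    df["is_incident"] = df["is_incident"].astype(bool)
    return df
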