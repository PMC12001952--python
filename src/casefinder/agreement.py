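"""Cross-algorithm agreement and evaluation against synthetic ground truth.

Two complementary analyses:

* **Agreement** — given several cohorts for the same window, count how many
  patients are flagged by exactly k and by at least k algorithms
  (k = 1..K).  ``n_at_least_K`` is the *core set*: patients every candidate
  algorithm agrees on.  A large core set relative to the union indicates the
  algorithms are triangulating the same population.
* **Truth evaluation** — only possible on synthetic data, where the latent
  case status is known: confusion counts and sensitivity / specificity /
  PPV per algorithm over an explicit eligible population (the
  post-age-filter patient universe, which defines the true negatives).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import CohortResult

__all__ = [
    "AgreementTable",
    "EvalMetrics",
    "agreement",
    "pairwise_overlap",
    "evaluate_against_truth",
]


@dataclass(frozen=True)
class AgreementTable:
    """Multiplicity-of-identification counts over K cohorts."""

    k_max: int
    n_exactly: tuple[int, ...]   # index k-1 -> patients flagged by exactly k
    n_at_least: tuple[int, ...]  # index k-1 -> patients flagged by >= k
    union_size: int
    core_set: frozenset[str]     # flagged by all K algorithms

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_algorithms": range(1, self.k_max + 1),
            "n_exactly_k": self.n_exactly,
            "n_at_least_k": self.n_at_least,
        })


def agreement(cohorts: Sequence[CohortResult]) -> AgreementTable:
    """Count patients by the number of algorithms that identify them.

    All cohorts must share a window.  Conservation holds by construction:
    the exact-k counts sum to the size of the union of all cohorts, and the
    at-least-k counts are non-increasing with ``n_at_least_1`` equal to the
    union size.
    """
    if not cohorts:
        raise ValueError("at least one cohort is required")
    windows = {c.window.label for c in cohorts}
    if len(windows) > 1:
        raise ValueError(f"cohorts span multiple windows: {sorted(windows)}")
    k_max = len(cohorts)
    mult: Counter[str] = Counter()
    for c in cohorts:
        mult.update(c.patients)
    exactly = [0] * k_max
    for count in mult.values():
        exactly[count - 1] += 1
    at_least = list(np.cumsum(exactly[::-1])[::-1])
    core = frozenset(p for p, m in mult.items() if m == k_max)
    return AgreementTable(
        k_max=k_max,
        n_exactly=tuple(exactly),
        n_at_least=tuple(int(x) for x in at_least),
        union_size=len(mult),
        core_set=core,
    )


def pairwise_overlap(
    cohorts: Sequence[CohortResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise intersection sizes and Jaccard indices.

    Returns two symmetric DataFrames indexed by algorithm id.  The Jaccard
    diagonal is 1 for non-empty cohorts and NaN for empty ones (0/0).
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts")
    windows = {c.window.label for c in cohorts}
    if len(windows) > 1:
        raise ValueError(f"cohorts span multiple windows: {sorted(windows)}")
    ids = [c.algorithm_id for c in cohorts]
    k = len(cohorts)
    inter = np.zeros((k, k), dtype=int)
    jac = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            n_int = len(cohorts[i].patients & cohorts[j].patients)
            n_uni = len(cohorts[i].patients | cohorts[j].patients)
            inter[i, j] = inter[j, i] = n_int
            if n_uni:
                jac[i, j] = jac[j, i] = n_int / n_uni
    return (
        pd.DataFrame(inter, index=ids, columns=ids),
        pd.DataFrame(jac, index=ids, columns=ids),
    )


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts and derived metrics for one algorithm.

    Undefined ratios (e.g. PPV of an empty cohort) are ``None`` and named in
    ``undefined`` — never silently 0 or NaN.
    """

    algorithm_id: str
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "algorithm_id": self.algorithm_id,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "undefined": ",".join(self.undefined),
        }


def evaluate_against_truth(
    cohort: CohortResult,
    truth: pd.DataFrame,
    eligible: frozenset[str] | set[str],
) -> EvalMetrics:
    """Confusion counts for one cohort against latent ground truth.

    ``eligible`` is the population the metrics are computed over (typically
    the post-age-filter patient universe); it defines the true negatives.
    Every cohort member must appear in the truth table and in ``eligible``.
    """
    eligible = frozenset(eligible)
    known = frozenset(truth["patient_id"].astype(str))
    stray = cohort.patients - known
    if stray:
        raise ValueError(
            f"cohort member(s) absent from ground truth: {sorted(stray)[:5]}"
        )
    if not cohort.patients <= eligible:
        raise ValueError("cohort contains members outside the eligible population")
    cases = frozenset(
        truth.loc[truth["is_true_case"], "patient_id"].astype(str)
    ) & eligible
    flagged = cohort.patients
    tp = len(flagged & cases)
    fp = len(flagged - cases)
    fn = len(cases - flagged)
    tn = len(eligible) - tp - fp - fn

    undefined = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    return EvalMetrics(
        cohort.algorithm_id, tp, fp, fn, tn, sens, spec, ppv, tuple(undefined)
    )
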