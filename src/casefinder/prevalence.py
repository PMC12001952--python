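"""Treated-prevalence band derivation and algorithm screening.

National survey work puts the prevalence of psychosis among adults in
England at about 0.7%; combining that base rate with care-setting fractions
(the share of people with severe mental illness seen in secondary care, the
share of severe mental illness that is psychosis, the share of people with
psychosis seen in both primary and secondary care) yields an annual
*treated* prevalence band of roughly 0.22%-0.33% — the fraction of the
population receiving secondary care for psychosis in a year.

Candidate case-finding algorithms are screened by this band: an algorithm is
plausible only if its cohort count falls inside the implied count interval
in *every* analysis year.  The exact multiplier arithmetic behind the
published bounds is not reconstructible, so the shipped default band stores
the published rates directly (an identity chain); :func:`derive_band`
supports explicit user-specified chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_CEILING, ROUND_FLOOR, ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .engine import CohortResult

__all__ = [
    "PrevalenceBand",
    "Denominator",
    "ScreenDecision",
    "DEFAULT_BAND",
    "derive_band",
    "band_to_counts",
    "screen",
]


@dataclass(frozen=True)
class PrevalenceBand:
    """Lower/upper annual treated-prevalence rates with their provenance."""

    low_rate: float
    high_rate: float
    provenance: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.low_rate <= self.high_rate < 1.0):
            raise ValueError(
                f"invalid band: 0 < {self.low_rate} <= {self.high_rate} < 1 required"
            )


@dataclass(frozen=True)
class Denominator:
    """Population at risk for one analysis window (e.g. an ONS mid-year
    estimate of persons aged 16-90)."""

    window_label: str
    population: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("population must be positive")


#: Published treated-prevalence bounds, stored directly (identity chains).
DEFAULT_BAND = PrevalenceBand(
    0.0022, 0.0033,
    provenance=(("published lower bound", (0.0022,)),
                ("published upper bound", (0.0033,))),
)


def derive_band(
    base_prevalence: float,
    low_chain: Sequence[float],
    high_chain: Sequence[float],
) -> PrevalenceBand:
    """Derive a band by multiplying a base prevalence through fraction chains.

    Each bound is ``base_prevalence * prod(chain)``; every fraction must lie
    in (0, 1].  The chains are recorded as provenance on the result.
    """
    if not 0.0 < base_prevalence < 1.0:
        raise ValueError("base_prevalence must lie in (0, 1)")
    for chain in (low_chain, high_chain):
        if not chain:
            raise ValueError("multiplier chains must be non-empty")
        for f in chain:
            if not 0.0 < f <= 1.0:
                raise ValueError(f"fraction {f} outside (0, 1]")
    low = base_prevalence
    for f in low_chain:
        low *= f
    high = base_prevalence
    for f in high_chain:
        high *= f
    if low > high:
        low, high = high, low
    return PrevalenceBand(
        low, high,
        provenance=(("low", tuple(low_chain)), ("high", tuple(high_chain)),
                    ("base", (base_prevalence,))),
    )


_ROUNDING = {
    "half-up": ROUND_HALF_UP,
    "ceiling": ROUND_CEILING,
    "floor": ROUND_FLOOR,
}


def band_to_counts(
    band: PrevalenceBand,
    denom: Denominator,
    rounding: str = "half-up",
) -> tuple[int, int]:
    """Convert the rate band to an inclusive count interval for a population.

    Uses exact decimal arithmetic; the rounding convention is configurable
    (default round-half-up) because published count thresholds cannot be
    re-derived without the original population figures.
    """
    if rounding not in _ROUNDING:
        raise ValueError(f"unknown rounding {rounding!r}")
    mode = _ROUNDING[rounding]
    pop = Decimal(denom.population)
    low = int((pop * Decimal(str(band.low_rate))).to_integral_value(rounding=mode))
    high = int((pop * Decimal(str(band.high_rate))).to_integral_value(rounding=mode))
    return low, high


@dataclass(frozen=True)
class ScreenDecision:
    algorithm_id: str
    retained: bool
    #: per-window (window, count, low, high, within)
    detail: tuple = ()
    reason: str = ""


def screen(
    cohorts: Sequence[CohortResult],
    band: PrevalenceBand,
    denominators: Mapping[str, Denominator],
    rounding: str = "half-up",
) -> tuple[list[ScreenDecision], pd.DataFrame]:
    """Screen algorithms by the treated-prevalence count interval.

    An algorithm is retained iff its count lies inside the inclusive
    interval ``[low, high]`` in every supplied window; the first failing
    window and bound are recorded as the rejection reason.  Returns the
    per-algorithm decisions plus a tidy report frame
    (algorithm_id, window, count, low, high, within, retained).
    """
    by_alg: dict[str, list[CohortResult]] = {}
    for c in cohorts:
        if c.window.label not in denominators:
            raise ValueError(f"no denominator supplied for window {c.window.label!r}")
        by_alg.setdefault(c.algorithm_id, []).append(c)

    decisions: list[ScreenDecision] = []
    rows = []
    for alg_id in sorted(by_alg):
        detail = []
        reason = ""
        for c in sorted(by_alg[alg_id], key=lambda c: c.window.label):
            low, high = band_to_counts(band, denominators[c.window.label], rounding)
            within = low <= c.count <= high
            detail.append((c.window.label, c.count, low, high, within))
            if not within and not reason:
                bound = "below lower bound" if c.count < low else "above upper bound"
                reason = f"{c.window.label}: count {c.count} {bound} [{low}, {high}]"
        retained = all(d[4] for d in detail)
        decisions.append(ScreenDecision(alg_id, retained, tuple(detail), reason))
        for w, count, low, high, within in detail:
            rows.append({
                "algorithm_id": alg_id, "window": w, "count": count,
                "low": low, "high": high, "within": within, "retained": retained,
            })
    return decisions, pd.DataFrame(rows)
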