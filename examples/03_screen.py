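"""Screen candidate algorithms against the treated-prevalence band.

An algorithm is plausible only if its cohort count falls inside the count
interval implied by the published 0.22%-0.33% annual treated prevalence of
psychosis in every analysis year.
"""

from casefinder import (
    DEFAULT_BAND, Denominator, GeneratorConfig, band_to_counts,
    builtin_algorithms, build_cohort, compute_all_atoms, generate, screen,
)
from casefinder.engine import enumerate_candidates

cfg = GeneratorConfig(n_patients=100_000, true_prevalence=0.003, seed=1)
tables, _ = generate(cfg)
atoms = compute_all_atoms(tables, cfg.window)
denom = Denominator(cfg.window.label, cfg.n_patients, "generated population")
low, high = band_to_counts(DEFAULT_BAND, denom)
print(f"plausible count interval for {denom.population} persons: "
      f"[{low}, {high}]  (0.22%-0.33%)")

candidates = enumerate_candidates()
cohorts = [build_cohort(s, atoms, tables, cfg.window) for s in candidates]
decisions, report = screen(cohorts, DEFAULT_BAND, {denom.window_label: denom})
retained = [d.algorithm_id for d in decisions if d.retained]
print(f"candidates: {len(candidates)}, retained: {len(retained)}")

for spec in builtin_algorithms():
    cohort = build_cohort(spec, atoms, tables, cfg.window)
    inside = low <= cohort.count <= high
    print(f"{spec.id}: count {cohort.count} -> {'retained' if inside else 'rejected'}")
# Retained algorithms produce cohort sizes consistent with how many people
# actually receive secondary care for psychosis in a year; the rest over- or
# under-ascertain.
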