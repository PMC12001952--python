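"""Generate a synthetic MHSDS-like data set with known ground truth.

Each patient has a latent psychosis status; conditionally on it, the six
coded data elements are recorded with per-element sensitivities and
false-positive rates, so downstream algorithms can later be scored against
the truth.
"""

from casefinder import GeneratorConfig, generate, expected_atom_count

cfg = GeneratorConfig(n_patients=50_000, true_prevalence=0.003, seed=1)
tables, truth = generate(cfg)

print(f"patients: {len(tables.patients)}")
for name, df in tables:
    if name != "patients":
        print(f"{name}: {len(df)} rows")
print(f"true cases: {int(truth.is_true_case.sum())} "
      f"(expected {cfg.n_patients * cfg.true_prevalence:.0f}), "
      f"incident: {int(truth.is_incident.sum())}")
mean, sd = expected_atom_count(cfg, "DX")
print(f"expected primary-diagnosis (DX) element count: {mean:.1f} +/- {sd:.1f}")
# The row counts emulate the multi-table MHSDS structure; the true-case
# count is binomial around n * prevalence, and the closed-form DX expectation
# is what the recorded diagnoses should fluctuate around.
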