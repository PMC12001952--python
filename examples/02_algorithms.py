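"""Evaluate the built-in case-finding algorithms on synthetic data.

Atoms are per-element patient sets; algorithms combine them with OR/AND set
algebra and then pass through the age filter (14-105 for prevalent cohorts)
and the 55-65 dementia/psychotic-depression exclusion.
"""

from casefinder import (
    GeneratorConfig, generate, compute_all_atoms, builtin_algorithms,
    build_cohort, parse_algorithm,
)

cfg = GeneratorConfig(n_patients=50_000, true_prevalence=0.003, seed=1)
tables, _ = generate(cfg)
atoms = compute_all_atoms(tables, cfg.window)

print("atom sizes:", {label: len(res) for label, res in atoms.items()})
for spec in builtin_algorithms():
    cohort = build_cohort(spec, atoms, tables, cfg.window)
    print(f"{spec.id}: {spec.expression_text:45s} -> {cohort.count} patients")

custom = parse_algorithm("DX OR R02 OR (R18 AND EIP)", id="custom")
print(f"custom: {custom.expression_text:45s} -> "
      f"{build_cohort(custom, atoms, tables, cfg.window).count} patients")
# A6 uses the fewest elements and finds the fewest patients; A1/A5/A7 add
# OR terms and can only grow the cohort (set union is monotone).
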