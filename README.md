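# casefinder

Boolean case-finding algorithms for identifying people with psychosis in
MHSDS-like secondary-care administrative data, with a seeded synthetic data
generator, treated-prevalence screening and cross-algorithm agreement
analysis.

## The problem

The Mental Health Services Data Set (MHSDS) covers all NHS-funded secondary
mental healthcare in England, but diagnostic coding in it is not mandatory,
so there is no single field that reliably identifies people with psychosis
(schizophrenia, schizoaffective disorder and other psychotic disorders —
excluding bipolar disorder, psychotic depression and dementia). Case
ascertainment instead combines six coded data elements, each individually
imperfect:

| atom | element | usable alone? |
|------|---------|----------------|
| `DX` | primary ICD-10 diagnosis in the psychosis code set (F20–F29 subset) | yes |
| `R02`| reason for referral 02 — ongoing/recurrent psychosis | yes |
| `FEP`| first-episode-psychosis flag | yes |
| `EIP`| early-intervention-in-psychosis team flag | yes |
| `R01`| reason for referral 01 — (suspected) first episode | joint only |
| `R18`| reason for referral 18 — in crisis (must pair with `EIP`) | joint only |
| `CLUSTER` | psychosis mental-health cluster assignment | joint only |
| `HONOS` | HoNOS hallucinations/delusions item (6/7/8 by version) scored ≥ 3 | joint only |

An **algorithm** is a boolean expression over these atoms — independently
usable elements joined by OR, joint-only elements inside AND composites,
e.g. `DX OR FEP OR EIP OR (CLUSTER AND HONOS)`. Evaluation is set algebra
(OR = union, AND = intersection), so each patient is counted once. Cohorts
then pass an age filter (incident: 14–65 at the qualifying record;
prevalent: 14–105; under-14s always excluded) and an exclusion of
55–65-year-old first-episode cases with concurrent dementia or psychotic-
depression coding.

Because no chart-review gold standard exists, candidate algorithms are
screened externally: an algorithm is plausible only if its cohort count
falls inside the count interval implied by the published annual treated
prevalence of psychosis, 0.22%–0.33% of the population, in **every**
analysis year. Agreement analysis then asks whether the retained
algorithms identify the same core set of patients.

The real MHSDS is access-restricted, so the package ships a seeded
generator of MHSDS-like table sets with a latent true psychosis status and
per-element recording probabilities, making every stage testable — and
letting sensitivity/specificity/PPV be measured against ground truth,
which is impossible on the real data.

## Worked example

```python
from casefinder import (GeneratorConfig, generate, compute_all_atoms,
                        builtin_algorithms, build_cohort)

cfg = GeneratorConfig(n_patients=50_000, true_prevalence=0.003, seed=1)
tables, truth = generate(cfg)
atoms = compute_all_atoms(tables, cfg.window)
for spec in builtin_algorithms():
    cohort = build_cohort(spec, atoms, tables, cfg.window)
    print(spec.id, spec.expression_text, cohort.count)
```

prints

```
A1 DX OR EIP OR FEP OR R02 161
A5 (CLUSTER AND HONOS) OR DX OR FEP OR R02 158
A6 DX OR EIP OR FEP 107
A7 (CLUSTER AND HONOS) OR DX OR EIP OR FEP 116
```

A6 combines the fewest independently usable elements and finds the fewest
patients; A1, A5 and A7 add OR terms and can only enlarge the cohort
(union is monotone). At 50 000 patients and 0.3% latent prevalence, 150
true cases are expected; A1's 161 includes false positives contributed by
each element's false-positive rate. The `examples/` directory walks
through each capability (simulation, algorithms, screening, agreement,
truth evaluation) as short narrative scripts, and `examples/config.yaml`
is an annotated configuration for the CLI pipeline:

```
casefinder simulate|run|screen|agree|evaluate --config examples/config.yaml --out out
```

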