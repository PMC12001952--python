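# Methods

## Case definition and coded vocabularies

Psychosis is defined as schizophrenia, schizoaffective disorder and other
psychotic disorders. The default ICD-10 code set is the prefix set
{F20, F21, F22, F23, F24, F25, F28, F29}, which deliberately excludes
bipolar disorder (F30–F31), psychotic depression (F32.3/F33.3) and the
dementias (F00–F03, G30): these conditions can involve psychotic symptoms
but are outside the case definition. No authoritative machine-readable
code list exists for this definition, so every code set is configuration
with these defaults, not a constant.

The psychosis mental-health clusters default to codes 10–17 (the
clustering tool's psychotic super-class). The HoNOS "problems associated
with hallucinations and delusions" item is version-dependent — item 6 on
the working-age, 65+ and acquired-brain-injury instruments, item 7 on the
child/adolescent clinician-rated version, item 8 on the learning-
disability version — and qualifies at a score ≥ 3. Score 9 is the
explicit "not known" sentinel and never qualifies at any threshold.
Reason-for-referral codes are stored as zero-padded two-character strings
("01", "02", "18") end to end, so CSV round-trips cannot corrupt them into
integers.

## Windows, ages and filters

Analysis windows are half-open intervals [start, end); the NHS financial
year runs 1 April–31 March. Age is completed years (floor) at a given
date. Each atom is evaluated per window and carries each patient's
earliest qualifying date. For an algorithm, the per-patient qualifying
date is computed recursively: a leaf qualifies at its first record, an
AND composite only once all parts hold (maximum of part dates), an OR at
its earliest satisfied branch (minimum). This date is the "at diagnosis"
date for the incident age filter (14–65); prevalent cohorts keep ages
14–105; under-14s are removed in both modes because psychosis onset
before 14 is rare.

The older-age exclusion removes members whose qualifying evidence falls
at ages 55–65 **and** who carry an in-window diagnosis (any rank) in the
dementia or psychotic-depression code sets — both sets are applied
because either condition can masquerade as late-onset psychosis. By
default the rule applies only to members with first-episode evidence (FEP
flag or referral code 01), which is the narrow reading of the exclusion's
scope; `strict=True` applies it to every cohort member. Both choices are
logged in the run provenance.

## Joint-use constraints

Cluster assignments, HoNOS scores and referral codes 01 and 18 are not
diagnosis-specific enough to stand alone, so the expression validator
rejects any algorithm in which one of them is reachable from the root
through OR nodes only; referral 18 (in crisis) additionally must appear in
an AND composite that also contains the EIP flag. The EIP flag itself is
treated as independently usable — the shipped compositions A1 and A6 use
it bare — even though, conversely, it is the required partner of code 18.
Expressions are canonicalised (children sorted by text) so parsing,
enumeration and hashing are deterministic; `DX OR FEP` and `FEP OR DX`
are the same algorithm.

Candidate enumeration forms every OR-combination of a non-empty subset of
the independent atoms {DX, R02, FEP, EIP} with any subset of the joint
composites, by default {(CLUSTER∧HONOS), (R01∧FEP), (R18∧EIP)} — the
R01 composite pairs the suspected-first-episode referral with the FEP
flag, since code 01 alone captures unconfirmed cases. That yields
(2⁴−1)·2³ = 120 candidates. The enumeration count is reported, never
pinned: different joint-use inventories legitimately yield different
counts, and no inventory is canonical.

## Synthetic data generator

The generator emulates the multi-table structure of secondary-care
administrative data: per-patient tables of primary diagnoses, referrals,
cluster assignments, HoNOS item scores and FEP/EIP flags, linked by a
pseudonymised identifier.

Each patient draws a latent true status Bernoulli(`true_prevalence`,
default 0.003 — inside the 0.22–0.33% treated-prevalence band).
Conditionally on status, each of the eight atoms is recorded
independently with probability `sens` (cases) or `fpr` (non-cases). The
defaults (DX 0.55/0.0005, R02 0.45/0.0005, CLUSTER 0.60/0.002,
HONOS 0.50/0.002, FEP 0.12/0.0001, EIP 0.10/0.0001, R01 0.10/0.0002,
R18 0.10/0.002) are illustrative, not calibrated: real coding-completeness
rates for the MHSDS are not published, only that missingness is high, so
the diagnosis element misses roughly half of true cases and the
non-specific elements (crisis referrals, clusters, HoNOS) carry the
larger false-positive rates. Non-case HONOS "hits" receive genuine
qualifying scores (≥ 3), emulating conditions such as personality
disorder and PTSD that present with psychotic symptoms; background
(non-qualifying) rows — low HoNOS scores and "not known" sentinels,
non-psychosis diagnoses, clusters and referral reasons — give every table
realistic bulk without affecting atom membership.

Marginally, each patient records an element with probability
q = p·sens + (1−p)·fpr independently across patients, so an atom's count
is Binomial(N, q); `expected_atom_count` returns N·q and √(N·q·(1−q)),
the exact unconditional moments under this model. Incidence is derived
from evidence: a true case is incident iff its recorded evidence includes
a first-episode marker (referral 01 or FEP flag), which preserves the
conditional-independence model and the closed form exactly. Cases aged
55–65 additionally receive a concurrent dementia/psychotic-depression
code with probability `comorbid_dementia_prob` (default 0.05), so the
older-age exclusion has material to act on. An optional shared latent
severity scalar (`shared_severity_rho`, Gaussian copula) induces positive
pairwise dependence between elements while preserving all marginal rates,
for robustness checks; the default is independence.

Ages are drawn from configurable bands spanning 0–105 (default weights
describe a secondary mental-health service population and deliberately
include under-14s and over-65s so the filters are exercised); birth dates
are placed so the completed age at window start is exact. All record
dates are uniform inside the window. One global seed feeds a
hierarchical per-table stream (`SeedSequence` spawn keys), so identical
seeds give byte-identical CSVs and adding a new table would not perturb
existing ones.

What the generator does **not** emulate: service pathways and repeat
contacts, provider effects, multi-year patient careers, correlated
missingness, or realistic ICD-10 sub-code frequencies. Passing tests
therefore demonstrate the correctness of the machinery (set algebra,
filters, screening arithmetic, agreement counting) and the statistical
calibration of the generator itself — not the field performance of any
algorithm on real data.

## Prevalence screening

The default band stores the published 0.22%–0.33% treated-prevalence
bounds directly, since the exact multiplier arithmetic that produced them
from the 0.7% adult survey prevalence and the care-setting fractions is
not reconstructible; `derive_band` multiplies explicit user-supplied
fraction chains and records them as provenance. Rate bounds convert to
count intervals by exact decimal arithmetic with configurable rounding
(default round-half-up). Bounds are inclusive at both ends — "within the
range" is read inclusively, and the choice is recorded in the screening
output. Denominators are user-supplied inputs (for self-contained
synthetic runs the generated population size is the default); the package
never downloads population data.

## Agreement and truth evaluation

The agreement table counts patients flagged by exactly k and at least k
of K cohorts; Σₖ n_exactly_k equals the union size by construction, and
n_at_least_K is the core set. Truth evaluation computes confusion counts
by set algebra over an explicit eligible population — the post-age-filter
patient universe, stated in every report, since true negatives are
meaningless without a denominator. Undefined ratios (PPV of an empty
cohort) are reported as explicitly undefined, never as 0 or NaN.

## Numerical and scale choices

Tables are pandas DataFrames; dates ISO-8601; all set operations are on
frozen sets of opaque patient identifiers. The test suite exercises the
engine against independent brute-force oracles (row-by-row filters,
per-patient truth tables) on fixtures of up to a few hundred patients,
runs the generator's parameter-recovery study at N = 50 000 over 100
seeds (4-SD binomial criterion, ≥ 99/100 pass per atom), and checks
end-to-end byte determinism at N = 100 000 — sizes chosen to estimate
every quantity stably while keeping the full suite fast on one CPU. The
acceptance script uses N = 200 000 per financial year for the same
reason.

## Known limitations

* Exclusion-code checks consider any diagnosis rank; if real extracts
  code comorbidity differently, the strictness is configurable only via
  the code sets.
* The joint use of CLUSTER and HONOS requires both atoms in the same
  window for the same patient, not on the same assessment event — the
  loosest faithful reading; a same-event join would need an event
  identifier the tables do not carry.
* Incident/prevalent status interacts with the qualifying-date
  definition: for OR expressions the earliest satisfied branch defines
  "diagnosis", which can precede the branch a clinician would call the
  diagnosis event.
* The generator's single-window design cannot express patients whose
  first episode predates the window; incident status is within-window by
  construction.
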