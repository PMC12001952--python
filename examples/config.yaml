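# Annotated run configuration for the casefinder CLI.
#
#   casefinder simulate --config examples/config.yaml --out out
#   casefinder run      --config examples/config.yaml --out out
#   casefinder screen   --config examples/config.yaml --out out
#   casefinder agree    --config examples/config.yaml --out out
#   casefinder evaluate --config examples/config.yaml --out out
#
# A run is reproducible from this file plus the seed alone.

seed: 1
mode: prevalent          # prevalent: ages 14-105; incident: 14-65 at diagnosis

windows: [2017, 2018]    # NHS financial years (1 April - 31 March); or
                         # explicit {label, start, end} mappings

generator:               # synthetic data; one table set per window
  n_patients: 100000
  true_prevalence: 0.003 # latent psychosis prevalence
  comorbid_dementia_prob: 0.05   # dementia coding among cases aged 55-65
  shared_severity_rho: 0.0       # >0: positive dependence between elements
  # atom_noise:          # per-element recording probabilities (defaults shown
  #   DX: {sens: 0.55, fpr: 0.0005}   # for one; all eight configurable)

algorithms:
  builtin: true          # ship A1, A5, A6, A7
  extra:                 # any further boolean expressions over the atoms
    - {id: X1, expression: "DX OR R02 OR (R18 AND EIP)"}

# codesets:              # optional overrides, e.g.
#   psychosis: {codes: [F20, F21, F22, F23, F24, F25, F28, F29], match_mode: prefix}

screen:
  band: {low: 0.0022, high: 0.0033}  # published annual treated prevalence
  # or derive from a base rate and fraction chains:
  # band: {base: 0.007, low_chain: [0.69, 0.64], high_chain: [1.0]}
  rounding: half-up
  # denominators:        # population at risk per window; defaults to the
  #   - {window: 2018-2019, population: 44723636, source: ONS mid-year}

paths:
  out_dir: out
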