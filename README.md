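# osmoforge

A tested, reusable pipeline for osmotic-tablet formulation development:

- **`osmoforge.sedem`** — powder compressibility scoring on the 12-parameter
  SeDeM diagram: raw micromeritic measurements → derived parameters →
  linearized 0–10 radii → diagram indices (IP, IPP, IGC with the published
  12-parameter reliability factor 0.952) → corrective-excipient fractions
  and radar-chart geometry.
- **`osmoforge.doe`** — 2^k full-factorial designs (standard order + seeded
  randomized run order), coded-unit main-effects OLS, term-wise ANOVA,
  prediction, and Derringer–Suich desirability optimization by exhaustive
  grid search over the coded cube.
- **`osmoforge.release_kinetics`** — the seven classical dissolution models
  (zero-order, first-order, Higuchi, Korsmeyer–Peppas, Hixson–Crowell,
  Baker–Lonsdale, Weibull) fitted by untransformed nonlinear least squares
  with multi-start; release-mechanism classification from the
  Korsmeyer–Peppas exponent; f2 similarity with the regulatory 85%
  truncation rule.
- **`osmoforge.pk`** — two-compartment disposition with first-order oral
  absorption (closed form + independent ODE route), a classical
  compartmental-absorption-and-transit chain driven by in-vitro release
  curves, two-compartment parameter fitting, multiple-dose superposition,
  NCA (Cmax/Tmax/trapezoidal AUC/λz/AUCinf), and dose-normalized relative
  bioavailability.
- **`osmoforge.synth_data`** — seed-deterministic generators for every
  input the pipeline consumes (powder measurements, dissolution curves,
  plasma profiles, factorial response tables), each a measurable inverse
  of its analysis stage and each writing a `*.truth.json` sidecar.
- **`osmoforge.interface`** — strict config validation, schema-checked CSV
  loading, and an end-to-end driver that runs the stages in workflow order
  and writes JSON reports with full provenance.

## CLI

```bash
osmoforge run config.yaml                 # full pipeline (defaults if no config)
osmoforge sedem profile measurements.csv --sieves sieves.csv --out report.json
osmoforge sedem correct --re 10 --rp 2.06 --r 5
osmoforge doe build --k 4 --seed 7
osmoforge kinetics fit profiles.csv --models all
osmoforge kinetics f2 ref.csv test.csv
osmoforge pk nca profile.csv
osmoforge pk relba --test-auc 7388.4 --test-dose 190 --ref-auc 7917.4 --ref-dose 200
osmoforge synth dissolution --model zero_order --param k0=5.898 --seed 1 --out d.csv
```

`osmoforge run` accepts a YAML config with strict key checking (unknown keys
are rejected); every report embeds the resolved config and seeds so any run
is reproducible byte-for-byte.

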