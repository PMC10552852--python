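# concresp

Concentration-response curve processing for medium- and high-throughput
screening bioactivity data: bidirectional fitting of ten parametric
models under a robust t(4) likelihood, AIC winner selection, continuous
hit calling, potency and benchmark-dose estimation with
profile-likelihood confidence intervals, fit categorization, cautionary
flags, and cytotoxicity-burst thresholds — plus a synthetic-data
generator with known ground truth and a CSV pipeline/CLI.

It is written for toxicologists and screening-informatics engineers who
need a transparent, reproducible path from a normalized long-format
well table (sample, endpoint, concentration in µM, response) to
per-curve activity calls and potency estimates.

## The model and the statistics

Each sample x endpoint series is fit with ten families — constant,
linear and quadratic polynomials, power, Hill, gain-loss (a Hill gain
multiplied by a Hill loss, with the loss AC50 forced at least 1.5 log10
units above the gain AC50), and four exponential forms — under
Student-t(4) errors with scale exp(er). The winner is the non-constant
fit with the lowest AIC (ties to fewer parameters); the constant model
can never win but anchors the hit call. The continuous hit call is the
product of three confidence weights,

    hitc = w_aic · w_median · w_top ∈ [0, 1]

for: the winner beats the zero-response model on AIC; some
concentration's median response exceeds the efficacy cutoff; and the
modeled top exceeds the cutoff. hitc ≥ 0.90 is labeled active by
default. Potency metrics (AC5/AC10/AC50/AC95, ACC at the cutoff, ACB at
3·BMAD, and the BMD at BMR = 1.349 x baseline SD, with a 90%
profile-likelihood interval [BMDL, BMDU]) are obtained by inverting the
winning curve in log10-concentration space, in µM. Each curve then
receives a fit-category code (informative actives are 37/41; actives
with AC50 below the tested range 36/40; unsaturated actives 38/42) and
a set of purely annotational cautionary flags. A separate module
summarizes cytotoxicity "burst" activity per chemical as the median
log10 AC50 over active burst endpoints and a lower bound at 3 global
MADs below it. Details and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a small endpoint (Hill curves, tp = 50, AC50 = 1 µM, t(4)
noise) and run the full pipeline:

```sh
$ concresp simulate --out sim --seed 42 --n-samples 4
wrote sim/mc3.csv (96 wells, 4 samples)
$ concresp fit --input sim/mc3.csv --out out
processed 4 series -> out/
$ concresp report --outdir out
4 series processed
active: 4
fit categories:
  fitc 41: 4
```

The winner table (`out/mc5.csv`) holds one row per series:

```
     spid modl     hitc  active  fitc     coff       top     ac50      bmd
spid_0000 hill 0.999932    True    41 15.25725 53.454637 1.121385 0.618289
spid_0001 exp5 0.999921    True    41 15.25725 47.874222 0.911293 0.714496
spid_0002 hill 0.999808    True    41 15.25725 51.557397 1.018421 0.665823
spid_0003 exp5 0.999904    True    41 15.25725 47.115989 1.199782 0.793796
```

Reading the first row: the series is best described by a Hill curve
whose top (53.5) clears the endpoint cutoff (coff = 15.26, i.e.
3 x BMAD estimated from the two lowest concentration groups), the hit
call is essentially 1 (confidently active), the AC50 is 1.12 µM
(generating value 1 µM), the benchmark dose 0.62 µM, and fit category
41 marks a moderate-efficacy active whose AC50 and AC95 both sit inside
the tested range — the most quantitatively informative kind of curve.
The run log (`out/run_log.txt`) echoes every method applied per
endpoint:

```
endpoint ep: bmad_method=lowconc_twells cutoff_methods=['bmad3'] direction=bidirectional bmad=5.08575 onesd=10.6417 bmr=14.3556 coff=15.2572
```

Outputs are long-format CSVs mirroring the conventional level-4/5/6
layout: `mc4`/`mc4_param` (all model fits and their parameters),
`mc5`/`mc5_param` (winner, hit call weights, potencies), `mc6` (flags).
The same functionality is available as a library
(`concresp.run_pipeline`, `concresp.fit_all`,
`concresp.continuous_hitcall`, ...), and per-endpoint methods
(cutoff rules, fit direction, response scale) come from a YAML config
passed to `concresp fit --config`.

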