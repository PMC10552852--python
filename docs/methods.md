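# Methods

`concresp` processes multiple-concentration screening bioactivity data:
normalized response versus test-chemical concentration, one series per
sample x endpoint. This note records the models, the statistical
procedures, the defaults, and the design choices made where the design
was genuinely open.

## Concentration-response models

Ten parametric families are fit to every series (concentrations x in
µM; responses f(x) in the endpoint's normalized units):

| model    | f(x)                                   | parameters (+ er) |
|----------|----------------------------------------|-------------------|
| constant | 0                                      | —                 |
| poly1    | a·x                                    | a                 |
| poly2    | a·(x/b + (x/b)²)                       | a, b              |
| power    | a·xᵖ                                   | a, p              |
| hill     | tp / (1 + (ga/x)ᵖ)                     | tp, ga, p         |
| gnls     | tp / [(1 + (ga/x)ᵖ)(1 + (x/la)^q)]     | tp, ga, p, la, q  |
| exp2     | a·(e^(x/b) − 1)                        | a, b              |
| exp3     | a·(e^((x/b)ᵖ) − 1)                     | a, b, p           |
| exp4     | tp·(1 − 2^(−x/ga))                     | tp, ga            |
| exp5     | tp·(1 − 2^(−(x/ga)ᵖ))                  | tp, ga            |

All curves pass through the origin as x → 0⁺. The scale parameter (tp
or a) is free in sign, so one family covers induction and inhibition
(bidirectional fitting); endpoints meaningful in only one direction can
be constrained (`gain_only` / `loss_only`). Each fit carries an
error-scale parameter `er` (the log residual scale), included in the
parameter counts (constant has 1 parameter; poly1 2; poly2/power/
exp2/exp4 3; exp3/exp5/hill 4; gnls 6).

The gain-loss model's loss AC50 must exceed its gain AC50 by at least
1.5 log10 units. The bound is enforced as a box constraint on the
optimized width `log10(la) − log10(ga)`, so no fitted gnls curve can
violate it; its purpose is to keep a narrow gain-loss spike from
explaining a single elevated concentration at half-log plate spacing.

poly2's concentration scale b is restricted to b > 0; negative b would
create non-monotone shapes that this model is not intended to cover.

## Likelihood and optimization

Residuals are modeled as Student-t with 4 degrees of freedom and scale
exp(er) — a robust likelihood under which single outlying wells carry
bounded influence. Maximum likelihood is obtained by bounded L-BFGS-B
from three deterministic, data-derived starting points per model
(extreme group median, half-max crossing concentration, and grid-spread
alternatives), with central-difference gradients. Central differences
make the optimization exactly equivariant under response negation, so
fitting a series and its sign-flipped copy yields mirrored parameters
and bit-identical AIC values; this replaces the older practice of
duplicating endpoints and flipping responses into the positive
direction.

Parameter boxes: ga, la, b in [cmin/10, cmax·10]; p, q in (0.3, 8];
|tp|, |a| ≤ 12·max|resp|; er in [−12, log(max|resp|)+2]. The
concentration-scale parameters are optimized as log10 values. Bounds
keep inversions finite and are wide relative to any plausible signal;
the er floor makes the likelihood of an exactly noiseless series finite
(such fits sit at the floor and their AIC comparisons are dominated by
residual rounding — degenerate by construction, and harmless because
any ranking among perfect fits is acceptable).

Winner selection: the successful non-constant fit with the lowest AIC
(AIC = 2k − 2·loglik, k counting er). The constant model is always fit
but can never win; its AIC is retained as the reference for hit
calling. Exact AIC ties go to the model with fewer parameters, then to
a fixed precedence order (poly1, power, exp2, exp4, hill, exp3, exp5,
poly2, gnls) — arbitrary but stable. Series with fewer than 4 distinct
concentrations are not fit: winning model "none", hit call 0.

The constant model is the zero-response curve with only er free; the
alternative of fitting a free mean was rejected because the model is
defined as baseline (zero) response and the hit-call weight needs
exactly that null.

## Baseline variability and cutoff

Per endpoint, pooling across all samples:

* **BMAD** = 1.4826 × median absolute deviation of baseline responses.
  Baseline wells are the treatment wells at the two lowest
  concentration indices (default) or neutral-control wells. The
  consistency constant makes BMAD estimate sigma for normal noise.
  Pooling is per endpoint, not per plate; plate-level pooling is the
  documented alternative for designs with strong plate effects.
* **onesd** = pooled sample SD at the two lowest concentration indices;
  **BMR** = 1.349 × onesd (the response shift detectable at ~1.349
  baseline SDs). A neutral-control onesd variant is exposed but off by
  default.
* **cutoff (coff)** = max over the endpoint's assigned cutoff methods:
  `bmad3` (3×BMAD), `pc20` (20, for percent scales), `fc1.2`
  (log2(1.2), for log2 fold-change scales — the "1.2-fold change"
  method interpreted on the log2 scale, declared per endpoint via its
  scale annotation). The max rule mirrors how multiple assigned
  methods are conventionally aggregated.

## Continuous hit call

hitc = w_aic × w_median × w_top, each weight in [0, 1]:

* **w_aic** = 1 / (1 + exp((AIC_win − AIC_const)/2)) — the two-model
  Akaike weight of the winner against the constant model. A constant
  model 10 AIC units better caps hitc below 0.01.
* **w_median** — probability that at least one concentration group's
  median response exceeds the cutoff in magnitude, computed as the
  maximum over concentrations of the t(4) two-tail mass beyond ±coff
  for a median treated as t(4) around the fitted value with scale
  exp(er)/√n. The maximum-over-concentrations combination (rather
  than 1 − Π(1 − pᵢ)) was chosen so a single clear exceedance saturates
  the weight; the two differ only for borderline curves. A
  `v4.0_replicate` dialect scores individual replicate exceedance
  instead of group medians; the two coincide at one replicate per
  concentration.
* **w_top** — probability that the modeled |top| exceeds the cutoff:
  the signed-root likelihood-ratio statistic comparing the free fit to
  the fit with |top| profiled at the cutoff (scale parameter solved
  from the constraint, remaining parameters re-optimized), mapped
  through the standard normal CDF. It is 0.5 when the top sits exactly
  at the cutoff and approaches 0/1 as the evidence sharpens.

A hit call of ≥ 0.90 is labeled active by default; the threshold is a
user setting. The "approaches 0" contract for the constant-dominated
case is asserted quantitatively as hitc < 0.01 at ΔAIC ≥ 10.

## Potency metrics

All potencies are computed by inverting the winning model in
log10-concentration space and are reported in µM; a level that is never
attained is reported absent, never clamped.

ACxx values are fractions of the curve's *efficacy top*: the asymptote
tp for hill/exp4/exp5 (so AC50 = ga exactly), the interior peak for
gnls, and the modeled response at the highest tested concentration for
the unbounded families. This intrinsic-ceiling convention is what
allows a shallow, unsaturated curve to have its AC95 beyond the tested
range — the case the fit-category tree singles out. The *modeled top*
used for efficacy comparisons (fit categories, flags, w_top) is,
distinctly, the signed response of maximal magnitude within the tested
range. The inversion window extends four decades below and above the
tested range, because informative fits can place the AC50 below the
lowest tested concentration.

ACC inverts at the cutoff; ACB at 3×BMAD (always 3×BMAD, regardless of
which cutoff method is assigned); BMD at the BMR.

**BMD confidence interval.** The model is reparameterized so the BMD is
explicit: for a candidate BMD value, the scale parameter is solved from
f(BMD) = BMR and the remaining parameters and er are re-optimized,
giving the profiled log-likelihood. The 90% bounds are the
concentrations where the profile drops χ²₁(0.90)/2 ≈ 1.3528 below its
maximum, located by stepping 0.25 log10 units outward (warm-starting
each profile point from its neighbor) and Brent root-finding, within
two decades of the tested range; a bound that never brackets is
reported absent (noisy, flat data). On the package's fixed validation
design (exp4, tp=50, ga=1 µM, 8×3 half-log wells, t(4) noise of scale
5, seed bank 1..500) the acceptance suite computes the empirical
coverage of these intervals; the asymptotic χ² threshold is known to be
slightly anticonservative at 24 points with a heavy-tailed likelihood,
so small-sample coverage sits a few points below nominal. No Bartlett-
type correction is applied: the χ² drop is the normative definition
here.

## Fit categories

Curves split into cannot-determine (no winning model), inactive
(hitc < 0.90), and active. Inactive curves with |top| ≥ 0.8·coff are
borderline-inactive (the boundary counts as borderline); below that,
clearly inactive. Active curves split on |top| ≤ 1.2·coff (borderline)
versus above (moderate), then place by potency: AC50 ≤ cmin → 36/40;
else AC95 ≥ cmax (or AC95 absent) → 38/42; else 37/41 — the most
quantitatively informative AC50s. The 36–42 codes are fixed by
convention; cannot-determine and the inactive leaves carry codes 2, 13,
15 with the symbolic labels authoritative, since no conserved numbers
exist for them.

## Cautionary flags

Thirteen independent, purely annotational checks (they never alter any
result): replicate and concentration count floors, BMD above AC50,
single-concentration activity (baseline = 3×BMAD, consistent with the
ACB), multi-point inactives, incomplete gain-loss curves (gain AC50
below the range or loss AC50 above the mean of distinct tested
concentrations), RMSE above the cutoff, borderline efficacy band
[0.8, 1.2]·coff, sub-50% efficacy (50 response units on percent scales,
log2(1.5) on log2 scales), AC50 below the tested range, questionable
directionality (group medians beyond ±coff/2 on both sides — a
documented heuristic threshold, since "split across both axes" needs
an operational magnitude), and gain-loss winners on cell-viability
endpoints.

## Cytotoxicity burst

Rows with gnls winners or proliferation-direction responses are removed
first, so only genuine viability losses contribute. Per chemical, the
burst point is the median log10(AC50) over *active* endpoints (activity
= hitc ≥ 0.90), reported only when at least 3 endpoints were tested and
3 were active; otherwise the 1000 µM default. The global MAD is the
median, over chemicals tested in ≥ 60 burst endpoints with a hit rate
above 5%, of the scaled MAD of their active log10(AC50)s; the lower
bound is the burst point minus 3 global MADs. Chemicals on the default
never contribute to the global MAD. The tested/active thresholds are
exposed separately because the default rule counts tested endpoints
while lower-bound eligibility counts actives.

## Synthetic data

The generator emulates plate-style screening series: 8 concentrations
from 0.03 µM at 0.5 log10 spacing, 3 replicates, a known generating
model, and t(4) (default, scale 5 response units — a typical baseline
spread on percent scales) or normal noise, in either direction.
Identical configurations (including seed) are byte-reproducible. The
endpoint generator emits a long-format well table whose two lowest
concentration groups serve as baseline wells; the burst generator
plants per-chemical medians and dispersions exactly (symmetric
offsets), so downstream medians and MADs recover the planted truth.

What the generator does *not* emulate: plate positional artifacts,
normalization-step errors, correlated replicates, vendor-specific
designs, or concentration-dependent variance. Passing tests therefore
demonstrate correctness of the processing chain under its own error
model, not robustness to every real-data pathology.

## Validation problem sizes

The shipped suites use: 1000 inversion round-trips; 500 random mixed-
model series for winner-AIC minimality (with mirror-symmetry, hit-call
decomposition, and flag-purity spot checks); 100 seeds per model for
gain-AC50 recovery at noise SD equal to 5% of the top, judged by the
median estimate (per-seed scatter at this design is ~±7%, so a per-seed
criterion would measure sampling noise, not estimator quality); 500
simulations for BMD interval coverage; and byte-level determinism of
the pipeline outputs. These sizes were chosen as the smallest that make
the stochastic checks statistically meaningful.

## Known limitations

* Only gnls and poly2 depart from monotonicity; u-shaped and
  multiphasic responses are out of scope.
* No small-sample AIC correction and no model averaging.
* The BMD interval's χ² threshold is mildly anticonservative at
  plate-scale n (see above).
* LOEC-style hit calling for low-replicate, narrow-range designs is
  not implemented.
* The burst module consumes a prepared chemical x endpoint table; the
  curation of which endpoints count as burst-relevant is upstream of
  this package.
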