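# Methods

## Indicators

**Percent surface fines (SF).** Wolman pebble-count particles are assigned to
11 half-open size classes `[lower, upper)` in mm; the default boundaries are
0, 2.5, 6, 15, 30, 60, 120, 180, 300, 600, 1000, ∞ (a modified-Wentworth
series) and are configurable per run. All particles across the three bankfull
transects of a sample event are pooled before the fines fraction is taken:
SF = 100 × (count < 2.5 mm) / total. A particle measured exactly at 2.5 mm
falls in the next class up and is not fines; SF is therefore invariant to how
particles are split across transects and strictly increasing when a fines
particle is added.

**FSBI.** An occurrence-only index: the sum of per-taxon sediment-sensitivity
scores over the distinct taxa present (duplicates collapse, abundance is
ignored). Taxon names match case-insensitively after whitespace
normalization; there is no taxonomic roll-up, because roll-up rules are
program-specific. The authoritative published score table is external
literature; the packaged 26-taxon table is a synthetic demonstration table
for tests and examples. Scores above the 0–350 plausibility band are logged,
not rejected. Tolerance derivation (`derive_taxon_tolerance`) reports, per
taxon occurring at ≥ 5 events (configurable), the type-7 75th percentile of
SF at its occurrences; mapping percentiles to scores is left to a
user-supplied binning table.

## Reference benchmarks

Per Strahler order (1–4), a linear quantile regression of SF on bankfull
width at τ = 0.75 is fitted to reference-labelled events by minimizing the
pinball loss. Two solvers sit behind one interface:

- n ≤ 200 (default cutoff): exhaustive enumeration of all lines through
  pairs of observations with distinct widths. With two free parameters the
  LP optimum is attained at such a vertex, so this is exact. Pinball-loss
  problems can have flat optima; ties within 1e-9 of the best loss break
  deterministically to the smallest |slope|, then the smallest intercept.
- n > 200: iteratively reweighted least squares (statsmodels `QuantReg`),
  which agrees with the LP optimum to high relative precision at these
  sample sizes.

`predict_sf_ref` evaluates the fitted line at a reach's bankfull width and
clips to [0, 100]; the clipping rule is the package's choice for wide-reach
extrapolation, where the raw line goes negative. Degenerate inputs (all
widths equal, n below a configurable minimum of 10) are errors at the
operation level and "unavailable cells" at the orchestration level.

FSBI_ref is the type-7 25th percentile of reference FSBI per site class.
Type-7 (linear interpolation) is the default sample-quantile definition in
the major statistical environments and is recorded in the benchmark-set
metadata.

Before any fitting, when stream-segment ids (comid) are present, one
reference/stress event per segment is retained, selected by a seeded RNG
(`subsample_seed` is a required config field — without it the subsampling
step would be irreproducible).

## Stressor-response benchmarks

The binary response is 1 iff FSBI is **strictly** less than the class
FSBI_ref. Per site class × order cell, a binomial GLM with logit link is
fitted by IRLS; standard errors come from the observed information. Complete
separation (a single SF threshold perfectly splitting the labels) and
single-label cells are rejected with explicit errors; at the batch level
every failure is converted to an "unavailable" cell with a reason, never a
crash.

Diagnostics per cell: model χ² = null deviance − residual deviance (1 df);
odds ratio exp(β₁) with Wald CI exp(β₁ ± z·se₁) by default, or a profile
likelihood CI (intercept refitted with the slope fixed via an offset) on
request; and the Hosmer–Lemeshow test with 10 predicted-probability bins.
HL bins are near-equal-count with boundaries snapped forward past tied
predictions so the split is order-independent; bins whose expected count is
degenerate are merged into a neighbor and the statistic uses
χ² with (groups used − 2) df, erroring below 1 df. A cell with significant
HL p but adequate χ² and odds ratio is retained with a warning — calibration
lack-of-fit alone does not invalidate a benchmark whose discrimination is
good.

SR benchmarks invert the fitted curve: SF(p) = (logit(p) − β₀)/β₁, defined
only for β₁ > 0 (a non-increasing risk curve has no exceedance benchmark).
Reported values are rounded to the nearest integer, half away from zero;
full precision is retained internally, so
`predict_probability(invert_logistic(p))` is an identity to 1e-10.

A note on the published coefficient table this package can reproduce from
print: one intercept is printed as a bare magnitude (2.18) while every other
cell is negative, and only the negative reading is consistent with that
cell's printed SR75; the package reads it as −2.18 and flags the
interpretation here.

## Relative risk and false positives

Events are rated good/poor on each side: SF poor iff strictly above its
benchmark (reach-specific SF_ref, or a cell's SR50/SR75), biology poor iff
strictly below its benchmark (class FSBI_ref; or SMI2 / O:E cutoffs —
defaults 54/53/52 by class and 0.63, both configurable; the published
SMI2 guidance gives a 52–54 range without the class mapping, so the default
is a monotone assignment across classes). Equality is always "achieved".

RR is the ratio of survey-weighted stratum proportions
p̂₁ = Σw·1[bio poor, SF poor]/Σw·1[SF poor] over the analogous p̂₂ in the
good-SF stratum. The CI is Wald on the log scale with
var(log RR) = v̂₁/p̂₁² + v̂₂/p̂₂², where v̂ = Σw²(y−p̂)²/(Σw)² is the
single-stage Taylor-linearized variance of a weighted proportion. With unit
weights this reduces to the textbook 1/a − 1/(a+b) + 1/c − 1/(c+d) formula,
and the estimate and CI are invariant under rescaling all weights. Survey
packages for spatially balanced designs use a local-neighborhood variance
estimator instead; the simpler linearization is recorded in the output
metadata and is the package's design choice for generic weighted tables.
A zero denominator probability is an error (RR undefined); a zero numerator
returns RR = 0 with a degenerate CI and a warning.

False-positive rates on reference events are the percentages failing the SF
benchmark, failing the FSBI benchmark, and rated "likely" (failing both); by
construction the joint rate never exceeds either marginal.

## Assessment framework

The rating is a pure function of the two achievement flags:
(T,T) → unlikely, one of each → mixed_evidence, (F,F) → likely. No rating is
emitted on partial data — the framework is defined on paired data only, so
events missing an indicator, a width, or a benchmark cell are excluded and
tallied by reason. Only benchmark status matters, never the exceedance
magnitude. Aggregating ratings across reaches or years into a regulatory
assessment decision is out of scope.

## Synthetic data generator

The generator emulates the structure of a multi-year wadable-stream
monitoring dataset. Defaults (the study conditions of the packaged
experiments): 3 site classes with proportions (0.20, 0.54, 0.26) and orders
1–4 with proportions (0.17, 0.43, 0.30, 0.10), matching the cell sizes of
the published per-cell model table; per-order lognormal bankfull widths
(log-means 1.1/1.6/2.1/2.5 m, log-sd 0.35, i.e. typical widths ~3/5/8/12 m);
generating reference 75th-percentile SF lines equal to the published
per-order quantile equations; disturbance mix 10% reference / 10% stress /
80% ambient (mirroring the least/most-disturbed decile screening that
defines the labels).

SF is logit-normal around the quantile line:
`logit(SF/100) = logit(q75(BW)/100) + s·(z − z₀.₇₅) + d`, z ~ N(0,1), with
`s = sf_noise_scale` (default 0.5, chosen to give within-reach spreads of
roughly ±10–20 points at mid-range SF) and d an upward logit shift of 1.6
(stress) or 0.8 (ambient). By construction the conditional 75th percentile
of reference SF equals the configured line exactly for every width, SF is
bounded in (0,100), and `s = 0` collapses reference SF onto the line. The
within-reach noise law is a modelling convenience, not a claim about field
data.

Taxon presence is independent Bernoulli with logistic occupancy in SF over
a 26-taxon pool tied to the packaged score table: sensitive taxa (scores
14–25) have occupancy slopes of −0.065 to −0.09 per %SF, moderate taxa
around −0.02 to −0.03, tolerant taxa ≈ 0. A per-class intercept shift
(+0.7 / 0 / −1.2 logits) creates the richness gradient across classes, so
the emergent class FSBI_ref values fall in the same order-of-magnitude
pattern (~120/80/25) as real reference distributions. This mechanism
produces the characteristic wedge: high FSBI variance at low fines with a
declining upper bound as fines increase. Auxiliary SMI2 and O:E columns are
noisy linear functions of FSBI, sufficient for exercising the alternative
response indicators.

Weights are 1 (equal scheme) or stratum extent / stratum sample size under
order stratification with extent shares (0.45, 0.30, 0.15, 0.10); pebble
counts per event are three multinomial transects whose finest-class
probability is SF/100, so recomputed SF is unbiased for the event's SF.

The generating truth is recorded exactly as used: quantile lines are the
config's own coefficients; class FSBI_ref truth and per-cell SR truth (SF at
50%/75% exceedance probability of the true class 25th percentile) are
computed by Monte Carlo from the generating distributions (8000 reference
draws; exceedance curve on a 2-point SF grid with 3000 draws per point,
monotonized and inverted) inside a dedicated seed substream — never
re-estimated from the emitted sample.

What the generator does **not** emulate: spatial structure and GIS context,
temporal autocorrelation and repeat visits, taxonomic co-occurrence
(presence is independent across taxa given SF), crew and laboratory
measurement error, and non-logistic occupancy shapes. Passing
parameter-recovery tests therefore demonstrates the estimators are correct
under the stated model, not that field data meet these assumptions.

## Problem sizes of the packaged experiments

The end-to-end recovery experiment uses uniform class/order/disturbance
mixes with 6000 events (≈500 per logistic cell and ≈500 reference events
per order) and `sf_noise_scale = 0.15`. The low noise is deliberate: a
relative ±15% band on the order-4 quantile slope (−0.63 %/m) requires a
slope standard error ≲ 0.04, which at 500 reference events is only
attainable when the within-reach spread is small; the low-noise design
isolates estimator bias from sampling noise, the standard construction for
a recovery experiment. Other simulation-based tests use 120–4000 events and
40–200 replicates, sized to keep the default suite around ten seconds on
one CPU while leaving several standard errors of margin on every stochastic
assertion.

## Known limitations

- The quantile fits are independent across orders; nothing prevents fitted
  lines from crossing between orders.
- The RR confidence interval ignores spatial-balance information a design-
  based local-neighborhood estimator would use; with strongly informative
  designs it can be anti-conservative.
- Wald odds-ratio intervals degrade near separation; the profile option is
  preferable for small cells.
- The packaged score table is demonstrative; production FSBI scoring
  requires the published taxon table for the target region.
- Site-class derivation, landscape-disturbance screening, and the internal
  computation of SMI2 / O:E indices are consumed as inputs, not
  reimplemented.
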