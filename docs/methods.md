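# Methods

`thermotol` re-implements, as a tested pipeline, the statistical analysis
of the costs and benefits of winter acclimatization in *Drosophila
melanogaster*: nonparametric comparisons of thermal-tolerance limits
between field-acclimatized and laboratory-acclimated flies, and a
thermal-performance-curve analysis of egg-to-adult viability. Because no
raw data accompany the study, all inputs are produced by a synthetic-data
generator calibrated to the published summary statistics, so every
downstream guarantee is testable end to end.

## Randomization tests on median differences

Thermal-tolerance scores (static heat-knockdown time at 37 °C, CTmax and
CTmin from 0.1 °C/min ramps, 2 h chill-coma recovery time) violate
normality and homoscedasticity, so group contrasts use a two-sample
randomization test with the difference of group medians as the statistic,

    Md = median(group A) − median(group B).

The pooled values are re-partitioned into groups of the observed sizes; the
two-tailed p-value counts null statistics with |Md*| ≥ |Md_obs| (the
absolute-value method rather than tail-doubling, which assumes no symmetry
of the null distribution). Implementation choices:

* **Exact enumeration for small samples.** When C(n, min(n_A, n_B)) ≤ 10⁵
  all partitions are enumerated and the p-value is exact. Above that, the
  default Monte-Carlo budget is 100,000 draws, with the add-one correction
  p = (1 + #extreme)/(n_perm + 1), which guarantees p > 0 and a valid test.
  Whether the original analysis used such a correction is not stated; this
  is our documented choice.
* **Ties.** |Md*| ≥ |Md_obs| is evaluated with exact floating-point
  comparison. Heavy ties (e.g. vial proportions on a grid of 1/20) make
  the test conservative; no tolerance fudging is applied.
* **Symmetry.** The null stream depends only on the sorted pooled values,
  the smaller group size and the seed, so swapping the group order with the
  same seed returns the identical p-value and a negated Md.

Group medians are accompanied by percentile bootstrap confidence intervals
(default 10,000 resamples, 95% level, quantiles with linear interpolation).
The percentile method is the simplest interval consistent with the
published description; BCa-style corrections are out of scope.

## Quasi-binomial cubic viability model

Egg-to-adult viability at ten constant developmental temperatures
(11–33 °C; 20 vials × 20 eggs per temperature per parental treatment) is
modelled at the vial level as grouped-binomial logistic regression:

    logit p = β₀ + β₁z + β₂z² + β₃z³ + γ₀t + γ₁tz + γ₂tz² + γ₃tz³

with t the treatment indicator and z the centered/scaled temperature
(mean 0, sd 1 over the vials entering the fit). Raw powers of °C up to the
cube span three orders of magnitude and produce an ill-conditioned normal
matrix; standardizing first removes that while leaving deviances, fitted
values and F-tests unchanged. A raw polynomial basis (not orthogonal
polynomials) is used so the report stays interpretable; fitted coefficients
are also re-expressed on the raw °C scale.

Extra-binomial variation among vials is expected (shared micro-environment
within a vial) and handled quasi-likelihood style: point estimates are the
ordinary binomial IRLS fit (converged when the deviance changes by < 10⁻⁸,
at most 100 iterations), the dispersion is φ = Pearson χ²/df_resid, and
standard errors are scaled by √φ. Nested models are compared with

    F = [(D_reduced − D_full)/df_num] / φ_full  on (df_num, df_resid_full) df,

first the full model against an intercept-only null, then the full model
against the no-interaction reduction (df_num = 3 on this design; the
denominator df is n_vials − 8, i.e. 392 for the full 400-vial design).

**Benign-temperature standardization.** To compare curve *shape* rather
than overall level, each vial's proportion is divided by its treatment's
mean proportion over the benign temperatures 20 and 25 °C. Standardized
values are no longer binomial, so at each non-benign temperature the two
treatments are compared with the same median-difference randomization test
at the vial level. We interpret the standardization as vial-level relative
values (the declared test statistic is a median, so vial-level values are
the natural unit); the per-temperature p-values are reported unadjusted, as
in the original tables, with an optional Holm correction available but off
by default.

## Synthetic data generator

The generator's defaults *are* the study conditions; they are not tuning
knobs.

**Tolerance scores.** Each treatment × sex × assay group draws n = 25
values from a location-shifted gamma family: for requested skewness g ≠ 0
the shape is k = (2/|g|)², the scale is set so the sd equals the requested
spread, the draw is sign-flipped for g < 0, and the family is re-centered
so its *population median* equals the target exactly (g = 0 falls back to a
normal, spread = 0 to a constant). Two parameters thus control skew and
spread independently of the median — exactly the assumption violations the
randomization test is there for. Target medians reproduce the published
values: CTmin group medians are printed directly (field 0.62/0.74 °C,
lab-25 °C 6.19/5.92 °C for females/males; lab-13 °C implied 0.65/0.99 °C);
the other assays print only differences, so one anchor per assay is fixed
at a physiologically typical value (field-male knockdown 25 min, lab-female
CTmax 39.1 °C, field-female recovery 28 min) and the remaining medians
follow from the printed differences. Spreads and skews are unreported in
the study and are free parameters here, chosen once at values typical for
these assays (right-skewed times with sd 6–30 min, mildly skewed ramp
endpoints with sd 0.5–1.3 °C) such that the published significance pattern
is reproducible: the ~2 min recovery-time contrast stays undetectable at
n = 25 while the knockdown and ramping contrasts are detected essentially
always. The printed within-treatment sex differences for recovery time are
internally inconsistent by 0.02 min (rounding in the source tables); the
generator uses the within-sex differences, so the implied laboratory sex
difference is −0.67 min rather than the printed −0.65.

**Viability vials.** Vial counts are beta-binomial around the cubic
logistic curve: the vial's success probability is drawn from a Beta with
mean p and intra-vial correlation ρ, inflating the count variance by
1 + (m−1)ρ. The closed-form variance makes the generator testable against
an analytic oracle, and ρ = 0 reduces exactly to binomial sampling. The
default ρ = 0.05 gives φ ≈ 1.95, a moderate overdispersion. The default
curve coefficients were calibrated once (constrained least squares against
anchor viabilities) so that: both treatments have high, similar viability
at 20–25 °C with the field curve slightly lower overall (the feature that
motivates standardization); the field curve is depressed at 27–31 °C
(the cross-generational cost of winter acclimatization); and both curves
collapse together at 32–33 °C. The study's own per-temperature effect
sizes are not recoverable without raw data; the defaults reproduce the
significance *pattern*, not the printed Md values.

**Temperature logs.** Air temperature is a sinusoidal daily cycle
(default mean 2 °C, amplitude 4 °C, peak mid-afternoon) sampled half-hourly;
compost-heap sensors add an 8 °C fermentation offset and damp the daily
amplitude (0.35 near the surface, 0.12 at depth), plus optional Gaussian
noise. Readings are quantized to 0.1 °C after noise, mimicking logger
resolution. The generator does not model weather fronts, seasonal drift or
sensor drop-outs; microclimate summaries computed from it verify the
pipeline's bookkeeping (whole-day means, daily amplitudes, heap-vs-air
offsets), not meteorology.

## Determinism and seeds

Every stage seed is derived from the master seed by a stable hash
(SHA-256 of "seed:stage", truncated below 2³¹), so stages are decoupled
and the full pipeline is byte-identical across re-runs of the same
configuration. All randomness flows through `numpy.random.default_rng`.

## Problem sizes used in validation

The validation suite uses the study's resampling budgets where they are
cheap (bootstrap 10,000) and reduced budgets where many replicates are
needed: type-I error is estimated from 1,000 null replicates at 5,000
permutations each; bootstrap coverage from 500 replicates; the qualitative
pattern from 50 pipeline replicates at 2,000 permutations; coefficient
recovery from 100 replicates of the full 400-vial design. The
`--fast` configuration (5,000 permutations / 1,000 bootstrap draws) exists
for the same reason and leaves all qualitative conclusions unchanged.

## What passing tests do and do not show

Passing tests show the machinery is correct (exact agreement with
enumeration and Newton–Raphson oracles, nominal error rates and coverage
under the generator's assumptions) and that the analysis recovers the
published qualitative conclusions under data *shaped like* the study's.
They do not validate the generator's free parameters against real fly
data: real tolerance distributions, vial correlations, and microclimate
dynamics are richer than a three-parameter family, a single ρ, and a
sinusoid. The study's own real-data statistics (e.g. its interaction F
value and per-temperature Md values at n = 393 surviving vials — the lost
7 vials are unexplained, and the synthetic default uses the full 400-vial
design) are not reproducible from summaries and are not targets.

## Known limitations

* Only the percentile bootstrap and the median statistic are implemented;
  no stratified/paired permutation schemes, no alternative thermal
  performance forms (Gaussian, Weibull, Sharpe–Schoolfield), no GLMM vial
  random effects.
* The randomization test is conservative under heavy ties (standardized
  viability at near-zero survival).
* Fly age, parasite load, diet and diapause state — uncontrolled
  differences between field and laboratory flies in the original design —
  are deliberately not modelled.
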