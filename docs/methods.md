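# Methods

## The observer-actor model

A trial is modelled as a three-stage chain.  A sample `s` is drawn from the
task prior (discrete uniform; e.g. 11 interval values on [600, 1000] ms).
A noisy **pre-inference stage** produces `x`; a deterministic **inference
stage** maps `x` to an estimate; a noisy **post-inference stage** produces
the response `t_p`.  Noise at either stage is Gaussian and either *scalar*
(Weber: SD = `w · mean`, dimensionless `w`; used for time and length) or
*additive* (SD = `σ` in stimulus units; used for reach angles).  Scalar
noise is undefined at non-positive centers and the code enforces that.

The inference stage is the Bayes-Least-Squares estimator that minimises
expected squared *production* error, i.e. it knows the production stage is
noisy.  With a uniform prior on `[a, b]` and the Gaussian measurement
likelihood, the solution is the posterior mean under additive production
noise, and the posterior mean divided by `1 + w_post²` under scalar
production noise (producing large magnitudes is costlier when noise grows
with magnitude, so optimal estimates shrink slightly toward zero).  The
package carries both a closed-form implementation (`bls_closed_form`, and
its vectorised sibling `bls_estimate`) and a brute-force expected-loss
minimiser (`bls_numeric`) kept deliberately independent so it can serve as
the oracle in tests; they agree to within 0.1% of the prior range across a
randomized sweep.

Strategies differ in where this estimator sits:

* **none** — no inference; the response is the noisy transformed
  measurement.
* **early** — infer the sample (prior over samples), then transform, then
  produce.  Note the early observer applies its scalar-production shrinkage
  on the *pre-transform* scale; this is a defined behavior of the chain,
  marginally suboptimal for non-gain transforms.
* **late** — transform, then infer the transformed value (prior over
  transformed values), then produce.  Under late inference, scalar
  pre-inference noise scales with the transformed magnitude (`w_pre · g·s`),
  since Weber noise scales with the mean of the quantity it corrupts.  The
  alternative reading (scaling with the raw sample) is an exact
  reparameterisation `w → w/g` of the same family, so nothing observable
  hinges on the choice.

The observer's internal prior is **continuous** uniform over the support
range even though samples are drawn from a discrete grid — matching the
Simpson-rule integration of the fitting procedure; a discrete-prior variant
is available via `inference_prior_for(..., form="discrete_uniform")`.

## Summary statistics and the analysis pipeline

Per sample value `i` with `n_i` trials: `bias_i` = mean error, `var_i` =
sample variance (ddof 1).  The context-level statistics are the
trial-count-weighted combinations `BIAS = √(Σ nᵢ biasᵢ²/Σ nᵢ)`,
`√VAR = √(Σ nᵢ varᵢ/Σ nᵢ)`, `RMSE = √(VAR + BIAS²)`; weighting uses
`n_i/Σn_i` for both (the source text states trial-count normalisation
without a formula).  The pipeline order is fixed: adaptation exclusion →
lapse filter → offset removal → summarize → (optionally) fit.

*Lapse filter.* Within each (context, sample) cell, trials farther than
3× the raw median absolute deviation from the **cell mean** are excluded;
no 1.4826 consistency factor is applied (the literal reading of the
procedure).  Consequence worth knowing: for clean Gaussian cells 3×MAD ≈
2.02 SD, so roughly 4.3% of legitimate trials are trimmed; the resulting
small downward pull on variance-driven quantities is shared by data and
model comparisons alike because the pipeline is applied uniformly.  Cells
with fewer than 4 usable trials are skipped with a warning.  Degenerate
cells (MAD = 0) remove nothing (strict inequality).

*Offset.* One constant per subject and context, estimated as the mean
signed error and subtracted; it represents an overall tendency to respond
long/short and is deliberately *not* a fitted model parameter.

*Bootstrap.* Basic (reflected) 95% intervals, `n = 1000` by default,
resampling trials with replacement stratified within each sample cell to
preserve the per-sample design.

*Null predictions.* Under no extra transformation noise, a gain-`g`
remapping of a scalar-noise observer scales the whole production
distribution by `g` (scale covariance), hence BIAS, √VAR and RMSE each
scale by `g`; an additive remapping with additive noise leaves all three
unchanged.  `excess_bias` is observed minus predicted, the package's
headline quantity: positive excess bias is the late-inference signature.

*Group stage.* Across-subject comparisons use the two-sided Wilcoxon
signed-rank test (exact null distribution for n ≤ 25 without zero
differences), and subject screening uses d′ between the extreme sample
cells (pooled-SD denominator; `+inf` sentinel when responses are
noise-free).

## Maximum-likelihood fitting

The per-trial likelihood marginalises the unobserved pre-inference value:
`p(t_p|s) = ∫ p(t_p | c(x)) p(x | m(s)) dx`, where `m(s)` is the stage mean
(sample for early, transformed sample for late) and `c(x)` the production
center (`T(f_BLS(x))` early, `f_BLS(x)` late).  The integral runs over
`m(s) ± 4` local SDs on a 101-node Simpson grid; posteriors use 201 nodes
over the prior support (doubling either grid changes fitted parameters by
far less than their sampling error).  Densities are floored at 1e-300
before logs; parameter regions that push scalar production centers
non-positive get that floor as their likelihood.

Optimisation is Nelder–Mead on log-parameters (positivity without
constraints), tolerance 1e-6, ten restarts by default with log-uniform
initialisations on [0.01, 0.5] (Weber) or [0.1, 0.3 × prior range]
(additive σ).  The reported solution is the best restart; estimates
collapsing below 1e-3 of the initialisation floor flag the fit as
degenerate (this is what noise-free data produce — the likelihood has no
interior optimum there).  Early and late variants have equal parameter
counts, so model comparison uses raw log-likelihood differences.

### Identifiability of early vs. late inference

A single-context comparison can only distinguish the strategies when the
noise family is *not* closed under the context transformation.  Scalar
noise + gain (the interval and length tasks) and additive noise + gain or
offset (the reaching task) each admit an exact reparameterisation mapping
one family onto the other, so their fitted log-likelihoods tie identically
— the package asserts this equivalence as a test, and the scientific
discrimination in those designs comes from *cross-context parameter
changes* (extra MTN surfacing in `w_pre` for late observers vs. `w_post`
for early ones).  The one symmetry-breaking combination in this model space
is scalar noise with an additive remapping; `make_strategy_probe_spec`
exposes such a design (the [600, 1000] ms prior remapped by −450 ms so the
response range [150, 550] ms has strong Weber heteroscedasticity), on which
single-table strategy recovery at 600 trials succeeds in ≥ 18/20
replicates with MTN equal to the baseline sensory noise.

## Synthetic study conditions

The generators emulate the four designs exactly as printed: interval
reproduction (11-point prior on [600, 1000] ms; gains 1, 1.5, 0.75; scalar
noise; 600-trial sessions), center-out reaching (11 angles spanning 45°
centered straight ahead; +60° rotation implemented as `correct = sample +
60` with no wraparound — the prior spans only 45°, so circular statistics
are unnecessary and the rotation sign is a convention; additive noise;
150-trial blocks with the first 25 trials tagged as adaptation), and
length identification (7-point prior on [4, 7] deg; gain 1.5; 29 response
options on [2, 9] / [3, 13.5] deg).  Productions in the length task are
snapped to the nearest option *after* production noise (ties to the
smaller option), while the fitted model keeps the continuous
infinite-choice limit — the generator is intentionally slightly
misspecified relative to the fitted model, mirroring the modelling
simplification it emulates.  Samples are drawn uniformly *with*
replacement, so per-sample trial counts are unbalanced, which is why the
summary statistics are count-weighted.

Cohorts draw per-subject parameters uniformly from ranges chosen to bracket
the fitted values reported for human subjects in this task family: Weber
fractions `w_pre ∈ [0.08, 0.16]`, `w_post ∈ [0.05, 0.09]`, extra
remapped-context MTN `∈ [0.10, 0.16]` (folded in quadrature into `w_pre`
for late cohorts, `w_post` for early ones), lapse rate 2%, per-subject
offset SD 10 ms, 11 subjects, 600 trials per context.  Lapse productions
are uniform on [0.5 × min correct, 1.5 × max correct] — a modelling choice;
the analysis pipeline only removes lapses, it never fits them.  An optional
exponentially decaying under-compensation (time constant 10 trials) can be
prepended to remapped reaching blocks to motivate the 25-trial exclusion;
it is off by default.

What the generators deliberately do **not** emulate: movement kinematics
and reaction times, feedback staircases and hit/miss thresholds, trial-by-
trial learning of the transformation, non-Gaussian lapse structure, and
drifting parameters within a session.  Passing tests therefore demonstrate
that the analysis pipeline and estimator behave correctly under the model's
own assumptions — parameter recovery, strategy geometry, null calibration —
not that those assumptions exhaust real behavior.

## Problem sizes and numerical checks

Monte-Carlo assertions use n = 1e5 trials (strategy geometry, scaling law,
excess-bias signatures), where the statistics' sampling error is well below
the asserted margins; recovery studies use the session size of 600 trials
with 20 replicates (10 restarts per fit for parameter recovery, 4 for the
model-recovery study, where the log-likelihood gap between strategies
dwarfs restart-to-restart variation).  The oracle sweep covers 1000 random
(prior, noise, observation) configurations, half scalar, half additive.
Bootstrap coverage is checked over 120 replicate experiments against the
long-run RMSE of a 1.5e5-trial run.  All randomness flows through explicit
seeds; cohort members derive their streams from (master seed, subject
index).

## Known limitations

* The likelihood treats the length task's discrete choices as continuous;
  at 29 closely spaced options the discretisation error is far below the
  fitted noise, but very coarse choice sets would need the discrete
  likelihood this package deliberately omits.
* The lapse filter's ~4% trim of clean Gaussian data (see above) makes all
  variance-derived quantities mildly conservative; the recovery harness
  therefore fits generator output directly when no lapse process is
  simulated.
* `run_reproduce` fits, when enabled, use the cohort's generating strategy;
  fitting both strategies per subject is available through
  `compare_models` but is only informative on symmetry-breaking designs.
* Degenerate posteriors (observations numerically outside the support) are
  flagged, not silently clipped; callers looping over extreme parameter
  regimes should handle `DegeneratePosteriorError`.
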