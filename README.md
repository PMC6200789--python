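# obsact — Bayesian observer-actor models of mental transformations

`obsact` is a simulation and analysis toolkit for a family of psychophysics
experiments in which people measure a scalar quantity (a time interval, an
angle, a length) and then produce a *transformed* version of it — 1.5× the
interval, the angle plus 60°, three quarters of the duration.  Applying such
a sensorimotor or mental transformation is itself noisy (mental
transformation noise, MTN), and the central scientific question the package
operationalises is **where the brain places its Bayesian inference relative
to that transformation**:

* **early inference** — estimate the stimulus first, then transform: prior
  knowledge can only counteract measurement noise, so extra MTN shows up as
  extra response *variability*;
* **late inference** — transform first, infer afterwards: the prior now also
  absorbs MTN, which shows up instead as extra *bias* toward the prior mean,
  while keeping the total error lower.

## The model

Each trial passes through three stages.  A sample `s` drawn from a discrete
uniform prior is corrupted to a pre-inference value `x` (Gaussian, either
*scalar* — Weber — noise with SD `w_pre · mean`, or *additive* noise with SD
`σ_pre`); a deterministic Bayes-Least-Squares stage maps `x` to the estimate
minimising expected squared production error,

```
f_BLS(x) = argmin_t ∬ (t_p − t_c)² p(x | t_c) π(t_c) p(t_p | t) dt_p dt_c
         = E[t_c | x]                    (additive production noise)
         = E[t_c | x] / (1 + w_post²)    (scalar production noise)
```

with `π(t_c)` uniform over the (early: sample; late: transformed) support;
and a noisy production stage emits `t_p`.  Behavior is summarised per
context by the trial-count-weighted statistics

```
BIAS = √(Σᵢ nᵢ biasᵢ² / Σᵢ nᵢ),   √VAR = √(Σᵢ nᵢ varᵢ / Σᵢ nᵢ),
RMSE² = BIAS² + VAR
```

and compared against the no-extra-MTN null (identity-context statistics
scaled by the gain, or unchanged for a rotation).  Observer noise
parameters are fitted per subject and context by maximum likelihood, with
the unobserved pre-inference value marginalised by Simpson quadrature and a
multi-restart Nelder–Mead simplex in log-parameter space.

Because the original human datasets are not publicly deposited, the package
ships generators that emulate the four experiment designs (interval
reproduction with gains 1.5 and 0.75, center-out reaching with a 60°
rotation, length identification with a 29-option choice set), so every
analysis stage is exercised end-to-end on synthetic cohorts.

## Worked example

```python
import obsact as oa

spec = oa.make_experiment_spec("exp1_rsg_g15")     # interval task, gain 1.5
remapped_obs = oa.ObserverParams("late", oa.NoiseModel("scalar", 0.17),
                                 oa.NoiseModel("scalar", 0.07))
identity_obs = oa.ObserverParams("late", oa.NoiseModel("scalar", 0.11),
                                 oa.NoiseModel("scalar", 0.07))

tables = {"identity": oa.generate_subject(spec, "identity", identity_obs, 600, seed=42),
          "remapped": oa.generate_subject(spec, "remapped", remapped_obs, 600, seed=43)}
stats = {}
for name, t in tables.items():
    t, _ = oa.filter_lapses(t)          # 3×MAD lapse removal
    t, off = oa.remove_offset(t)        # constant response offset
    stats[name] = oa.summarize(t, offset_removed=off)
    s = stats[name]
    print(f"{name:9s}  BIAS {s.bias:6.1f}  sqrtVAR {s.sqrt_var:6.1f}  RMSE {s.rmse:6.1f} ms")

pred = oa.predict_h0(stats["identity"], spec.contexts["remapped"])
print(f"H0 pred    BIAS {pred.bias:6.1f}  sqrtVAR {pred.sqrt_var:6.1f}  RMSE {pred.rmse:6.1f} ms")
```

prints

```
identity   BIAS   42.9  sqrtVAR   64.1  RMSE   77.2 ms
remapped   BIAS   98.9  sqrtVAR  105.0  RMSE  144.2 ms
H0 pred    BIAS   64.4  sqrtVAR   96.2  RMSE  115.8 ms
```

The remapped-context BIAS (98.9 ms) far exceeds the 64.4 ms predicted by
simply scaling the identity context — the excess bias (≈34 ms) is the
late-inference signature: the simulated observer carried extra
transformation noise *before* its inference stage, and the prior soaked it
up as bias rather than variability.  Fitting the model recovers where the
noise lives:

```python
t, _ = oa.filter_lapses(tables["remapped"]); t, _ = oa.remove_offset(t)
res = oa.ObserverActorModel(t, spec, "remapped", strategy="late").fit(seed=0)
print(res.summary())
```

```
Observer-actor model fit
==============================================
experiment            exp1_rsg_g15
context               remapped
strategy              late inference
noise kind            scalar
n trials              575
log-likelihood        -3483.481
restarts (converged)  10 (10)
----------------------------------------------
w_pre                 0.1556
w_post                0.0531
==============================================
```

`w_pre` (generating value 0.17) comes back much larger than the
identity-context value (0.11), while `w_post` stays near its generating
0.07 — the fitted fingerprint of late inference.

A command-line interface mirrors the library
(`obsact simulate | stats | fit | recover | compare | reproduce`); e.g.

```sh
obsact reproduce --subjects 11 --trials-per-context 600 --outdir run1
```

chains generation → lapse filtering → offset removal → summary statistics
with bootstrap CIs → null predictions → group signed-rank tests and writes
CSV/JSON report tables.

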