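# svcpois

Semi-varying coefficient conditional Poisson models for daily helpline call
counts driven by television advertising exposure.

## The problem

Telephone quitlines are a front-line smoking-cessation intervention, and
television anti-smoking campaigns are their main demand driver.  Campaign
pressure is measured in TARPs (target audience rating points — the expected
audience exposure of a demographic group per day).  The statistical question
is how daily call volume responds to advertising weight and day-of-week
structure when the relationship also drifts with time: holiday surges,
residual effects of past campaigns, and news events all move call volume in
ways no recorded covariate explains.

A useful mental model is a cohort at risk of calling: of the `Y_{j-1}` people
engaged enough to call yesterday, a time-varying fraction carries over into
today's callers, while fresh callers "immigrate" in response to today's
advertising and the day of the week.  A chain-binomial depletion model with a
large cohort and small daily call probabilities leads to the conditional
Poisson form used here.

## The model

For daily counts `Y_j` with `F_{j-1}` the history through day `j-1`,

```
E(Y_j | F_{j-1}) = Y_{j-1} (alpha_j + X_j' beta) + Z_j' gamma
```

with `Y_j | F_{j-1} ~ Poisson` (identity link), where

* `alpha_j = alpha(t_j)` is a smooth time-varying carryover rate — the
  nonparametric part that absorbs unmeasured temporal structure;
* `X_j` holds six day-of-week indicators (Mon..Sat; Sunday is the all-zero
  reference), so `beta` modulates the carryover by weekday;
* `Z_j = [X_j, TARP_quit_j, TARP_nrt_j]` and `gamma` gives the mean number
  of new callers per day: six day effects (calls/day) and two advertising
  effects (calls per TARP unit).

Estimation is profile backfitting: local-linear kernel smoothing of partial
residuals for `alpha(.)` alternating with identity-link quasi-Poisson
estimating equations for `(beta, gamma)`.  Standard errors come from an
overdispersion-adjusted residual bootstrap (conditional variance `phi * mu`),
with goodness of fit summarised by the Poisson deviance R², Pearson
residuals, and a regression-based overdispersion test.  Four simpler
reference models (least squares on TARPs, identity-link Poisson on TARPs,
constant-`alpha`, varying-`alpha` without the weekday carryover) support an
MSE comparison.  A generator produces realistic synthetic series — TARP
flight schedules, weekly call cycles, smooth `alpha(t)` with troughs in the
no-advertising season and a New-Year surge — with known ground truth, under
Poisson, negative-binomial, or chain-binomial noise.

## Worked example

```python
import svcpois as sp

series, truth = sp.simulate_calls(sp.SimConfig(), seed=1)   # 360 days
fit  = sp.SVCPoissonRegressor(bandwidth=14.0).fit(series)
boot = sp.bootstrap_se(fit, B=500, seed=1)
print(sp.wald_table(fit, boot).head(3).to_string(index=False,
                                                 float_format=lambda v: f"{v:.3f}"))
rep = sp.diagnose(fit)
print(f"deviance R2 = {rep.deviance_r2:.3f}; MSE = {rep.mse:.1f}")
print(sp.compare_models(series, bandwidth=14.0).to_string(index=False))
```

prints

```
       name  estimate    se      z     p
beta1 (Mon)     0.053 0.062  0.848 0.396
beta2 (Tue)    -0.170 0.039 -4.339 0.000
beta3 (Wed)    -0.389 0.036 -10.802 0.000
deviance R2 = 0.974; MSE = 65.3
  model         mse
Model 1 1516.460850
Model 2 1537.928125
Model 3  190.288095
Model 4  196.141030
Model 5   65.341428
```

The `beta` rows say how yesterday's callers carry into today: the negative
Tuesday–Saturday modifiers mean a busy day depletes the at-risk pool for the
next day, while Monday recovers the weekend's accumulated demand.  The MSE
table shows the full model (Model 5) halving the error of its constant-rate
restriction (Model 3) and improving on unconditional regression on TARPs
(Model 1) twenty-fold, because the simulated carryover rate truly varies
over the year.  The same pipeline runs from the shell:

```
svcpois simulate --seed 1 --outdir out/
svcpois fit --input out/series.csv --models 1,2,3,4,5 --outdir out/
svcpois bootstrap --input out/series.csv --B 500 --seed 1 --outdir out/
```

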