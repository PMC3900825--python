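# Methods

## Model and assumptions

The observed record is a gap-free run of days with call count `Y_j` and two
non-negative advertising-weight covariates (TARPs).  The model is a
first-order conditional Poisson autoregression with an identity link and a
semi-varying coefficient:

```
mu_j = E(Y_j | F_{j-1}) = Y_{j-1} (alpha(t_j) + X_j' beta) + Z_j' gamma,
```

`X_j` six weekday indicators (Sunday reference), `Z_j = [X_j, TARP_quit,
TARP_nrt]`.  Day 1 is conditioning-only: all fitting, diagnostics and
exports are indexed by response days `j = 2..J`, and exported tables carry
the calendar date to avoid off-by-one ambiguity.  Weekday is derived from
the calendar date, so arbitrary start days and partial weeks work.

Assumptions worth keeping in mind:

* identity link — effects are additive in calls, and a fitted mean can in
  principle go non-positive.  The public `conditional_mean` treats
  `mu <= 0` as a hard error; iterative solvers clip instead (below).
* conditional Poisson variance, relaxed to `Var = phi * mu` for inference
  (quasi-likelihood: only the first two moments are used).
* `alpha(.)` smooth at the multi-week scale; weekly structure belongs to
  `beta` and `gamma`, not to the curve.
* days with `Y_{j-1} = 0` contribute only through the immigration term, and
  carry zero weight in the smoothing step (the curve multiplies `Y_{j-1}`).

## Estimation

Profile backfitting with two half-steps:

**Curve step.** Given `(beta, gamma)`, form partial residuals
`R_j = Y_j - Y_{j-1} X_j'beta - Z_j'gamma` and fit, at each target day
`t0`, the kernel-weighted least-squares problem

```
min_{a,b}  sum_j w_j(t0) [R_j - Y_{j-1} (a + b (t_j - t0))]^2 ,
```

`alpha(t0) = a`.  Weights are `K((t_j - t0)/h)` (Epanechnikov by default;
Gaussian available) divided by `max(mu_j, floor)` when quasi-Poisson
variance weighting is on (the default).  Local-linear fitting is
design-adaptive at the boundaries, so the asymmetric end windows are used
as-is, with no reflection.  A target whose window holds fewer than two
effective points (kernel support with `Y_{j-1} > 0`) gets a progressively
doubled window, with a warning; if the whole series is uninformative the
smoother falls back to a local-constant value.  The kernel moment matrices
depend only on the time grid and bandwidth, so they are computed once and
reused across iterations and bootstrap refits.

**Parametric step.** Given the curve, solve the identity-link quasi-Poisson
estimating equations `sum_j (Y_j - mu_j)/mu_j * d_j = 0` by iteratively
reweighted least squares with offset `Y_{j-1} alpha_j` and weights
`1/max(mu_j, floor)`.  The step also estimates a constant shift `c` of the
curve (design column `Y_{j-1}`) and folds it back into `alpha`: the constant
direction of the curve is partially confounded with the carryover columns,
and without profiling it out it is the slowest backfitting mode by far.
One IRLS sweep per backfit iteration suffices — the outer alternation
supplies the remaining sweeps and keeps each iteration a plain coordinate
update.

**Initialization and convergence.** The starting point is a single joint
constant-`alpha` fit (the constant-rate restriction, Model 3).  The loop
stops when the largest change across `(alpha, beta, gamma)`, relative to
the largest current magnitude, drops below `tol = 1e-6`, with a cap of 100
iterations; non-convergence produces a warning and the last iterate, never
a silent failure.  The Pearson-weighted residual sum of squares is recorded
per iteration; because a local-polynomial smoother is not a symmetric
projection, descent is not exactly monotone — in practice the overall path
descends, with isolated single-step upticks below about `1e-4` relative.

**Numerical guards.** Means are clipped at `eps = 1e-8` inside solvers, but
variance *weights* use a higher floor of 1% of the mean count: an
identity-link mean that wanders to `eps` mid-iteration would otherwise hand
one day a weight of `1e8` and capsize the weighted solve.  Singular weighted
cross-products are detected by Cholesky; the public parametric-step API
raises naming the collinear columns, while the full fit falls back to a
minimum-norm solution with a `DegenerateDesignWarning` (constant counts,
which make `Y_{j-1} X_j` collinear with `X_j`, are the canonical case).  An
identically-zero TARP column is a hard error: the advertising effect is not
identifiable.

**Bandwidth.** Default 14 days, with candidates {7, 10, 14, 21, 30}: the
trend features of interest (flights, holiday surges, advertising-gap
troughs) live at the one-to-four-week scale.  `bandwidth="auto"` runs
leave-one-out cross-validation of the one-step squared prediction error:
for each candidate the full backfit runs (warm-started along the grid), and
`alpha(t_j)` is re-estimated leaving day `j` out of the smoothing step with
`(beta, gamma)` and the weights frozen — the parametric part has 14
parameters against hundreds of days, so its leave-one-out perturbation is
negligible.  At the target's own time point the left-out observation sits
at local abscissa zero, so only two moment sums change, and the whole CV
curve costs little more than one fit per candidate.  Ties break toward the
smoother bandwidth.

**Reference models** (for the MSE comparison, all scored on days `2..J` so
every model sees identical responses): (1) ordinary least squares of `Y_j`
on `(1, TARP_quit, TARP_nrt)` via statsmodels; (2) the identity-link Poisson
with the same mean, fitted by the package's own IRLS (statsmodels'
identity-link Poisson aborts when an IRLS step goes negative; the in-house
solver clips and carries a weight floor, and is cross-checked against
statsmodels on a benign design in the tests); (3) the constant-`alpha`
restriction, fitted as one joint parametric solve; (4) varying `alpha` with
immigration but no weekday carryover; (5) the full model.  Models 3 and 4
are not nested in each other: which wins depends on whether the temporal
variation of the carryover rate or its weekday modulation explains more
variance, and with weekday modifiers as large as those used in the default
scenario (Saturday carryover 0.75 below baseline) the constant-rate model
usually edges out the no-weekday model on synthetic data even though the
original study's data ordered them the other way.

## Inference

**Dispersion.** `phi_hat = (1/n) sum (y_j - mu_j)^2 / mu_j`, the value
giving the modified Pearson residuals `r*_j = (y_j - mu_j)/sqrt(phi mu_j)`
unit second moment.  A near-zero estimate is flagged: data sitting exactly
on the fitted means cannot carry Poisson noise.

**Bootstrap.** Conditional (fixed-design) residual bootstrap: residuals
`r*` are re-centred and resampled with replacement; pseudo-responses
`y^b_j = mu_j + r*^b_j sqrt(phi mu_j)` are refitted with the bandwidth
frozen at the original value (the target is the parametric component;
re-selecting the bandwidth per replicate would mix smoothing variability
into the standard errors).  All regressors — including the previous-day
counts the model conditions on — stay at their observed values: for a
conditional autoregression the sampling variance of the estimator is the
conditional-on-past one, and lagging pseudo-responses into the design would
add errors-in-variables spread to exactly the carryover coefficients.
Pseudo-responses are not rounded (the quasi-likelihood refit needs only
moments); negatives are truncated at zero and counted.  Replicates that
raise (singular refit) are redrawn, and more than 10% of them is an error;
non-converged refits are kept, since their estimates are still defined.
Residual standardization always uses the data's own dispersion; the `phi`
argument sets only the reconstruction scale, so `phi=1` yields the
unadjusted Poisson-scale bootstrap and the default restores the empirical
dispersion.  Day 1 is fixed throughout.  `B = 5000` is the reporting
default; calibration-style studies in the test suite use `B = 200`.

Wald `z = estimate/se` with two-sided normal p-values; pointwise bands for
`alpha(.)` are percentile bands across the replicate curves (a normal
variant is available), expanded where needed to contain the point estimate.
The band's construction is a package choice — uniform bands and
bias-corrected intervals are out of scope.

**Diagnostics.** Poisson deviance R² (`0 ln 0 = 0` convention; all-equal
counts make the null saturated and raise), Pearson residual mean/variance,
and the intercept-only overdispersion regression `Y*_j = phi + u_j` with
`Y*_j = [(Y_j-mu_j)^2 - Y_j]/mu_j`, tested one-sided against
overdispersion with the ordinary intercept standard error (an HC-robust
variant sits behind a flag; for an intercept-only regression the two differ
only in a degrees-of-freedom factor).

## Synthetic data

The generator emulates the structure of a year of quitline data without
reproducing any real series.  Schedules and the curve presets are functions
of *relative* position `u = t/n_days`, so longer series stretch the same
scenario and sample each feature more densely.

* **TARPs**: four flights per campaign with sine envelopes and
  gamma-distributed day-to-day jitter; campaign A ("Quit") places ~75% of
  its weight Monday–Wednesday, campaign B ("NRT") is uniform over the week;
  both are dark across `u ~ 0.56-0.88` (the autumn advertising gap).
  Overlapping flights sum.
* **Carryover curve** preset "seasonal-troughs": baseline 0.92 with three
  troughs across the advertising gap (floor ~0.72) and two isolated
  surges — a New-Year peak (+0.33) and a smaller late-May one (+0.20).
  Surge height is bounded by weekly subcriticality: a sustained carryover
  product above 1 per week makes counts explode, which pins realistic peak
  amplitudes well below what the Saturday-positivity floor alone would
  allow.  The published weekday and advertising effects (rounded) serve as
  the parametric truth; they set realistic scales, not values any fit must
  reproduce on real data.
* **Noise**: Poisson; negative binomial with `Var = phi mu` (`phi > 1`);
  or a chain-binomial depletion model `Y_j ~ Bin(N_j, mu_j/N_j)`,
  `N_{j+1} = N_j - Y_j`, whose small-p, large-N behaviour is Poisson — the
  `p`-link is a generator convention, documented, not a claim about any
  real mechanism.  A zero conditional mean is an absorbing state (the draw
  is zero); a negative one is a configuration error reported with the
  offending day.  A deterministic dry run of the expectation path validates
  positivity before any draws.

What the generator does *not* emulate: overdispersion that varies over
time, holiday calendar effects beyond the smooth surge, campaign creative
changes, serial correlation beyond first order, and hourly structure with
its many zeros.  Passing tests therefore demonstrate correctness of the
machinery under the stated data-generating mechanisms, not robustness to
every feature of real helpline data.

## Study sizes used by the test suite

Chosen to give stable Monte-Carlo answers at desk scale: parameter-recovery
bias uses 200 replicates of the 360-day scenario (bias is compared against
15% of each coefficient's scale, where scale is the coefficient's magnitude
floored at its block's root-mean-square — blocks: carryover modifiers, day
immigration effects, TARP effects, whose magnitudes span two orders).
Smoothing error is studied on the stretched design with the bandwidth a
fixed fraction of the series length (14/360), so doubling the length
doubles the in-window sample and the variance term halves while the
(small) bias term is unchanged; 60 replicates per length.  Bootstrap
calibration compares Monte-Carlo sd over 200 datasets with bootstrap se
averaged over 8 datasets at `B = 200`.  Coverage, power and approximation
checks run at similarly reduced sizes, documented in the individual tests.

## Known limitations

* Identity-link means can go non-positive on wild data; the fit warns,
  clips, and flags `positive_ = False` rather than failing.
* In-sample MSE comparisons favour flexibility; no degrees-of-freedom
  penalty is applied across the model zoo (formal non-nested selection is
  out of scope).
* The curve's bandwidth is treated as fixed for inference; uncertainty in
  `h` is not propagated.
* Out-of-sample prediction would need `alpha(t)` beyond the fitted range
  and is deliberately not offered; refit on the extended series instead.
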