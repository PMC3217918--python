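# Methods

## Model

Two compartments, CSCs `S(t)` and differentiated cancer cells `D(t)`, in a
nutrient-unconstrained suspension culture:

    dS/dt = k1·S − a·S + b·D
    dD/dt = k2·D + a·S − b·D

All four rates are non-negative per-day constants.  The symbols `k1, k2, a,
b` are conventions of this package: `k1`, `k2` are the intrinsic (net
birth) rates of the two compartments, `a` converts CSCs to differentiated
cells (asymmetric division is encoded as symmetric division followed by
conversion), and `b` converts differentiated cells back to the stem state
(e.g. EMT).  Conversion is taken proportional to the population (`a·S`,
`b·D`), not to the proliferative flux (`a·k1·S`): this keeps all four
parameters directly comparable per-day rates, which is how their fitted
magnitudes are interpreted against each other.  The flux-proportional
alternative would rescale `a` and `b` by the growth rates and is not
implemented.

Assumptions: exponential (density-independent) growth, constant rates over
the 160-day culture, instantaneous well-mixed conversion, and no death
terms separate from the net rates.  Density-dependent or stochastic
birth–death formulations are out of scope.

## Closed form, ratio dynamics, limiting ratio

The system matrix `[[k1−a, b], [a, k2−b]]` has discriminant
`((k1−a)−(k2−b))² + 4ab ≥ 0`, so the eigenvalues `λ1 ≥ λ2` are always real
and `S(t)`, `D(t)` are sums of two real exponentials determined by `(S0,
D0)`.  The ratio `r = D/S` obeys the Riccati equation

    dr/dt = a + (k2 − b − k1 + a)·r − b·r²,

whose non-negative fixed point is the limiting ratio.  Two routes to it are
implemented and cross-checked: the dominant-eigenvalue expression
`(λ1 − (k1 − a))/b` and the positive root of the steady-state quadratic
`b·r² − (k2 − b − k1 + a)·r − a = 0`; they agree to 1e−10 relative
tolerance on random draws (property-tested).

Edge cases.  With `b = 0` the system is triangular: if `a > 0` and the CSC
eigenvalue dominates (`k1 − a > k2`) the ratio converges to the finite
value `a/(k1 − a − k2)`; otherwise it diverges and `+inf` is returned.
With `a = b = 0` the limit is 0 or `+inf` by the sign of `k2 − k1` (NaN at
exact equality, where `r(t) ≡ r0`).  With `a = 0` and `r0 = 0` the
trajectory is identically zero whatever the limiting ratio; callers who
seed a pure CSC culture with no forward conversion get that constant
trajectory, as they should.

Identifiability.  Adding a constant to both `k1` and `k2` multiplies `S`
and `D` by the same exponential factor, so `r(t)` depends on the rates only
through `(a, b, δ = k2 − k1)`.  Ratio-only data therefore cannot separate
the growth rates; the marginal posteriors of `k1` and `k2` track their
priors while `δ` is data-driven, and every summary reports `(a, b, δ)`
alongside the raw parameters.

## Numerical choices

- Ratio evaluation factors out `exp(λ1 t)` and forms only the decaying
  `exp(−(λ1−λ2) t)`; naive evaluation overflows for `λ·t` beyond ~700
  (hundreds of culture days at ~0.2/day are fine, but the fitted curve is
  routinely evaluated far beyond that and the guard costs nothing).
- The eigenvalue shifts `λ1 − (k1−a)` and `λ1 − (k2−b)` are computed with
  rationalized, cancellation-free formulas (`ab/(s ∓ h)` where `s` is the
  half-gap and `h` the half-difference of the diagonal).  Naive subtraction
  loses all precision when `ab` is tiny, which corrupts the closed-form
  coefficients badly enough to make `D(t)` go negative in near-triangular
  systems.  For exactly triangular systems (`ab = 0`) the diagonal entries
  are used as exact eigenvalues.
- A repeated eigenvalue (only possible with `ab = 0` and `k1 − a = k2 − b`)
  switches to the confluent solution `(c + u·t)·exp(λt)`; the relative-gap
  threshold is 1e−12.
- Percentages are on the 0–100 scale throughout, matching how cytometry
  results are printed; times are days.

## Data

The packaged time course is the 12-observation MCF-7 mammosphere series
(day 0 = 96.2% CSCs after sorting, r = 0.0395, through day 160 at 1.5%,
r = 65.6667).  The ratio column stores the values at their printed 4-decimal
precision rather than recomputing them, so printed rounding is preserved;
the loader checks percent/ratio consistency.  Input CSVs carry
`time_days,csc_percent[,ratio]`; either of the two measurement columns may
be omitted and is derived from the other.

## Inference

Likelihood: independent Gaussian errors on the observed ratio with one
unknown scale σ sampled jointly with the rates — the natural probabilistic
counterpart of the SSD objective used by the sensitivity analysis.  Because
observed ratios span three orders of magnitude, a Gaussian-on-log-ratio
("lognormal") option is provided; the default fit of the packaged data uses
the plain Gaussian form.

Priors: independent uniforms, `k1, k2 ~ U(0, 1)`/day, `a, b ~ U(0, 0.5)`
/day, `σ ~ U(0, 20)` (ratio units) — weakly informative boxes that encode
non-negativity and little else; all bounds are configurable.  `r0` is fixed
to the first observed ratio by default (the day-0 point is a measured
sorting purity); a config switch samples it instead with a `U(0, 1)` prior.

Sampler: adaptive Metropolis.  The first 10% of iterations use a fixed
diagonal Gaussian proposal (2% of each prior range); thereafter the
proposal covariance is refreshed every 25 iterations as
`2.38²/d · cov(second half of history) + jitter`.  Using only the recent
half of the history keeps the early transient from inflating the proposal.
The default schedule is 10,000 iterations with 3,000 burn-in.  Runs are
bit-for-bit reproducible given the seed, and a run that accepts nothing
raises a diagnostic error.

Initialization.  The posterior mode occupies a tiny corner of the prior box
(conversion rates near 1e−3–1e−2), and chains started at the prior midpoint
routinely fail to find it within the 10,000-iteration schedule.  The
sampler therefore starts from a deterministic-given-seed coarse scan in the
identifiable coordinates (log a, log b, δ) followed by a Nelder–Mead polish
of the SSD (top five scan candidates, guarding against local minima), with
σ started at the residual scale `sqrt(SSD/n)` of the polished point.  This
is initialization only; it does not alter the target distribution.

Summaries.  Point estimates are posterior medians with equal-tailed 95%
credible intervals.  Derived quantities — `δ`, the limiting ratio, the
asymptotic CSC percentage `100/(1 + r_inf)` — are computed per posterior
sample and then summarized, never from summarized parameters.  The "best
fit" curve is the trajectory at the posterior-median parameters.

## Sensitivity analysis

Design function: the SSD between observed and model ratios at the fitted
point estimate.  Each parameter is perturbed by ±1, 2, 3, 4, 5%, giving ten
local sensitivity coefficients per parameter.  The standardization is the
absolute finite-difference change per unit relative perturbation,

    LSC_i(ε) = |F(θ with θ_i(1+ε)) − F(θ)| / |ε|,

i.e. the absolute semi-elasticity `|∂F/∂θ_i|·θ_i` to first order.  Dividing
by the relative change (the parameter's change range) makes coefficients
dimensionless in the parameter and hence comparable across rates of very
different magnitude; a raw-derivative variant is available.  Magnitudes are
stored as absolute values, and means and SDs use the sample (n−1)
convention.  Note that because the SSD depends on `k1, k2` only through
`δ`, their unscaled derivatives agree in magnitude and their standardized
LSCs differ exactly by the factor `k1/k2` (asserted in tests); LSC
magnitudes also scale with the fitted point itself, so only the ordering of
the groups — growth rates above conversion rates — is a robust conclusion,
not the absolute values.

Group comparison: one-way ANOVA across the four ten-value groups (delegated
to `scipy.stats.f_oneway`, with the all-constant degenerate cases defined
explicitly), followed by Tamhane's T2 for unequal-variance multiple
comparisons, implemented as all-pairs Welch t statistics on
Welch–Satterthwaite degrees of freedom with Šidák adjustment over the
number of pairs.

## Synthetic data

`SimDesign` defaults reproduce the study design: 12 observations at the
experimental schedule over 160 days, `r0 = 0.0395`, rates
`(k1, k2, a, b) = (0.2, 0.22, 0.01, 0.001)` — growth near the
mammosphere-culture scale with δ = 0.02/day and conversion rates 20× and
200× smaller — and 5% multiplicative lognormal noise on the ratio.
Lognormal is the default because measured ratios span three decades and
cytometry proportion error is approximately relative; an additive-Gaussian
mode (clipped at zero) matches the Gaussian likelihood exactly.  The
generator emulates observation noise only: it does not simulate gating,
sorting impurity, finite cell counts, or passage-to-passage batch effects,
so passing recovery tests demonstrate statistical calibration of the
pipeline under its own noise model, not robustness to those artefacts.

The recovery harness (analysis script 03 and the corresponding test) fits
with the matched lognormal likelihood and an estimated `r0`, since a
calibration check is only meaningful under a well-specified model; 20
replicates at the default design give ~95% empirical coverage of the true
`(a, b, δ)` by the 95% credible intervals.  At this sample size (n = 12)
credible-interval coverage is close to, but not exactly, the nominal
frequentist rate.

## Problem sizes

Closed-form-versus-integrator agreement is checked on 1,000 random
parameter draws (rates bounded so that `λ1·t` stays well inside double
range over the 300-day horizon); the fit uses the full 10,000-iteration
schedule; recovery uses 20 replicate fits.  A full fit takes well under a
second on a single core.

## Limitations

- Ratio-only data leave `k1` and `k2` individually undetermined; any
  reading of their raw posteriors reflects the prior box.
- Constant-rate, density-independent kinetics cannot capture late-passage
  changes in proliferative behaviour; the limiting ratio is a property of
  the fitted linear model, not a guaranteed biological plateau.
- The Gaussian-on-ratio likelihood weights the large late-time ratios most
  heavily; the log-ratio option rebalances this but changes the implied
  error model.
- LSC magnitudes depend on the (partly prior-driven) fitted point; only
  the growth-versus-conversion ordering is reported as a conclusion.
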