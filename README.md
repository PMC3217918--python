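# cscdrift

Kinetic analysis of cancer-stem-cell (CSC) ratio drift in long-term sphere
culture: a two-compartment linear growth/interconversion model with a
closed-form ratio solution, Bayesian fitting of the rate constants by
adaptive Metropolis–Hastings, and a local sensitivity analysis of the fit.

## The problem

Sorted CD44⁺CD24⁻/low breast-cancer stem cells can be expanded as
mammospheres in serum-free suspension culture, but over months of serial
passaging the CSC fraction drifts downward: a culture seeded at 96.2%
purity falls to ~1.5% CSCs by day 160.  This package models that drift with
two interconverting compartments — CSCs `S(t)` and differentiated cancer
cells `D(t)` — each growing exponentially and converting into the other by
mass action:

    dS/dt = k1·S − a·S + b·D
    dD/dt = k2·D + a·S − b·D

with per-day rates `k1`, `k2` (intrinsic growth of the two compartments),
`a` (CSC → differentiated conversion; asymmetric division modelled as a
symmetric division followed by conversion) and `b` (differentiated → CSC
conversion, e.g. via EMT).  The observable is the ratio `r(t) = D(t)/S(t)`
(the CSC percentage is `100/(1 + r)`), which obeys the Riccati equation

    dr/dt = a + (k2 − b − k1 + a)·r − b·r²

and converges to the limiting ratio `r_inf` — the positive root of
`b·r² − (k2 − b − k1 + a)·r − a = 0`, equivalently
`(λ1 − (k1 − a))/b` with `λ1` the dominant eigenvalue of the system.
Because `r(t)` depends on the growth rates only through `δ = k2 − k1`,
ratio-only data identify `(a, b, δ)` but not `k1` and `k2` separately; all
summaries report the identifiable combination alongside the raw rates.

## Worked example

The packaged 12-point MCF-7 mammosphere time course ships with the package
and drives the three analysis scripts:

```sh
python analysis/01_fit_mammosphere_timecourse.py
python analysis/02_sensitivity_analysis.py
python analysis/03_parameter_recovery.py
```

The fit (10,000 MCMC iterations, 3,000 burn-in, seed 1) prints

```
identifiable parameters (posterior median [95% CI]):
  a     = 0.00181 [0.00011, 0.01266] /day
  b     = 0.00082 [0.00049, 0.00099] /day
  k2 - k1 = 0.05854 [0.03320, 0.06609] /day
limiting ratio r_inf = 73.2 [64.1, 93.1]
asymptotic CSC percentage = 1.35% [1.06, 1.54]
```

i.e. differentiated cells outgrow CSCs slightly (`δ ≈ 0.06`/day), both
conversion rates are small, and the culture is predicted to settle at about
73 differentiated cells per CSC — an asymptotic CSC fraction of ~1.35%, in
line with the observed plateau near 1.5%.  The sensitivity script then
shows that the SSD design function responds orders of magnitude more
strongly to 1–5% perturbations of the growth rates than of the conversion
rates (one-way ANOVA p ≈ 3e−7, Tamhane T2 pairwise tests), so the long-term
CSC fraction is controlled chiefly by the growth-rate difference.  The
recovery script checks calibration: across 20 simulated experiments with
the same design, the 95% credible intervals cover the true `(a, b, δ)` 95%
of the time.

The same stages are scriptable through the `cscdrift` console command
(`fit`, `predict`, `sensitivity`, `simulate`), e.g.

```sh
cscdrift fit --data table1.csv --iterations 10000 --burn-in 3000 --seed 1
```

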