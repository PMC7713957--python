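# lvfit

Fit Lotka-Volterra interaction models to abundance time series of one to a
few interacting species — the classic workflow behind logistic growth curves,
competition experiments and predator-prey cycles in microcosm and field data.
It is aimed at ecologists and students who want interpretable growth rates,
interaction coefficients and carrying capacities from raw counts, without
hand-coding ODE fitting.

## Model and method

The community model is the generalized Lotka-Volterra system

    dN_i/dt = N_i ( r_i + Σ_j a_ij N_j )

with intrinsic growth rates `r_i`, interaction coefficients `a_ij` (effect of
species *j* on species *i*; the diagonal `a_ii` is self-limitation) and
carrying capacity `K_i = -r_i/a_ii` for a species alone.  Fitting proceeds in
four steps:

1. consecutive observations in each (species, treatment) group become lagged
   pairs;
2. per-capita growth over each interval is the log ratio
   `ln(N_t2/N_t1)/(t2-t1)`;
3. dividing the model by `N_i` makes it linear, so ordinary least squares of
   growth rates on interval-start abundances gives starting values
   (intercept → `r_i`, slopes → `a_ij`) and each parameter's a priori sign;
4. a Nelder-Mead search then tunes the log-magnitudes of the sign-constrained
   parameters (including initial abundances) so that the fully simulated
   dynamics — integrated on log abundances for positivity — match the
   observations, compared after dividing each species by its mean observed
   abundance.

The result carries curvature-based approximate standard errors and an
R²-like goodness-of-fit index (1 = perfect, ≤ 0 = no better than the mean),
reported per species and pooled across standardized species.  See
`docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Generate a noisy logistic monoculture (true parameters `r = 0.96`,
`a = -0.005`, `N0 = 0.22`, i.e. `K = 192`, with 10% lognormal observation
noise) and refit it:

```python
from lvfit import preset, generate, fit_lv

spec = preset("logistic_monoculture", noise_sd=0.1, seed=1)
table, truth = generate(spec)
res = fit_lv(table)
print(f"r    = {res.params.r[0]:.3f} (+/- {res.r_se[0]:.3f})")
print(f"a_ii = {res.params.A[0,0]:.5f} (+/- {res.A_se[0,0]:.5f})")
print(f"N0   = {res.params.N0[0]:.3f} (+/- {res.N0_se[0]:.3f})")
print(f"K    = {res.carrying_capacities()[0]:.1f}")
print(f"total GOF = {res.gof.total:.3f}")
```

prints

```
r    = 1.052 (+/- 0.159)
a_ii = -0.00555 (+/- 0.00086)
N0   = 0.129 (+/- 0.090)
K    = 189.5
total GOF = 0.975
```

— the growth rate and self-limitation land within one standard error of the
truth, the carrying capacity within ~1.5%, and the fit explains ~97% of the
standardized variance.  At `noise_sd=0` every parameter is recovered to
numerical precision (GOF = 1).

The same pipeline is available from the shell:

```sh
lvfit generate --preset paramecium_competition --seed 2 --out obs.csv
lvfit fit --input obs.csv --treatment mixture --out fit.json --trajectory-out traj.csv
lvfit gof --observed obs.csv --trajectory traj.csv --out gof.json
```

Constraint files (YAML/JSON) pin parameters to zero or force signs, e.g.
`a:moose:moose: zero` or `a:prey:predator: {sign: -1}`.

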