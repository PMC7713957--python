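# Methods

## Model

The package fits the generalized Lotka-Volterra model for n interacting
species,

    dN_i/dt = N_i ( r_i + sum_j a_ij N_j ),

where `r_i` (1/time) is the intrinsic growth rate of species i, `a_ij`
(1/(abundance·time)) the per-capita effect of species j on species i, and the
diagonal `a_ii` self-limitation.  The interaction matrix follows the
column-acts-on-row convention.  For a single self-limited species the model is
logistic growth with carrying capacity `K = -r/a_ii`, for which the closed
form `N(t) = K / (1 + (K/N0 - 1) e^{-rt})` is used wherever possible.

The model is deterministic and assumes constant, density-independent
interaction coefficients, a closed community (no immigration or harvesting)
and purely multiplicative observation error.  Process noise, time-varying or
higher-order interactions, and spatial structure are out of scope; systems
driven by them (e.g. sustained oscillations whose amplitude and period vary)
cannot be matched by any parameterization of this model — the
neutral-versus-damped oscillation tests demonstrate exactly that boundary.

## Fitting procedure

Fitting proceeds in four stages, automated in `fit_lv`:

1. **Lagged pairs.** Within each (species, treatment) group sorted by time,
   consecutive observations form interval records.  Sampling may be
   irregular; the actual elapsed time `t2 - t1` is carried.  Pairs never span
   treatments.
2. **Per-capita growth.** Each interval's growth rate is
   `ln(N_t2/N_t1)/(t2 - t1)`.  Records with zero or missing endpoint
   abundance are flagged invalid and excluded downstream (no pseudo-counts or
   imputation; the dropped count is logged).
3. **Linearized OLS.** Dividing the model by `N_i` makes per-capita growth
   linear in abundances, so each species' growth rates are regressed
   (independently per species, via statsmodels OLS) on the interval-*start*
   abundances of all species whose coefficient is free: the intercept
   estimates `r_i`, the slopes estimate `a_ij`.  Interval-start covariates
   avoid using future information.  When a table mixes monoculture and
   mixture treatments, the regressions pool them by default, treating species
   absent from a treatment as abundance 0.  These estimates carry
   discretization bias for coarsely sampled or fast dynamics and serve as
   starting values and a priori sign assignments only; their OLS standard
   errors are reported as starting-value diagnostics.
4. **Simulation-based refinement.** A Nelder-Mead simplex (deterministic, no
   restarts; max 5000 iterations, `xatol = fatol = 1e-8`) minimizes the sum
   of squared differences between observed and simulated abundances, both
   divided by each species' mean observed abundance (computed once from the
   observations) so that abundant species do not dominate.  Dynamics are
   integrated on log abundances by default (RK45, `rtol 1e-8`, `atol 1e-10`),
   which keeps trajectories positive near zero.  Initial abundances are
   always fitted (started at the first observations).  Each free parameter is
   optimized as the log of its magnitude with its sign fixed a priori from
   stage 3 (user constraints override); this prevents sign flips that can
   send the dynamics into run-away growth mid-search, at the price of ruling
   out significance tests on signs.

### Numerical choices

- **Integration divergence guard:** the integration aborts once any
  `|ln N_i| > ln 1e15`; the objective then returns the finite penalty `1e10`
  so the simplex can contract away rather than stall on infinities.  The
  guard is symmetric: abundances collapsing below ~1e-15 of their unit also
  abort, since the log-state is then numerically meaningless.
- **Zero-valued sign decisions:** an exactly zero OLS estimate still needs a
  sign for the log transform; diagonals default to negative (self-limitation,
  the stabilizing choice), intercepts and off-diagonals to positive.
- **Zero-valued starting magnitudes** are replaced by 1e-6 (log of zero is
  undefined); the optimizer is free to move them.
- **Never-worse guarantee:** if the simplex somehow ends above its starting
  value, the start is returned, so the refined objective is never worse than
  the linearized start.
- **Ties and degenerate inputs:** duplicate (time, species, treatment) keys
  are a validation error; rank-deficient regression designs and groups with
  fewer valid records than free coefficients raise estimation errors naming
  the species.

### Standard errors

Reported standard errors are Gaussian curvature approximations.  The
objective's Hessian `H` at the optimum is computed by central differences
(step 1e-4 in log-parameter space; implemented in-package in `_numdiff`),
converted to a covariance via the least-squares approximation
`cov = 2 sigma^2 H^{-1}` with `sigma^2 = SSQ/(m - k)` (m = all species-time
residuals jointly, k = free parameters).  The log-space standard deviation
`s_j` of each parameter maps to the natural scale as the distance from the
estimate to its lower one-sigma point, `|p|(1 - e^{-s_j})`.  Non-positive
curvature or `m <= k` yields NaN with a warning.  These are rough
approximations: the objective is not a likelihood, residuals are correlated
in time, and the sign constraint truncates the parameter space.  The formula
lives behind the single function `approx_se` so alternatives can be swapped.

### Goodness of fit

`1 - SS_res/SS_tot` with `SS_tot` about the observed mean: 1 is a perfect
fit, 0 no better than the mean, unbounded below.  The univariate index uses
raw abundances per species; the total index pools all species after dividing
by per-species observed means (matching the objective's standardization;
raw pooling is available via a flag).  The two can disagree: the pooled total
is dominated by the species with the largest standardized variance.

## Synthetic data

The generator simulates ground-truth dynamics (log-space integration),
optionally per treatment (monocultures reuse the mixture's `r` and `a_ii`),
and multiplies each observation by `e^eps`, `eps ~ Normal(0, sd^2)` i.i.d. —
lognormal multiplicative noise, the natural error model for strictly positive
abundances analyzed through log ratios.  Default noise sd is 0.1 (≈10%
observation error, typical of digitized counts).  It does not emulate process
noise, demographic stochasticity, replicate-level variation, immigration
pulses, or digitization artifacts of real historical data — so passing
recovery tests shows correctness of the estimation machinery under the
model's own assumptions, not robustness to model misspecification.

Preset scenarios, sampled at unit intervals:

- `logistic_monoculture`: one species, `r = 0.96`, `a = -0.005`,
  `N0 = 0.22`, 25 daily samples — the classically reported *P. caudatum*
  monoculture parameters.
- `paramecium_competition`: two self-limited competitors with a stable
  coexistence point (r = 1.1/0.9; all interactions negative), grown as two
  monocultures plus a mixture over the same 24-day protocol.
- `predator_prey_damped` / `predator_prey_neutral`: classic cycles
  (`r = (1, -0.5)`, `a_12 = -0.1`, `a_21 = 0.05`) with diagonals −0.02
  (damped) or 0 (neutrally stable; the zero diagonals are part of the
  scenario's constraint mask).
- `three_trophic_chain`: plant-herbivore-predator (fir-moose-wolf) with the
  non-adjacent interaction and the herbivore's self-limitation fixed to zero
  and top-down control of the herbivore; rates are deliberately slow relative
  to the unit sampling step (as in yearly counts of long-lived species, 81
  samples) so interval growth rates approximate instantaneous ones — with
  fast dynamics the linearized stage can even mis-sign parameters, which the
  sign-constrained optimizer cannot undo.

All presets at zero noise close the loop: the full pipeline recovers every
free parameter within 5% (typically far better) with total GOF > 0.999.

## Open design decisions taken

- Residual degrees of freedom in the SE approximation count all species-time
  observations jointly (not per species).
- Standardization scales use observed values only, never predictions, keeping
  the objective a fixed function of the parameters.
- The simulation stage fits a single treatment trajectory; monoculture
  treatments inform only the linearized stage (pooled regressions).
- The total GOF standardizes before pooling by default; raw pooling is a
  flag.
- Immigration/replenishment events in historical predator-prey cultures are
  not modeled; affected intervals are treated like any other.
- A species absent (zero) at the first time point cannot be fitted in log
  space; strictly positive initial abundances are required.

## Limitations

- Sign constraints mean a parameter whose true sign differs from the
  linearized estimate's sign cannot be recovered (only driven toward zero
  magnitude).
- Only observation error is addressed; no process noise, no state-space
  updating, no bootstrap or Bayesian uncertainty.
- The optimizer is local; with poor starting values (coarse sampling, fast
  dynamics, strong noise) it can converge to local optima.  No multi-start
  is performed by default.
- Standard errors are rough approximations (see above) and must not be used
  for significance testing.
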