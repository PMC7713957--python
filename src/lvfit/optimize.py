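"""Simulation-based parameter tuning with sign-constrained log parameters.

Linearized regression gives cheap starting values, but trajectories of the
Lotka-Volterra equations are very sensitive to the parameters, so the final
estimates come from matching fully simulated dynamics to the observations.
Three devices keep that optimization well behaved:

* **Standardized objective.**  Observed and predicted abundances are divided
  by each species' mean observed abundance before computing the sum of
  squares, so no species dominates the fit merely by being abundant.
* **Log-space simulation.**  Dynamics are integrated on ln N by default and
  back-transformed, which keeps trajectories positive near zero.
* **Sign-constrained log parameters.**  Each free parameter is optimized as
  the log of its magnitude, with its sign fixed a priori (from the linear
  regressions, optionally overridden by the user).  This prevents sign flips
  mid-search — e.g. an interaction turning mutualistic and blowing up the
  dynamics — at the cost of ruling out significance tests on the signs.

The search itself is a Nelder-Mead simplex (derivative free, deterministic).
Standard errors are Gaussian curvature approximations from a numerically
differentiated Hessian of the objective in log-parameter space and should be
read as rough uncertainty indications only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._numdiff import hessian
from .dynamics import Trajectory, simulate
from .errors import SimulationError, ValidationError
from .gof import GOFReport, gof_report
from .linear import LinearFitReport, determine_signs, fit_linear
from .params import ConstraintMask, LVParameters
from .timeseries import ObservationTable, lagged_observations

__all__ = ["FitResult", "pack", "unpack", "LVObjective", "optimize_lv",
           "approx_se", "fit_lv", "SIMULATION_FAILURE_PENALTY"]

logger = logging.getLogger(__name__)

#: Objective value returned when the simulation fails: large but finite, so
#: the simplex can contract away from the infeasible region instead of
#: stalling on infinities.
SIMULATION_FAILURE_PENALTY = 1e10

#: Magnitude substituted for an exactly-zero starting estimate of a free
#: parameter (log of zero is undefined).
_ZERO_START_MAGNITUDE = 1e-6


def pack(params: LVParameters, mask: ConstraintMask) -> np.ndarray:
    """Map parameters to the optimization vector of log magnitudes.

    Order: free ``r`` entries (species order), free ``A`` entries (row-major),
    then all ``N0``.  Signs must match the mask; :func:`unpack` inverts the
    mapping exactly.
    """
    mask.check_params(params)
    parts = [np.log(np.abs(params.r[mask.r_free])),
             np.log(np.abs(params.A[mask.A_free])),
             np.log(params.N0)]
    return np.concatenate(parts)


def unpack(theta: np.ndarray, mask: ConstraintMask) -> LVParameters:
    """Inverse of :func:`pack`: rebuild parameters, reinstating zeros."""
    theta = np.asarray(theta, dtype=float)
    n = mask.n_species
    n_r = int(mask.r_free.sum())
    n_a = int(mask.A_free.sum())
    if theta.size != n_r + n_a + n:
        raise ValidationError(f"packed vector has length {theta.size}, "
                              f"expected {n_r + n_a + n}")
    r = np.zeros(n)
    r[mask.r_free] = mask.r_sign[mask.r_free] * np.exp(theta[:n_r])
    A = np.zeros((n, n))
    A[mask.A_free] = mask.A_sign[mask.A_free] * np.exp(theta[n_r:n_r + n_a])
    N0 = np.exp(theta[n_r + n_a:])
    return LVParameters(list(mask.species), r, A, N0)


class LVObjective:
    """Sum of squared standardized residuals as a function of packed
    parameters.

    Built once from an observation table (single trajectory, i.e. single
    treatment): observation times, the observed abundance matrix and the
    per-species standardization scales (mean observed abundance) are frozen at
    construction, so the objective is a fixed deterministic function of theta.
    A failed or divergent simulation yields the finite penalty
    :data:`SIMULATION_FAILURE_PENALTY`.
    """

    def __init__(self, observed: ObservationTable, mask: ConstraintMask,
                 space: str = "log", rtol: float = 1e-8, atol: float = 1e-10,
                 scales: np.ndarray | None = None):
        if len(observed.treatments) > 1:
            raise ValidationError(
                "objective needs a single-treatment table (one trajectory); "
                "select a treatment first")
        self.mask = mask
        self.space = space
        self.rtol, self.atol = rtol, atol
        species = mask.species
        df = observed.data
        self.times = np.unique(df["time"].to_numpy(dtype=float))
        obs = np.full((self.times.size, len(species)), np.nan)
        t_index = {t: k for k, t in enumerate(self.times)}
        for _, row in df.iterrows():
            if row["species"] not in species:
                raise ValidationError(
                    f"observed species {row['species']!r} not in mask")
            obs[t_index[float(row["time"])],
                species.index(row["species"])] = row["abundance"]
        self.observed = obs
        if scales is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                scales = np.nanmean(obs, axis=0)
        scales = np.asarray(scales, dtype=float)
        if np.any(~np.isfinite(scales)) or np.any(scales <= 0):
            raise ValidationError("standardization scales must be positive "
                                  "(every species needs observations)")
        self.scales = scales
        self._std_obs = obs / scales
        self._obs_finite = np.isfinite(self._std_obs)
        #: number of residuals entering the sum of squares
        self.n_residuals = int(self._obs_finite.sum())

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        params = unpack(theta, self.mask)
        traj = simulate(params, self.times, space=self.space,
                        rtol=self.rtol, atol=self.atol)
        std_pred = traj.abundances / self.scales
        return (std_pred - self._std_obs)[self._obs_finite]

    def __call__(self, theta: np.ndarray) -> float:
        try:
            res = self.residuals(theta)
        except SimulationError:
            return SIMULATION_FAILURE_PENALTY
        if not np.all(np.isfinite(res)):
            return SIMULATION_FAILURE_PENALTY
        return float(res @ res)


@dataclass
class FitResult:
    """Fitted parameters with diagnostics.

    SE arrays mirror the parameter shapes; entries are NaN for zero-fixed
    parameters and when the curvature approximation failed.
    """

    params: LVParameters
    r_se: np.ndarray
    A_se: np.ndarray
    N0_se: np.ndarray
    trajectory: Trajectory
    gof: GOFReport
    objective_value: float
    start_objective: float
    n_iterations: int
    n_evaluations: int
    converged: bool
    mask: ConstraintMask
    scales: np.ndarray
    linear_report: LinearFitReport | None = field(default=None, repr=False)

    def carrying_capacities(self) -> np.ndarray:
        """K_i = -r_i/a_ii per species (NaN where a_ii = 0)."""
        diag = np.diag(self.params.A)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(diag != 0, -self.params.r / diag, np.nan)


def approx_se(objective, theta_hat: np.ndarray, mask: ConstraintMask,
              f_min: float | None = None, step: float = 1e-4):
    """Curvature-based standard errors for the fitted parameters.

    The objective's Hessian ``H`` at the optimum is differenced numerically in
    log-parameter space; with the Gaussian least-squares approximation
    ``sigma^2 = SSQ/(m - k)`` (m residuals, k free parameters) the covariance
    is ``2 sigma^2 H^{-1}``.  The log-space standard deviation ``s_j`` of each
    parameter is mapped to the natural scale as the distance from the estimate
    to its lower one-sigma point, ``|p| - |p| e^{-s_j}``.  Failures
    (insufficient residual degrees of freedom, non-positive-definite H) leave
    NaNs with a warning — these SEs are rough approximations by construction.

    Returns ``(r_se, A_se, N0_se, log_sd)`` where ``log_sd`` is the packed
    vector of log-space standard deviations.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    k = theta_hat.size
    m = getattr(objective, "n_residuals", None)
    if f_min is None:
        f_min = objective(theta_hat)
    n = mask.n_species
    r_se = np.full(n, np.nan)
    A_se = np.full((n, n), np.nan)
    N0_se = np.full(n, np.nan)
    log_sd = np.full(k, np.nan)

    if m is None or m <= k:
        warnings.warn("cannot approximate SEs: no residual degrees of freedom")
        return r_se, A_se, N0_se, log_sd
    sigma2 = f_min / (m - k)
    H = hessian(objective, theta_hat, step=step)
    try:
        cov = 2.0 * sigma2 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("cannot approximate SEs: singular Hessian")
        return r_se, A_se, N0_se, log_sd
    var = np.diag(cov)
    bad = ~(var >= 0)
    if bad.any():
        warnings.warn("negative curvature for %d parameter(s); their SEs are "
                      "reported as NaN" % int(bad.sum()))
    log_sd = np.where(bad, np.nan, np.sqrt(np.where(bad, 0.0, var)))

    params = unpack(theta_hat, mask)
    natural = np.concatenate([np.abs(params.r[mask.r_free]),
                              np.abs(params.A[mask.A_free]),
                              params.N0])
    se_nat = natural * (1.0 - np.exp(-log_sd))
    n_r = int(mask.r_free.sum())
    n_a = int(mask.A_free.sum())
    r_se[mask.r_free] = se_nat[:n_r]
    A_se[mask.A_free] = se_nat[n_r:n_r + n_a]
    N0_se[:] = se_nat[n_r + n_a:]
    return r_se, A_se, N0_se, log_sd


def optimize_lv(start: LVParameters, observed: ObservationTable,
                mask: ConstraintMask | None = None, space: str = "log",
                maxiter: int = 5000, xatol: float = 1e-8,
                fatol: float = 1e-8, rtol: float = 1e-8, atol: float = 1e-10,
                compute_se: bool = True) -> FitResult:
    """Nelder-Mead refinement of ``start`` against simulated dynamics.

    Deterministic: identical inputs and settings give identical results (no
    random restarts).  Non-convergence within the iteration budget returns a
    result with ``converged=False`` and a warning rather than raising.
    """
    if mask is None:
        mask = ConstraintMask.free_all(start.species)
    objective = LVObjective(observed, mask, space=space, rtol=rtol, atol=atol)
    theta0 = pack(start, mask)
    f0 = objective(theta0)
    res = minimize(objective, theta0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "maxfev": 4 * maxiter,
                            "xatol": xatol, "fatol": fatol})
    if not res.success:
        warnings.warn(f"optimizer did not converge: {res.message}")
    # simplex never accepts a worse point than its start
    theta_hat = res.x if res.fun <= f0 else theta0
    f_hat = min(float(res.fun), f0)
    params = unpack(theta_hat, mask)
    traj = simulate(params, objective.times, space=space, rtol=rtol, atol=atol)
    gof = gof_report(observed, traj)
    if compute_se:
        r_se, A_se, N0_se, _ = approx_se(objective, theta_hat, mask,
                                         f_min=f_hat)
    else:
        n = mask.n_species
        r_se = np.full(n, np.nan)
        A_se = np.full((n, n), np.nan)
        N0_se = np.full(n, np.nan)
    return FitResult(params=params, r_se=r_se, A_se=A_se, N0_se=N0_se,
                     trajectory=traj, gof=gof,
                     objective_value=f_hat, start_objective=f0,
                     n_iterations=int(res.nit), n_evaluations=int(res.nfev),
                     converged=bool(res.success), mask=mask,
                     scales=objective.scales)


def fit_lv(observed: ObservationTable, user_mask: ConstraintMask | None = None,
           treatment: str | None = None, pool_linear: bool = True,
           space: str = "log", maxiter: int = 5000,
           compute_se: bool = True, **optim_kwargs) -> FitResult:
    """Full fitting pipeline from raw observations to tuned parameters.

    Four stages: (1) lagged observation pairs per species and treatment;
    (2) per-capita growth rates from log ratios; (3) per-species OLS on the
    linearized model for starting values and a priori parameter signs;
    (4) sign-constrained Nelder-Mead against fully simulated dynamics.

    The simulation stage fits one trajectory, so the table must contain a
    single treatment or ``treatment`` must select one.  With
    ``pool_linear`` (default) the starting-value regressions still pool all
    treatments — species absent from a treatment count as abundance zero —
    which uses monoculture information when fitting a mixture.
    ``user_mask`` pins parameters to zero and/or forces signs; user choices
    override the data-driven signs.
    """
    if treatment is not None:
        target = observed.select_treatment(treatment)
    elif len(observed.treatments) > 1:
        raise ValidationError(
            f"table has treatments {observed.treatments}; pass treatment= to "
            "choose the trajectory to fit")
    else:
        target = observed
    species = target.species
    if user_mask is not None and user_mask.species != species:
        raise ValidationError(
            f"user mask species {user_mask.species} != fitted {species}")

    design_mask = (user_mask.copy() if user_mask is not None
                   else ConstraintMask.free_all(species))
    lag_source = observed if pool_linear else target
    try:
        lagged = lagged_observations(lag_source)
        report = fit_linear(lagged, design_mask, species=species)
    except Exception as exc:
        raise type(exc)(f"linear starting-value stage: {exc}") from exc

    mask = determine_signs(report, base_mask=design_mask)
    mask = mask.merged_with(user_mask)

    start = report.params.copy()
    # make the start packable: respect forced signs, replace zero estimates
    start.r = _coerce_start(start.r, mask.r_free, mask.r_sign)
    start.A = _coerce_start(start.A, mask.A_free, mask.A_sign)
    start.N0 = target.first_abundances(species)
    if np.any(start.N0 <= 0):
        raise ValidationError("first observed abundance must be positive to "
                              "fit in log space")

    result = optimize_lv(start, target, mask, space=space, maxiter=maxiter,
                         compute_se=compute_se, **optim_kwargs)
    result.linear_report = report
    return result


def _coerce_start(values: np.ndarray, free: np.ndarray,
                  sign: np.ndarray) -> np.ndarray:
    out = np.where(free, values, 0.0)
    mag = np.where(np.abs(out) > 0, np.abs(out), _ZERO_START_MAGNITUDE)
    return np.where(free, sign * mag, 0.0)
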