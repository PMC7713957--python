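"""Starting-value estimation by ordinary least squares on per-capita growth.

Dividing the Lotka-Volterra equation by N_i linearizes it:

    dN_i/(N_i dt) = r_i + a_ii N_i + sum_{j != i} a_ij N_j

so for each species the interval growth rates from the lagged table can be
regressed on the interval-start abundances of all species: the intercept
estimates r_i and the slope with respect to species j estimates a_ij.  The
regressions are fitted independently per species (the model is linear per
species, with species-specific coefficients).  Coefficients fixed to zero by
the constraint mask are simply excluded from the design.

These estimates are exact for data that lie on the linearized model, but for
real trajectories they carry discretization bias (the log-ratio growth rate is
an interval average, the covariates are interval-start snapshots), so they
serve as starting values and sign assignments for the simulation-based
optimizer rather than as final parameter values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EstimationError, ValidationError
from .params import ConstraintMask, LVParameters

__all__ = ["LinearFitReport", "fit_linear", "carrying_capacity",
           "determine_signs"]

logger = logging.getLogger(__name__)


@dataclass
class LinearFitReport:
    """OLS point estimates with per-coefficient standard errors.

    ``params.N0`` holds the earliest valid interval-start abundance per
    species.  SE arrays are NaN where a coefficient was fixed to zero.
    ``resid_sd`` is the residual standard deviation of each species'
    regression; ``n_used``/``n_dropped`` count valid and discarded lagged
    records per species.
    """

    params: LVParameters
    r_se: np.ndarray
    A_se: np.ndarray
    resid_sd: np.ndarray
    n_used: np.ndarray
    n_dropped: np.ndarray


def fit_linear(lagged: pd.DataFrame, mask: ConstraintMask | None = None,
               species: list[str] | None = None,
               absent_as_zero: bool = True) -> LinearFitReport:
    """Per-species OLS of growth rate on interval-start abundances.

    ``lagged`` is the table from :func:`~lvfit.timeseries.lagged_observations`.
    Records flagged invalid are excluded (with a logged count).  Covariates of
    species entirely absent from a treatment are taken as abundance 0 when
    ``absent_as_zero`` (so monoculture and mixture treatments can be pooled in
    one regression); a covariate missing at a single time while the species
    was otherwise present in that treatment drops the record.
    """
    if species is None:
        species = (mask.species if mask is not None
                   else [c for c in lagged["species"].unique()])
    if mask is None:
        mask = ConstraintMask.free_all(species)
    elif mask.species != list(species):
        raise ValidationError("mask species mismatch")
    n = len(species)

    work = lagged.copy()
    if absent_as_zero and len(work):
        for treatment, grp in lagged.groupby("treatment"):
            present = set(grp["species"].unique())
            for sp in species:
                if sp not in present:
                    work.loc[work["treatment"] == treatment, sp] = 0.0

    r = np.zeros(n)
    A = np.zeros((n, n))
    r_se = np.full(n, np.nan)
    A_se = np.full((n, n), np.nan)
    resid_sd = np.full(n, np.nan)
    n_used = np.zeros(n, dtype=int)
    n_dropped = np.zeros(n, dtype=int)
    N0 = np.empty(n)

    for i, sp in enumerate(species):
        sub = work[work["species"] == sp]
        if sub.empty:
            raise EstimationError(f"no lagged records for species {sp!r}")
        free_cols = [species[j] for j in range(n) if mask.A_free[i, j]]
        needed = ["dNNdt"] + free_cols
        usable = sub[sub["valid"]].dropna(subset=needed)
        n_used[i] = len(usable)
        n_dropped[i] = len(sub) - len(usable)
        if n_dropped[i]:
            logger.info("fit_linear: species %r: dropped %d of %d records",
                        sp, n_dropped[i], len(sub))

        p = len(free_cols) + int(mask.r_free[i])
        if len(usable) < p + 1:
            raise EstimationError(
                f"species {sp!r}: {len(usable)} valid records for {p} free "
                "coefficients (need at least one residual degree of freedom)")
        X = usable[free_cols].to_numpy(dtype=float)
        if mask.r_free[i]:
            X = np.column_stack([np.ones(len(usable)), X])
        y = usable["dNNdt"].to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise EstimationError(f"species {sp!r}: rank-deficient design "
                                  "(collinear or constant abundances)")
        res = sm.OLS(y, X).fit()
        coef, se = res.params, res.bse
        k = 0
        if mask.r_free[i]:
            r[i], r_se[i] = coef[0], se[0]
            k = 1
        for col in free_cols:
            j = species.index(col)
            A[i, j], A_se[i, j] = coef[k], se[k]
            k += 1
        resid_sd[i] = float(np.sqrt(res.scale)) if res.df_resid > 0 else 0.0
        first = usable.loc[usable["t1"].idxmin()]
        N0[i] = first["N_t1"]

    params = LVParameters(list(species), r, A, N0)
    return LinearFitReport(params, r_se, A_se, resid_sd, n_used, n_dropped)


def carrying_capacity(r: float, a_ii: float) -> float:
    """Single-species equilibrium K = -r/a_ii of the logistic model."""
    if a_ii == 0:
        raise ValidationError(
            "a_ii = 0: no self-limitation, carrying capacity undefined")
    return -r / a_ii


def determine_signs(report: LinearFitReport,
                    base_mask: ConstraintMask | None = None) -> ConstraintMask:
    """A priori parameter signs for the log-parameter optimizer.

    Each free parameter gets the sign of its OLS point estimate.  An exactly
    zero estimate needs a convention: diagonal interaction terms default to
    negative (self-limitation, which keeps dynamics bounded), intercepts and
    off-diagonal terms to positive.  Zero-status entries of ``base_mask`` are
    preserved.
    """
    species = report.params.species
    mask = (base_mask.copy() if base_mask is not None
            else ConstraintMask.free_all(species))
    if mask.species != species:
        raise ValidationError("mask species mismatch")
    r_hat, A_hat = report.params.r, report.params.A
    mask.r_sign = np.where(r_hat < 0, -1, 1)
    a_sign = np.sign(A_hat).astype(int)
    zero = a_sign == 0
    default = np.ones_like(a_sign)
    np.fill_diagonal(default, -1)
    mask.A_sign = np.where(zero, default, a_sign)
    return mask
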