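"""Simulation of Lotka-Volterra dynamics and closed-form logistic growth.

The community ODE is integrated either on the natural abundance scale or on
log-transformed abundances x_i = ln N_i, where the right-hand side becomes
the per-capita growth rate r_i + sum_j a_ij e^{x_j}.  The log-space form is
the default for fitting: it keeps trajectories strictly positive even when
abundances pass close to zero, where naive integration can produce negative
values.  A divergence guard aborts the integration once any |x_i| exceeds
ln(1e15), which catches run-away growth (e.g. unconstrained mutualism) before
it overflows and lets the optimizer treat the parameter set as infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import SimulationError, ValidationError
from .params import LVParameters

__all__ = ["Trajectory", "logistic_solution", "lv_rhs", "lv_rhs_log",
           "simulate", "LOG_ABUNDANCE_CEILING"]

#: |ln N| beyond which the integration is declared divergent (N ~ 1e15).
LOG_ABUNDANCE_CEILING = float(np.log(1e15))


@dataclass
class Trajectory:
    """Simulated abundances: ``abundances[k, i]`` is species ``i`` at
    ``times[k]``."""

    species: list[str]
    times: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (self.times.size, len(self.species)):
            raise ValidationError("trajectory shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        """Wide table with a ``time`` column and one column per species."""
        out = pd.DataFrame(self.abundances, columns=self.species)
        out.insert(0, "time", self.times)
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        species = [c for c in df.columns if c != "time"]
        return cls(species, df["time"].to_numpy(dtype=float),
                   df[species].to_numpy(dtype=float))


def logistic_solution(N0: float, r: float, K: float, times, t0: float | None = None):
    """Closed-form logistic growth N(t) = K N0 e^{rt} / (K + N0 (e^{rt}-1)).

    ``times`` are absolute; growth is measured from ``t0`` (default: the
    first requested time).  This is the one-species Lotka-Volterra solution
    with self-limitation a = -r/K.
    """
    if N0 <= 0:
        raise ValidationError("N0 must be > 0")
    if K <= 0:
        raise ValidationError("K must be > 0")
    times = np.asarray(times, dtype=float)
    t = times - (times.flat[0] if t0 is None else t0)
    # algebraically identical form that avoids overflow of e^{rt}
    return K / (1.0 + (K / N0 - 1.0) * np.exp(-r * t))


def lv_rhs(N, params: LVParameters):
    """dN_i/dt = N_i (r_i + sum_j a_ij N_j) on the natural abundance scale."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        _warn_negative_once()
    return N * (params.r + params.A @ N)


_warned_negative = False


def _warn_negative_once() -> None:
    # negative abundances are mathematically admissible but usually signal an
    # integration excursion below zero; warn once per process
    global _warned_negative
    if not _warned_negative:
        _warned_negative = True
        import logging
        logging.getLogger(__name__).warning(
            "lv_rhs evaluated at negative abundance")


def lv_rhs_log(x, params: LVParameters):
    """dx_i/dt = r_i + sum_j a_ij e^{x_j} for log abundances x = ln N.

    Identical dynamics to :func:`lv_rhs` for positive states, but the state
    stays finite-positive by construction.  Raises :class:`SimulationError`
    when the state exceeds the divergence ceiling.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > LOG_ABUNDANCE_CEILING) or not np.all(np.isfinite(x)):
        raise SimulationError("log-abundance exceeded divergence ceiling")
    return params.r + params.A @ np.exp(x)


def simulate(params: LVParameters, times, space: str = "log",
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the community ODE from ``params.N0`` at ``times[0]``.

    ``space`` selects the integration variable: ``"log"`` (default) integrates
    ln N and back-transforms, guaranteeing positive abundances; ``"linear"``
    integrates N directly.  Adaptive Runge-Kutta (RK45) with dense output at
    the requested times.  Divergence or solver failure raises
    :class:`SimulationError` carrying the last time reached.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValidationError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    if space not in ("log", "linear"):
        raise ValidationError(f"unknown space {space!r}")

    if space == "log":
        if np.any(params.N0 <= 0):
            raise ValidationError("log-space simulation needs N0 > 0")
        y0 = np.log(params.N0)
        fun = lambda t, y: lv_rhs_log(y, params)
    else:
        y0 = params.N0.astype(float)

        def fun(t, y):
            if np.any(np.abs(y) > 1e15) or not np.all(np.isfinite(y)):
                raise SimulationError("abundance exceeded divergence ceiling")
            return lv_rhs(y, params)

    if times.size == 1:
        return Trajectory(params.species, times, params.N0[None, :].copy())

    try:
        sol = solve_ivp(fun, (times[0], times[-1]), y0, t_eval=times,
                        method="RK45", rtol=rtol, atol=atol)
    except SimulationError:
        raise
    except (OverflowError, FloatingPointError) as exc:  # pragma: no cover
        raise SimulationError(f"integration overflow: {exc}") from exc
    if not sol.success or sol.y.shape[1] != times.size:
        last = float(sol.t[-1]) if sol.t.size else float(times[0])
        raise SimulationError(f"integration failed: {sol.message}",
                              last_time=last)
    y = sol.y.T
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state in integration")
    abundances = np.exp(y) if space == "log" else y
    return Trajectory(params.species, times, abundances)
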