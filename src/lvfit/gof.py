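"""R-squared-like goodness of fit between observed and predicted abundances.

The index is 1 - SS_res/SS_tot with SS_tot taken about the observed mean: 1
means a perfect fit, 0 means the prediction does no better than the observed
mean, and the index is unbounded below for predictions worse than that.
The *univariate* index is computed per species on raw abundances; the *total*
index pools all species after dividing observed and predicted values by each
species' observed mean, so that species measured in different units (or at
very different abundances) contribute comparably — the same standardization
the optimization objective uses.  The two can disagree substantially: a
species fit well on its own scale can dominate or be dominated in the pooled
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory
from .errors import ValidationError
from .timeseries import ObservationTable

__all__ = ["GOFReport", "goodness_of_fit", "gof_report"]


@dataclass
class GOFReport:
    per_species: dict[str, float]
    total: float
    n_obs: dict[str, int]


def goodness_of_fit(observed, predicted) -> float:
    """1 - SS_res/SS_tot for paired observed/predicted values.

    Pairs with a missing member are dropped; at least two complete pairs and
    nonzero observed variance are required.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError("observed/predicted length mismatch")
    keep = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[keep], pred[keep]
    if obs.size < 2:
        raise ValidationError("need at least 2 complete pairs")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("zero variance in observations: index undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def gof_report(observed: ObservationTable, trajectory: Trajectory,
               standardize_total: bool = True) -> GOFReport:
    """Univariate index per species plus the pooled total index.

    Predictions are aligned to observations by (species, time); a missing
    prediction for an observed pair is an error.  ``standardize_total``
    selects whether the pooled index divides by per-species observed means
    (default) or pools raw values.
    """
    df = observed.data[observed.data["abundance"].notna()]
    time_index = {t: k for k, t in enumerate(trajectory.times)}
    per_species: dict[str, float] = {}
    n_obs: dict[str, int] = {}
    all_obs: list[np.ndarray] = []
    all_pred: list[np.ndarray] = []
    for i, sp in enumerate(trajectory.species):
        sub = df[df["species"] == sp]
        try:
            rows = [time_index[t] for t in sub["time"]]
        except KeyError as exc:
            raise ValidationError(
                f"no prediction for species {sp!r} at time {exc.args[0]}"
            ) from None
        obs = sub["abundance"].to_numpy(dtype=float)
        pred = trajectory.abundances[rows, i]
        per_species[sp] = goodness_of_fit(obs, pred)
        n_obs[sp] = obs.size
        scale = obs.mean() if standardize_total else 1.0
        all_obs.append(obs / scale)
        all_pred.append(pred / scale)
    total = goodness_of_fit(np.concatenate(all_obs), np.concatenate(all_pred))
    return GOFReport(per_species=per_species, total=total, n_obs=n_obs)
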