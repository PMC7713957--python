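"""Observed abundance time series and per-capita growth rates.

Observations are long-format records ``(time, species, abundance, treatment)``.
The linearization of the Lotka-Volterra model works on *lagged* observation
pairs: consecutive samples of one species within one treatment, from which the
per-capita growth rate over the interval is the log ratio of abundances
divided by the elapsed time,

    dN/(N dt) ~= ln(N_t2 / N_t1) / (t2 - t1).

Zero or missing abundances have no defined log ratio; such pairs are kept in
the lagged table but flagged invalid so downstream stages can report how many
records were dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["ObservationTable", "per_capita_growth", "lagged_observations",
           "LAG_FIXED_COLUMNS"]

logger = logging.getLogger(__name__)

#: Fixed (non-covariate) columns of the lagged-growth table, in output order.
LAG_FIXED_COLUMNS = ["species", "treatment", "t1", "t2", "N_t1", "N_t2",
                     "dNNdt", "valid"]


@dataclass
class ObservationTable:
    """Long-format abundance observations.

    ``data`` has columns ``time`` (float), ``species`` (str), ``abundance``
    (float, >= 0 or NaN for missing) and ``treatment`` (str; empty string
    denotes a single unnamed treatment).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = {"time", "species", "abundance"} - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        if "treatment" not in df.columns:
            df["treatment"] = ""
        df["treatment"] = df["treatment"].fillna("").astype(str)
        df["species"] = df["species"].astype(str)
        df["time"] = pd.to_numeric(df["time"])
        df["abundance"] = pd.to_numeric(df["abundance"])
        if (df["abundance"].dropna() < 0).any():
            raise ValidationError("negative abundance")
        dup = df.duplicated(subset=["time", "species", "treatment"])
        if dup.any():
            rows = df.loc[dup, ["time", "species", "treatment"]].head(3)
            raise ValidationError(
                f"duplicate (time, species, treatment) keys, e.g.\n{rows}")
        # rows keep their input order; species order (first appearance) is
        # part of the table's identity and survives treatment selection
        self._species_order = list(dict.fromkeys(df["species"]))
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "ObservationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False,
                         columns=["time", "species", "abundance", "treatment"])

    @property
    def species(self) -> list[str]:
        """Species identifiers in order of first appearance in the input."""
        return list(self._species_order)

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.data["treatment"]))

    def select_treatment(self, treatment: str) -> "ObservationTable":
        sub = self.data[self.data["treatment"] == treatment]
        if sub.empty:
            raise ValidationError(f"no records for treatment {treatment!r}")
        return ObservationTable(sub.reset_index(drop=True))

    def first_abundances(self, species: list[str] | None = None) -> np.ndarray:
        """Earliest non-missing abundance per species (used as N0 start)."""
        species = species if species is not None else self.species
        out = np.empty(len(species))
        for k, sp in enumerate(species):
            sub = self.data[(self.data["species"] == sp)
                            & self.data["abundance"].notna()]
            if sub.empty:
                raise ValidationError(f"species {sp!r} has no observations")
            out[k] = sub.loc[sub["time"].idxmin(), "abundance"]
        return out


def per_capita_growth(N_t1, N_t2, dt):
    """Per-capita growth rate over an interval, ``ln(N_t2/N_t1)/dt``.

    Accepts scalars or arrays.  Nonpositive abundances yield NaN (the pair
    carries no usable growth information); ``dt <= 0`` is a validation error.
    """
    N_t1 = np.asarray(N_t1, dtype=float)
    N_t2 = np.asarray(N_t2, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(dt <= 0):
        raise ValidationError("dt must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((N_t1 > 0) & (N_t2 > 0),
                       np.log(N_t2 / N_t1) / dt, np.nan)
    return out if out.ndim else float(out)


def lagged_observations(table: ObservationTable) -> pd.DataFrame:
    """Consecutive-observation pairs with per-capita growth rates.

    For every (species, treatment) group sorted by time, one record is emitted
    per consecutive observation pair, never spanning treatments.  The returned
    frame has :data:`LAG_FIXED_COLUMNS` plus one covariate column per species
    holding that species' abundance at the interval start ``t1`` within the
    same treatment (NaN when unobserved at that time).  Pairs with missing or
    nonpositive endpoint abundances get ``valid=False`` and NaN growth.
    """
    df = table.data
    all_species = table.species
    # abundance lookup at (treatment, time) for covariates
    wide = df.pivot(index=["treatment", "time"], columns="species",
                    values="abundance")
    rows: list[dict] = []
    for (treatment, sp), grp in df.groupby(["treatment", "species"], sort=False):
        grp = grp.sort_values("time")
        t = grp["time"].to_numpy()
        n = grp["abundance"].to_numpy()
        for k in range(len(grp) - 1):
            t1, t2 = float(t[k]), float(t[k + 1])
            n1, n2 = float(n[k]), float(n[k + 1])
            valid = bool(n1 > 0 and n2 > 0)
            rec = {
                "species": sp, "treatment": treatment,
                "t1": t1, "t2": t2, "N_t1": n1, "N_t2": n2,
                "dNNdt": per_capita_growth(n1, n2, t2 - t1) if valid else np.nan,
                "valid": valid,
            }
            cov = wide.loc[(treatment, t1)]
            for other in all_species:
                rec[other] = float(cov.get(other, np.nan))
            rows.append(rec)
    cols = LAG_FIXED_COLUMNS + all_species
    out = pd.DataFrame(rows, columns=cols)
    n_invalid = int((~out["valid"]).sum()) if len(out) else 0
    if n_invalid:
        logger.info("lagged_observations: %d of %d records flagged invalid "
                    "(zero or missing abundance)", n_invalid, len(out))
    return out
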