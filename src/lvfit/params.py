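"""Parameter containers for the Lotka-Volterra model and its constraints.

The community model is

    dN_i/dt = N_i (r_i + sum_j a_ij N_j)

with intrinsic growth rates ``r`` (1/time), interaction matrix ``A`` where
``A[i, j]`` is the per-capita effect of species ``j`` on species ``i``
(1/(abundance*time); the diagonal is self-limitation), and initial abundances
``N0``.  The row/column convention is "column acts on row".

:class:`ConstraintMask` records, for every parameter, whether it is free or
pinned to zero, and — for free parameters — the sign it is constrained to
during optimization (parameters are optimized as log magnitudes, so the sign
must be fixed a priori).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["LVParameters", "ConstraintMask"]


@dataclass
class LVParameters:
    """Point parameterization of an n-species Lotka-Volterra system."""

    species: list[str]
    r: np.ndarray
    A: np.ndarray
    N0: np.ndarray

    def __post_init__(self) -> None:
        self.species = list(self.species)
        n = len(self.species)
        if len(set(self.species)) != n:
            raise ValidationError("duplicate species identifiers")
        self.r = np.asarray(self.r, dtype=float).reshape(n)
        self.A = np.asarray(self.A, dtype=float).reshape(n, n)
        self.N0 = np.asarray(self.N0, dtype=float).reshape(n)
        for name, arr in (("r", self.r), ("A", self.A), ("N0", self.N0)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite entries in {name}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, species: str) -> int:
        try:
            return self.species.index(species)
        except ValueError:
            raise ValidationError(f"unknown species {species!r}") from None

    def copy(self) -> "LVParameters":
        return LVParameters(list(self.species), self.r.copy(), self.A.copy(),
                            self.N0.copy())

    def subset(self, species: list[str]) -> "LVParameters":
        """Sub-community restricted to ``species`` (e.g. a monoculture)."""
        idx = [self.index(s) for s in species]
        return LVParameters(
            species=list(species),
            r=self.r[idx],
            A=self.A[np.ix_(idx, idx)],
            N0=self.N0[idx],
        )

    def equilibrium(self) -> np.ndarray:
        """Interior equilibrium ``N* = -A^{-1} r`` (may have nonpositive
        entries if no feasible coexistence point exists)."""
        return -np.linalg.solve(self.A, self.r)


@dataclass
class ConstraintMask:
    """Free/zero status plus a priori signs for every model parameter.

    ``*_free`` are boolean arrays; ``*_sign`` hold +1/-1 and are meaningful
    only where the parameter is free.  Initial abundances are always free and
    always positive.
    """

    species: list[str]
    r_free: np.ndarray = field(default=None)  # type: ignore[assignment]
    A_free: np.ndarray = field(default=None)  # type: ignore[assignment]
    r_sign: np.ndarray = field(default=None)  # type: ignore[assignment]
    A_sign: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.species = list(self.species)
        n = len(self.species)
        if self.r_free is None:
            self.r_free = np.ones(n, dtype=bool)
        if self.A_free is None:
            self.A_free = np.ones((n, n), dtype=bool)
        if self.r_sign is None:
            # default a priori signs: growth positive, self-limitation negative
            self.r_sign = np.ones(n, dtype=int)
        if self.A_sign is None:
            self.A_sign = np.ones((n, n), dtype=int)
            np.fill_diagonal(self.A_sign, -1)
        self.r_free = np.asarray(self.r_free, dtype=bool).reshape(n)
        self.A_free = np.asarray(self.A_free, dtype=bool).reshape(n, n)
        self.r_sign = np.asarray(self.r_sign, dtype=int).reshape(n)
        self.A_sign = np.asarray(self.A_sign, dtype=int).reshape(n, n)
        if not np.all(np.isin(self.r_sign[self.r_free], (-1, 1))):
            raise ValidationError("every free r needs sign +1 or -1")
        if not np.all(np.isin(self.A_sign[self.A_free], (-1, 1))):
            raise ValidationError("every free A entry needs sign +1 or -1")

    @classmethod
    def free_all(cls, species: list[str]) -> "ConstraintMask":
        return cls(species=list(species))

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_free(self) -> int:
        """Number of optimized parameters (free r and A entries plus N0)."""
        return int(self.r_free.sum() + self.A_free.sum()) + self.n_species

    def copy(self) -> "ConstraintMask":
        return ConstraintMask(list(self.species), self.r_free.copy(),
                              self.A_free.copy(), self.r_sign.copy(),
                              self.A_sign.copy())

    def fix_zero(self, *, r: list[str] = (), a: list[tuple[str, str]] = ()) -> "ConstraintMask":
        """Return a copy with the named parameters pinned to zero.

        ``a`` entries are (row species, column species): the effect of the
        column species on the row species.
        """
        out = self.copy()
        idx = {s: i for i, s in enumerate(self.species)}
        for sp in r:
            out.r_free[idx[sp]] = False
        for row, col in a:
            out.A_free[idx[row], idx[col]] = False
        return out

    def merged_with(self, user: "ConstraintMask | None") -> "ConstraintMask":
        """Overlay user-supplied constraints; user zeros and signs win."""
        if user is None:
            return self.copy()
        if user.species != self.species:
            raise ValidationError("constraint mask species mismatch")
        out = self.copy()
        out.r_free &= user.r_free
        out.A_free &= user.A_free
        # a user mask created via from_config marks explicit signs; here any
        # sign differing from the default is taken as an explicit request
        explicit_r = getattr(user, "_explicit_r_sign", None)
        explicit_a = getattr(user, "_explicit_A_sign", None)
        if explicit_r is not None:
            out.r_sign[explicit_r] = user.r_sign[explicit_r]
        if explicit_a is not None:
            out.A_sign[explicit_a] = user.A_sign[explicit_a]
        return out

    def check_params(self, params: LVParameters) -> None:
        """Validate that ``params`` obeys this mask (zeros exact, signs match)."""
        if params.species != self.species:
            raise ValidationError("mask/parameter species mismatch")
        if np.any(params.r[~self.r_free] != 0.0):
            raise ValidationError("r entry fixed to zero is nonzero")
        if np.any(params.A[~self.A_free] != 0.0):
            raise ValidationError("A entry fixed to zero is nonzero")
        bad_r = self.r_free & (np.sign(params.r) != self.r_sign)
        bad_a = self.A_free & (np.sign(params.A) != self.A_sign)
        if np.any(bad_r) or np.any(bad_a):
            raise ValidationError("free parameter sign violates mask")
        if np.any(params.N0 <= 0):
            raise ValidationError("N0 must be strictly positive")
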