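"""Serialization: parameter JSON, constraint configuration, result JSON.

Constraint configuration (YAML or JSON) maps parameter names to a status:

    r:prey: free
    a:prey:predator: {sign: -1}
    a:moose:moose: zero

Keys are ``r:<species>``, ``a:<row>:<col>`` (column acts on row) and
``n0:<species>``; values are ``free``, ``zero`` or ``{sign: +1|-1}``.
Initial abundances may not be fixed to zero.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import yaml

from .errors import ValidationError
from .optimize import FitResult
from .params import ConstraintMask, LVParameters

__all__ = ["params_to_dict", "params_from_dict", "mask_from_config",
           "mask_to_config", "load_constraints", "fit_result_to_dict",
           "save_json", "tool_version"]


def tool_version() -> str:
    try:
        return version("lvfit")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _tolist(arr):
    return np.where(np.isfinite(arr), arr, None).tolist() \
        if isinstance(arr, np.ndarray) else arr


def params_to_dict(params: LVParameters, r_se=None, A_se=None,
                   N0_se=None) -> dict:
    out = {
        "species": list(params.species),
        "r": params.r.tolist(),
        "A": params.A.tolist(),
        "N0": params.N0.tolist(),
    }
    if r_se is not None:
        out["se"] = {"r": _tolist(r_se), "A": _tolist(A_se),
                     "N0": _tolist(N0_se)}
    return out


def params_from_dict(d: dict) -> LVParameters:
    try:
        return LVParameters(d["species"], d["r"], d["A"], d["N0"])
    except KeyError as exc:
        raise ValidationError(f"parameter JSON missing key {exc}") from None


def mask_from_config(config: dict, species: list[str]) -> ConstraintMask:
    """Build a constraint mask from a parsed configuration mapping.

    Signs given explicitly are marked so they override data-driven signs when
    the mask is merged in the fitting pipeline.
    """
    mask = ConstraintMask.free_all(species)
    explicit_r = np.zeros(len(species), dtype=bool)
    explicit_a = np.zeros((len(species), len(species)), dtype=bool)
    idx = {s: i for i, s in enumerate(species)}

    def lookup(name: str) -> int:
        if name not in idx:
            raise ValidationError(f"constraint names unknown species {name!r}")
        return idx[name]

    for key, value in config.items():
        parts = str(key).split(":")
        kind = parts[0].lower()
        status, sign = _parse_status(key, value)
        if kind == "r" and len(parts) == 2:
            i = lookup(parts[1])
            if status == "zero":
                mask.r_free[i] = False
            if sign is not None:
                mask.r_sign[i] = sign
                explicit_r[i] = True
        elif kind == "a" and len(parts) == 3:
            i, j = lookup(parts[1]), lookup(parts[2])
            if status == "zero":
                mask.A_free[i, j] = False
            if sign is not None:
                mask.A_sign[i, j] = sign
                explicit_a[i, j] = True
        elif kind == "n0" and len(parts) == 2:
            lookup(parts[1])
            if status == "zero":
                raise ValidationError("N0 may not be fixed to zero")
        else:
            raise ValidationError(f"bad constraint key {key!r}")
    mask._explicit_r_sign = explicit_r  # type: ignore[attr-defined]
    mask._explicit_A_sign = explicit_a  # type: ignore[attr-defined]
    return mask


def _parse_status(key, value):
    if isinstance(value, str):
        status = value.lower()
        if status not in ("free", "zero"):
            raise ValidationError(f"constraint {key!r}: status must be "
                                  f"'free', 'zero' or a sign mapping")
        return status, None
    if isinstance(value, dict) and set(value) == {"sign"}:
        sign = int(value["sign"])
        if sign not in (-1, 1):
            raise ValidationError(f"constraint {key!r}: sign must be +1 or -1")
        return "free", sign
    raise ValidationError(f"constraint {key!r}: unrecognized value {value!r}")


def mask_to_config(mask: ConstraintMask) -> dict:
    """Flat configuration mapping describing a mask (all entries explicit)."""
    out: dict[str, object] = {}
    for i, sp in enumerate(mask.species):
        out[f"r:{sp}"] = ({"sign": int(mask.r_sign[i])} if mask.r_free[i]
                          else "zero")
        for j, sq in enumerate(mask.species):
            out[f"a:{sp}:{sq}"] = ({"sign": int(mask.A_sign[i, j])}
                                   if mask.A_free[i, j] else "zero")
    return out


def load_constraints(path, species: list[str]) -> ConstraintMask:
    """Read a YAML/JSON constraint file into a mask."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if config is None:
        config = {}
    if not isinstance(config, dict):
        raise ValidationError("constraint file must be a mapping")
    return mask_from_config(config, species)


def fit_result_to_dict(result: FitResult, config: dict | None = None) -> dict:
    """Machine-readable fit summary embedding the tool version."""
    out = {
        "tool": {"name": "lvfit", "version": tool_version()},
        "parameters": params_to_dict(result.params, result.r_se,
                                     result.A_se, result.N0_se),
        "carrying_capacity": _tolist(result.carrying_capacities()),
        "mask": mask_to_config(result.mask),
        "scales": result.scales.tolist(),
        "goodness_of_fit": {
            "per_species": result.gof.per_species,
            "total": result.gof.total,
            "n_obs": result.gof.n_obs,
        },
        "optimizer": {
            "objective_value": result.objective_value,
            "start_objective": result.start_objective,
            "iterations": result.n_iterations,
            "evaluations": result.n_evaluations,
            "converged": result.converged,
        },
    }
    if config is not None:
        out["config"] = config
    return out


def save_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False)
        fh.write("\n")
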