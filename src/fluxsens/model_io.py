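"""Constraint-based model container and readers/writers.

A :class:`MetabolicModel` is the minimal FBA substrate: a sparse
stoichiometric matrix ``S`` (m metabolites x r reactions), per-reaction flux
bounds, and a linear objective ``w``. Files are read through cobrapy so both
SBML Level 3 (FBC bounds/objective) and COBRA-style JSON dialects — the forms
genome-scale reconstructions such as Recon2.2/Recon3D are distributed in —
are accepted.

Exchange (boundary) reactions are identified structurally: a column of S with
exactly one nonzero stoichiometric entry. Intake capability follows the
community sign convention that uptake flux is negative, so a boundary
reaction is intake-capable iff its lower bound is below zero. The intake
lower bounds are the factors of the sensitivity analysis; only lower bounds
are ever perturbed (secretion capacity is left untouched).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .errors import BoundOrderError, ModelFormatError, ModelValidationError

__all__ = [
    "MetabolicModel",
    "load_model",
    "save_model",
    "find_exchange_reactions",
    "apply_intake_bounds",
]


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Unique identifiers; ``reaction_ids`` order fixes the column order of
        every per-reaction vector.
    S
        Sparse m x r stoichiometric matrix (dimensionless coefficients).
    lower_bounds, upper_bounds
        Flux bounds per reaction (mM/h by convention; units are carried as
        opaque labels, no conversion is attempted).
    objective_coeffs
        Linear objective weights w; at least one must be nonzero.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective_coeffs: np.ndarray
    name: str = ""
    units: str = "mM/h"
    _index: dict[str, int] = field(init=False, repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.objective_coeffs = np.asarray(self.objective_coeffs, dtype=float)
        self._index = {rid: j for j, rid in enumerate(self.reaction_ids)}

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        return self._index[rid]

    def validate(self) -> "MetabolicModel":
        """Check all structural invariants; raise ModelValidationError on failure."""
        m, r = self.S.shape
        if m != len(self.metabolite_ids) or r != len(self.reaction_ids):
            raise ModelValidationError(
                f"S is {m}x{r} but model declares "
                f"{len(self.metabolite_ids)} metabolites and {len(self.reaction_ids)} reactions"
            )
        for vec, label in (
            (self.lower_bounds, "lower_bounds"),
            (self.upper_bounds, "upper_bounds"),
            (self.objective_coeffs, "objective_coeffs"),
        ):
            if vec.shape != (r,):
                raise ModelValidationError(f"{label} has shape {vec.shape}, expected ({r},)")
        bad = np.flatnonzero(self.lower_bounds > self.upper_bounds)
        if bad.size:
            j = int(bad[0])
            raise ModelValidationError(
                f"reaction {self.reaction_ids[j]!r}: lower bound "
                f"{self.lower_bounds[j]} exceeds upper bound {self.upper_bounds[j]}"
            )
        if not np.any(self.objective_coeffs):
            raise ModelValidationError("objective has no nonzero coefficient")
        if len(set(self.metabolite_ids)) != m:
            raise ModelValidationError("metabolite ids are not unique")
        if len(set(self.reaction_ids)) != r:
            raise ModelValidationError("reaction ids are not unique")
        return self

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            objective_coeffs=self.objective_coeffs.copy(),
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
        )

    def equals(self, other: "MetabolicModel") -> bool:
        """Structural equality: ids, stoichiometry, bounds and objective."""
        return (
            self.metabolite_ids == other.metabolite_ids
            and self.reaction_ids == other.reaction_ids
            and (self.S != other.S).nnz == 0
            and np.array_equal(self.lower_bounds, other.lower_bounds)
            and np.array_equal(self.upper_bounds, other.upper_bounds)
            and np.array_equal(self.objective_coeffs, other.objective_coeffs)
        )


def _from_cobra(cm) -> MetabolicModel:
    from cobra.util.array import create_stoichiometric_matrix

    S = sp.csc_matrix(create_stoichiometric_matrix(cm, array_type="lil"))
    lb = np.array([rx.lower_bound for rx in cm.reactions], dtype=float)
    ub = np.array([rx.upper_bound for rx in cm.reactions], dtype=float)
    w = np.array([rx.objective_coefficient for rx in cm.reactions], dtype=float)
    model = MetabolicModel(
        metabolite_ids=[met.id for met in cm.metabolites],
        reaction_ids=[rx.id for rx in cm.reactions],
        S=S,
        lower_bounds=lb,
        upper_bounds=ub,
        objective_coeffs=w,
        name=cm.id or "",
    )
    if not np.any(w):
        raise ModelValidationError(f"model {cm.id!r} declares no objective reaction")
    return model.validate()


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.name or "fluxsens_model")
    mets = [cobra.Metabolite(mid, compartment="c") for mid in model.metabolite_ids]
    cm.add_metabolites(mets)
    S = model.S.tocsc()
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rx = cobra.Reaction(rid)
        reactions.append(rx)
    cm.add_reactions(reactions)
    for j, rx in enumerate(reactions):
        col = S.getcol(j).tocoo()
        rx.add_metabolites({mets[i]: float(v) for i, v in zip(col.row, col.data)})
        rx.bounds = (float(model.lower_bounds[j]), float(model.upper_bounds[j]))
    cm.objective = {
        reactions[j]: float(model.objective_coeffs[j])
        for j in np.flatnonzero(model.objective_coeffs)
    }
    return cm


def load_model(path: str, format: str = "auto") -> MetabolicModel:
    """Load an SBML or COBRA-JSON model file into a :class:`MetabolicModel`.

    ``format`` is one of ``sbml``, ``cobra_json`` or ``auto`` (extension
    sniffing: .xml/.sbml -> SBML, .json -> COBRA JSON). Bounds and objective
    coefficients are taken verbatim from the file.
    """
    import cobra.io

    path = str(path)
    if format == "auto":
        lowered = path.lower()
        format = "sbml" if lowered.endswith((".xml", ".sbml")) else "cobra_json"
    if format not in ("sbml", "cobra_json"):
        raise ValueError(f"unknown model format {format!r}")
    try:
        if format == "sbml":
            cm = cobra.io.read_sbml_model(path)
        else:
            cm = cobra.io.load_json_model(path)
    except ValueError as exc:
        # cobrapy raises ValueError for inverted bounds inside the file;
        # anything else (e.g. JSON syntax) is a format problem
        if "bound" in str(exc).lower():
            raise ModelValidationError(f"{path}: {exc}") from exc
        raise ModelFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    except ModelValidationError:
        raise
    except Exception as exc:
        raise ModelFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return _from_cobra(cm)


def save_model(model: MetabolicModel, path: str) -> None:
    """Write a model as COBRA-style JSON (the dialect ``load_model`` reads back)."""
    import cobra.io

    cobra.io.save_json_model(_to_cobra(model.validate()), str(path))


def find_exchange_reactions(
    model: MetabolicModel,
    intake_only: bool = False,
    id_pattern: str | None = None,
) -> list[int]:
    """Indices of boundary (exchange) reactions, in reaction-id order.

    A boundary reaction is a column of S with exactly one nonzero entry.
    With ``intake_only`` the list is restricted to reactions whose lower
    bound is negative, i.e. those that can carry uptake flux under the
    negative-intake sign convention. ``id_pattern`` optionally overrides the
    structural rule with a regular expression on reaction ids (e.g. ``^EX_``).
    """
    if id_pattern is not None:
        rx = re.compile(id_pattern)
        idx = [j for j, rid in enumerate(model.reaction_ids) if rx.search(rid)]
    else:
        nnz_per_col = np.diff(model.S.tocsc().indptr)
        idx = [int(j) for j in np.flatnonzero(nnz_per_col == 1)]
    if intake_only:
        idx = [j for j in idx if model.lower_bounds[j] < 0]
    return idx


def apply_intake_bounds(
    model: MetabolicModel,
    factor_indices: list[int] | np.ndarray,
    values: np.ndarray,
) -> MetabolicModel:
    """Return a copy of ``model`` with lower bounds at ``factor_indices`` replaced.

    The input model is never mutated; only lower bounds change, upper bounds
    stay as in the source model. A value above the reaction's upper bound is
    a :class:`BoundOrderError`.
    """
    factor_indices = np.asarray(factor_indices, dtype=int)
    values = np.asarray(values, dtype=float)
    if factor_indices.shape != values.shape:
        raise ValueError(
            f"{factor_indices.size} factor indices but {values.size} values"
        )
    ub = model.upper_bounds[factor_indices]
    bad = np.flatnonzero(values > ub)
    if bad.size:
        k = int(bad[0])
        j = int(factor_indices[k])
        raise BoundOrderError(
            f"reaction {model.reaction_ids[j]!r}: requested lower bound "
            f"{values[k]} exceeds upper bound {ub[k]}"
        )
    out = model.copy()
    out.lower_bounds[factor_indices] = values
    return out
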