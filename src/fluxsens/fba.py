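"""Flux balance analysis: maximize w·v subject to S·v = 0 and v_l <= v <= v_u.

The LP is solved through an injected solver backend; the default is scipy's
HiGHS interface. Infeasible and unbounded outcomes are first-class statuses,
not exceptions — policy for them belongs to the caller (see
:mod:`fluxsens.executor`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import linprog

from .errors import EngineError
from .model_io import MetabolicModel

__all__ = ["FluxResult", "fba_optimize", "solve_highs"]

#: Solver backend contract: (c, A_eq, lb, ub) for the *maximization* of c·v
#: subject to A_eq·v = 0 and lb <= v <= ub, returning (status, objective, x)
#: with status in {"optimal", "infeasible", "unbounded"}.
SolverBackend = Callable[..., tuple]


@dataclass(frozen=True)
class FluxResult:
    """Outcome of one FBA optimization.

    ``objective_value`` and ``fluxes`` are defined only when ``status`` is
    ``"optimal"``; when optimal the flux vector satisfies |S·v| <= tol,
    v_l - tol <= v <= v_u + tol and objective_value = w·v within tol.
    """

    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float] = None
    fluxes: Optional[np.ndarray] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def solve_highs(c, A_eq, lb, ub):
    """Default backend: HiGHS via scipy.optimize.linprog (maximization)."""
    bounds = [
        (None if l == -np.inf else l, None if u == np.inf else u)
        for l, u in zip(lb, ub)
    ]
    res = linprog(-np.asarray(c, dtype=float), A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
                  bounds=bounds, method="highs")
    if res.status == 0:
        return "optimal", -float(res.fun), np.asarray(res.x, dtype=float)
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    raise EngineError(f"LP solver failed (status {res.status}): {res.message}")


def fba_optimize(
    model: MetabolicModel,
    tol: float = 1e-9,
    solver: SolverBackend = solve_highs,
) -> FluxResult:
    """Solve the FBA linear program for ``model``.

    Parameters
    ----------
    model
        A validated :class:`~fluxsens.model_io.MetabolicModel`.
    tol
        Constraint-residual tolerance used to sanity-check an optimal
        solution; violations beyond ``10*tol`` raise :class:`EngineError`.
    solver
        Backend conforming to the one-function solver contract.
    """
    status, obj, x = solver(model.objective_coeffs, model.S.tocsr(),
                            model.lower_bounds, model.upper_bounds)
    if status != "optimal":
        return FluxResult(status=status)
    residual = np.abs(model.S @ x)
    check_tol = max(10 * tol, 1e-7)
    if residual.size and residual.max() > check_tol:
        raise EngineError(
            f"solver returned mass-balance residual {residual.max():.3e} > {check_tol:.1e}"
        )
    return FluxResult(status="optimal", objective_value=obj, fluxes=x)
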