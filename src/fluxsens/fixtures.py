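"""Toy constraint-based models with analytically known sensitivity structure.

Three families cover the behaviours the estimators must distinguish:

* **Linear chain** — one exchange per nutrient, each feeding an independent
  unit pathway into a shared biomass sink with a per-nutrient yield y_i. The
  FBA optimum is sum_i y_i * |lb_i|: additive in the factors, so under
  independent uniform intake bounds the analytic indices are
  S_i = S_Ti = y_i^2 / sum_j y_j^2 and every interaction gap is zero.

* **Min-coupled** — two nutrients consumed 1:1 by the growth reaction; the
  optimum is min(|lb_A|, |lb_B|). On the unit scale E[min | X_i = x] =
  x - x^2/2, giving Var[E(Y|X_i)] = 1/45 against Var(min) = 1/18, hence
  S_1 = S_2 = 0.4 and (two factors) S_T1 = S_T2 = 0.6: a controlled
  interaction instance with gap 0.2.

* **Random small** — seeded sparse stoichiometry with finite bounds and the
  zero flux vector always feasible, small enough for brute-force vertex
  enumeration to certify the LP optimum.

Analytic test functions mirroring the first two (plus the centered product,
whose variance is pure interaction) let estimator tests bypass FBA entirely.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .model_io import MetabolicModel
from .saltelli import DEFAULT_INTERVAL

__all__ = [
    "make_linear_chain_model",
    "make_min_coupled_model",
    "make_random_small_model",
    "additive_function",
    "min_function",
    "centered_product_function",
    "analytic_chain_indices",
    "MIN_COUPLED_S1",
    "MIN_COUPLED_ST",
]

#: Analytic Sobol' indices of min(|X1|, |X2|) under independent uniform factors.
MIN_COUPLED_S1 = 0.4  # Var[E(Y|X_i)] / Var(Y) = (1/45) / (1/18)
MIN_COUPLED_ST = 0.6  # complement of the other factor's closed effect

_BIG = 1000.0  # conventional "unconstrained" internal-flux capacity


def make_linear_chain_model(
    yields: Sequence[float] = (1.0, 1.0),
    interval: tuple[float, float] = DEFAULT_INTERVAL,
) -> MetabolicModel:
    """Additive fixture: growth = sum of yield-weighted intake capacities."""
    yields = np.asarray(yields, dtype=float)
    if yields.size < 1 or np.any(yields <= 0):
        raise ValueError("at least one positive yield is required")
    k = yields.size
    met_ids = [f"nut{i}" for i in range(k)] + ["biomass_pool"]
    rxn_ids = [f"EX_nut{i}" for i in range(k)] + [f"CONV_nut{i}" for i in range(k)] + ["GROWTH"]
    S = sp.lil_matrix((k + 1, 2 * k + 1))
    for i in range(k):
        S[i, i] = -1.0  # exchange: negative flux imports nut_i
        S[i, k + i] = -1.0  # conversion consumes nut_i ...
        S[k, k + i] = yields[i]  # ... and produces yield_i of biomass precursor
    S[k, 2 * k] = -1.0  # growth drains the biomass pool
    lb = np.concatenate([np.full(k, interval[0]), np.zeros(k + 1)])
    ub = np.concatenate([np.full(k, interval[1]), np.full(k + 1, _BIG)])
    w = np.zeros(2 * k + 1)
    w[2 * k] = 1.0
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lower_bounds=lb,
        upper_bounds=ub,
        objective_coeffs=w,
        name=f"linear_chain_{k}",
    ).validate()


def make_min_coupled_model(
    interval: tuple[float, float] = DEFAULT_INTERVAL,
) -> MetabolicModel:
    """Interaction fixture: growth = min of the two intake capacities."""
    S = sp.lil_matrix((2, 3))
    S[0, 0] = -1.0  # EX_A imports A
    S[1, 1] = -1.0  # EX_B imports B
    S[0, 2] = -1.0  # growth consumes A and B 1:1
    S[1, 2] = -1.0
    return MetabolicModel(
        metabolite_ids=["A", "B"],
        reaction_ids=["EX_A", "EX_B", "GROWTH"],
        S=S,
        lower_bounds=np.array([interval[0], interval[0], 0.0]),
        upper_bounds=np.array([interval[1], interval[1], _BIG]),
        objective_coeffs=np.array([0.0, 0.0, 1.0]),
        name="min_coupled",
    ).validate()


def make_random_small_model(m: int = 5, r: int = 8, seed: int = 0) -> MetabolicModel:
    """Seeded random sparse model; finite bounds, zero flux always feasible.

    ``r`` is capped at 12 to keep brute-force vertex enumeration tractable
    for the oracle tests.
    """
    if r > 12:
        raise ValueError("r must be <= 12 (vertex-oracle tractability)")
    rng = np.random.default_rng(seed)
    while True:
        S = sp.lil_matrix((m, r))
        for j in range(r):
            k = rng.integers(1, min(3, m) + 1)
            rows = rng.choice(m, size=k, replace=False)
            for i in rows:
                S[i, j] = float(rng.choice([-2, -1, 1, 2]))
        lb = -rng.integers(0, 11, size=r).astype(float)  # 0 in every interval
        ub = rng.integers(0, 11, size=r).astype(float)
        w = np.zeros(r)
        nz = rng.choice(r, size=max(1, r // 3), replace=False)
        w[nz] = rng.choice([-1.0, 1.0, 2.0], size=nz.size)
        model = MetabolicModel(
            metabolite_ids=[f"m{i}" for i in range(m)],
            reaction_ids=[f"r{j}" for j in range(r)],
            S=S,
            lower_bounds=lb,
            upper_bounds=ub,
            objective_coeffs=w,
            name=f"random_{m}x{r}_seed{seed}",
        )
        try:
            return model.validate()
        except Exception:  # pragma: no cover - regenerate on a degenerate draw
            continue


def additive_function(yields: Sequence[float] = (1.0, 1.0)):
    """Closed form of the linear-chain optimum: sum_i y_i * |x_i|."""
    y = np.asarray(yields, dtype=float)

    def f(X: np.ndarray) -> np.ndarray:
        return np.abs(np.atleast_2d(X)) @ y

    return f


def min_function(X: np.ndarray) -> np.ndarray:
    """Closed form of the min-coupled optimum: min_i |x_i|."""
    return np.abs(np.atleast_2d(X)).min(axis=1)


def centered_product_function(X: np.ndarray) -> np.ndarray:
    """(x1 - 1/2)(x2 - 1/2) on [0, 1]^2: zero main effects, pure interaction."""
    X = np.atleast_2d(X)
    return (X[:, 0] - 0.5) * (X[:, 1] - 0.5)


def analytic_chain_indices(yields: Sequence[float]) -> np.ndarray:
    """Exact S_i = S_Ti for the linear chain under independent uniform factors."""
    y2 = np.asarray(yields, dtype=float) ** 2
    return y2 / y2.sum()
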