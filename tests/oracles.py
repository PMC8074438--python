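"""Independent oracles used by the test suite.

These deliberately share no code path with the package: the LP oracle
enumerates candidate vertices of the flux polytope by brute force, and the
Sobol' oracle estimates conditional variances with a plain double-loop
Monte-Carlo scheme.
"""

from __future__ import annotations

import itertools

import numpy as np


def vertex_enumeration_optimum(model, tol: float = 1e-7) -> float:
    """LP maximum of w·v over {S v = 0, l <= v <= u} by brute force.

    Enumerates every subset of reactions pinned at a lower or upper bound,
    solves the remaining equality system by least squares, keeps feasible
    candidates, and returns the best objective. Valid for models with all
    bounds finite (the feasible set is a polytope, so the optimum is at a
    vertex, and every vertex is produced by some pinned subset).
    """
    S = np.asarray(model.S.todense(), dtype=float)
    lb, ub, w = model.lower_bounds, model.upper_bounds, model.objective_coeffs
    m, r = S.shape
    best = None
    for k in range(r + 1):
        for pinned in itertools.combinations(range(r), k):
            free = [j for j in range(r) if j not in pinned]
            for choice in itertools.product(*[(lb[j], ub[j]) for j in pinned]):
                v = np.zeros(r)
                v[list(pinned)] = choice
                if free:
                    rhs = -S[:, list(pinned)] @ np.asarray(choice)
                    sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
                    v[free] = sol
                if np.abs(S @ v).max(initial=0.0) > tol:
                    continue
                if np.any(v < lb - tol) or np.any(v > ub + tol):
                    continue
                obj = float(w @ v)
                if best is None or obj > best:
                    best = obj
    if best is None:
        raise AssertionError("oracle found no feasible point")
    return best


def double_loop_sobol(
    f,
    D: int,
    n_outer: int = 400,
    n_inner: int = 400,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Double-loop Monte-Carlo estimate of (S1, ST, S1_se, ST_se) on U[0,1]^D.

    S1_i = Var_x[E(Y | X_i = x)] / Var(Y); ST_i = E[Var(Y | X_~i)] / Var(Y).
    Brute conditional expectations/variances, no cross-sampling tricks; the
    standard errors are over the outer loop.
    """
    rng = np.random.default_rng(seed)
    total = np.asarray(f(rng.random((n_outer * n_inner, D))), dtype=float)
    var_y = total.var()
    S1 = np.empty(D)
    ST = np.empty(D)
    S1_se = np.empty(D)
    ST_se = np.empty(D)
    for i in range(D):
        cond_means = np.empty(n_outer)
        for k in range(n_outer):
            X = rng.random((n_inner, D))
            X[:, i] = rng.random()
            cond_means[k] = np.mean(f(X))
        S1[i] = cond_means.var() / var_y
        sq_dev = (cond_means - cond_means.mean()) ** 2
        S1_se[i] = sq_dev.std(ddof=1) / np.sqrt(n_outer) / var_y
        cond_vars = np.empty(n_outer)
        for k in range(n_outer):
            X = np.tile(rng.random(D), (n_inner, 1))
            X[:, i] = rng.random(n_inner)
            cond_vars[k] = np.var(f(X))
        ST[i] = cond_vars.mean() / var_y
        ST_se[i] = cond_vars.std(ddof=1) / np.sqrt(n_outer) / var_y
    return S1, ST, S1_se, ST_se
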