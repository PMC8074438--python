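"""Morris elementary-effects screening.

The method walks r random one-at-a-time (OAT) trajectories through a p-level
grid on the unit hypercube: each trajectory starts at a random grid point
and moves every factor exactly once by +/-delta, giving r(D+1) design rows.
For factor i the elementary effect in a trajectory is the finite difference

    EE_i = (Y(x + s*delta*e_i) - Y(x)) / (s*delta)        s in {-1, +1}

on the unit scale. mu* (mean of |EE_i| over trajectories) measures a
factor's overall influence; sigma (standard deviation of EE_i) measures how
much the effect depends on where it is evaluated — nonlinearity and/or
interaction with other factors. For a purely additive linear output every
elementary effect is constant, so sigma is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import AlignmentError
from .saltelli import DEFAULT_INTERVAL, scale_to_bounds

__all__ = ["MorrisDesign", "MorrisResult", "morris_trajectories", "elementary_effects"]


@dataclass
class MorrisDesign:
    """r trajectories of D+1 points each, with step bookkeeping.

    ``unit_matrix`` holds the grid points in [0, 1]; ``matrix`` is the same
    design scaled to factor bounds. ``step_factor[t, k]`` is the factor
    moved at step k of trajectory t and ``step_sign[t, k]`` its direction.
    """

    factor_names: list[str]
    factor_bounds: np.ndarray
    unit_matrix: np.ndarray
    matrix: np.ndarray
    step_factor: np.ndarray  # r x D of int
    step_sign: np.ndarray  # r x D of +/-1
    delta: float
    levels: int

    @property
    def r(self) -> int:
        return self.step_factor.shape[0]

    @property
    def D(self) -> int:
        return len(self.factor_names)

    @property
    def n_rows(self) -> int:
        return self.unit_matrix.shape[0]


@dataclass
class MorrisResult:
    """Per-factor mu* and sigma of elementary effects."""

    factor_names: list[str]
    mu_star: np.ndarray
    sigma: np.ndarray
    n_trajectories: int
    mu: Optional[np.ndarray] = None  # signed mean, kept for diagnostics
    mu_star_conf: Optional[np.ndarray] = None

    def to_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"factor": self.factor_names, "mu_star": self.mu_star, "sigma": self.sigma}
        )
        if self.mu_star_conf is not None:
            df["mu_star_conf"] = self.mu_star_conf
        return df


def morris_trajectories(
    r: int,
    D: int,
    levels: int = 4,
    delta: Optional[float] = None,
    bounds: Optional[Sequence] = None,
    seed: Optional[int] = None,
) -> MorrisDesign:
    """Random OAT trajectory design of r(D+1) rows.

    ``levels`` (p, even) grid points per factor at 0, 1/(p-1), ..., 1; the
    step ``delta`` defaults to p/(2(p-1)) — 2/3 for the common p=4 — and
    must be a multiple of 1/(p-1). Consecutive rows within a trajectory
    differ in exactly one factor by +/-delta; each factor moves exactly once
    per trajectory. Deterministic under a fixed seed.
    """
    if r < 1 or D < 1:
        raise ValueError("r and D must be positive")
    if levels < 2 or levels % 2:
        raise ValueError("levels must be an even number >= 2")
    grid_step = 1.0 / (levels - 1)
    if delta is None:
        delta = levels / (2.0 * (levels - 1))
    ratio = delta / grid_step
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"delta={delta} is not a multiple of 1/(levels-1)={grid_step}")
    if not 0 < delta <= 1:
        raise ValueError("delta must lie in (0, 1]")
    if bounds is None:
        bounds = [DEFAULT_INTERVAL] * D
    bounds = np.asarray(bounds, dtype=float).reshape(D, 2)

    rng = np.random.default_rng(seed)
    rows = np.empty((r * (D + 1), D))
    step_factor = np.empty((r, D), dtype=int)
    step_sign = np.empty((r, D), dtype=int)
    grid = np.arange(levels) * grid_step
    for t in range(r):
        signs = rng.choice([-1, 1], size=D)
        # start on a grid point from which the signed step stays inside [0, 1]
        x = np.empty(D)
        for i in range(D):
            feasible = grid[(grid + signs[i] * delta >= -1e-12) & (grid + signs[i] * delta <= 1 + 1e-12)]
            x[i] = rng.choice(feasible)
        order = rng.permutation(D)
        base = t * (D + 1)
        rows[base] = x
        for k, i in enumerate(order):
            x = x.copy()
            x[i] += signs[i] * delta
            rows[base + k + 1] = x
        step_factor[t] = order
        step_sign[t] = signs[order]
    rows = np.clip(rows, 0.0, 1.0)
    return MorrisDesign(
        factor_names=[f"x{i}" for i in range(D)],
        factor_bounds=bounds,
        unit_matrix=rows,
        matrix=scale_to_bounds(rows, bounds),
        step_factor=step_factor,
        step_sign=step_sign,
        delta=float(delta),
        levels=levels,
    )


def elementary_effects(
    Y: np.ndarray,
    design: MorrisDesign,
    n_boot: int = 0,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> MorrisResult:
    """Compute mu* and sigma from outputs aligned with a trajectory design.

    With ``n_boot`` > 0, mu* confidence half-widths are estimated by
    bootstrap resampling of whole trajectories.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape != (design.n_rows,):
        raise AlignmentError(
            f"output length {Y.shape} does not match design rows {design.n_rows}"
        )
    r, D = design.r, design.D
    ee = np.empty((r, D))
    for t in range(r):
        base = t * (D + 1)
        for k in range(D):
            i = design.step_factor[t, k]
            ee[t, i] = (Y[base + k + 1] - Y[base + k]) / (design.step_sign[t, k] * design.delta)
    mu_star = np.abs(ee).mean(axis=0)
    mu = ee.mean(axis=0)
    sigma = ee.std(axis=0, ddof=1) if r > 1 else np.zeros(D)
    conf = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, D))
        for b in range(n_boot):
            idx = rng.integers(0, r, size=r)
            boots[b] = np.abs(ee[idx]).mean(axis=0)
        conf = norm.ppf(0.5 + level / 2) * boots.std(axis=0, ddof=1)
    return MorrisResult(
        factor_names=list(design.factor_names),
        mu_star=mu_star,
        sigma=sigma,
        n_trajectories=r,
        mu=mu,
        mu_star_conf=conf,
    )
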