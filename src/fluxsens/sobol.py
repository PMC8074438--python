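"""Variance-based (Sobol') sensitivity estimators with bootstrap CIs.

Given model outputs aligned with a Saltelli design, the first-order index

    S_i  = Var[E(Y | X_i)] / Var(Y)

is estimated with the Saltelli-2010 cross-block form
``mean(f_B * (f_ABi - f_A)) / V`` and the total-effect index

    S_Ti = 1 - Var[E(Y | X_~i)] / Var(Y)

with the Jansen form ``mean((f_A - f_ABi)^2) / (2 V)``, where V is the
variance of Y over the A and B blocks. These are the forms used by the
standard SA libraries, so results are directly comparable.

Monte-Carlo noise can push estimates slightly outside [0, 1]; values are
reported unclipped, and the result object flags factors that fall outside by
more than their CI half-width.

Confidence intervals come from bootstrap resampling of base-sample indices:
a resample picks N base rows with replacement and carries each row's A, B
and A_B^(i) entries together, preserving the cross-block pairing the
estimators rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import AlignmentError, DegenerateOutputError
from .saltelli import SamplingDesign

__all__ = [
    "EvaluationSet",
    "SensitivityResult",
    "estimate_first_order",
    "estimate_total_order",
    "estimate_second_order",
    "bootstrap_confidence",
    "interaction_gap",
    "rank_factors",
    "analyze",
]


@dataclass
class EvaluationSet:
    """Model outputs aligned one-to-one with a design's rows.

    ``Y[k]`` is the optimal objective for design row k (mM/h); ``n_failed``
    counts rows whose FBA was non-optimal and were imputed by the executor's
    failure policy. All entries are finite.
    """

    Y: np.ndarray
    n_failed: int = 0

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("EvaluationSet contains non-finite outputs")


@dataclass
class SensitivityResult:
    """Per-factor Sobol' indices, their 95% CI half-widths, and rankings."""

    factor_names: list[str]
    S1: np.ndarray
    ST: np.ndarray
    S1_conf: Optional[np.ndarray] = None
    ST_conf: Optional[np.ndarray] = None
    S2: Optional[np.ndarray] = None
    ranking_total: list[str] = field(default_factory=list)
    ranking_first: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ranking_total:
            self.ranking_total = rank_factors(self, by="total")
        if not self.ranking_first:
            self.ranking_first = rank_factors(self, by="first")

    def interaction_gap(self) -> np.ndarray:
        return interaction_gap(self)

    def out_of_range_factors(self) -> list[str]:
        """Factors whose indices fall outside [0, 1] by more than the CI half-width."""
        flagged = []
        for arr, conf in ((self.S1, self.S1_conf), (self.ST, self.ST_conf)):
            hw = conf if conf is not None else np.zeros_like(arr)
            mask = (arr < -hw) | (arr > 1 + hw)
            flagged.extend(np.asarray(self.factor_names)[mask])
        return sorted(set(flagged))

    def to_table(self) -> pd.DataFrame:
        rank_t = {n: k + 1 for k, n in enumerate(self.ranking_total)}
        rank_f = {n: k + 1 for k, n in enumerate(self.ranking_first)}
        return pd.DataFrame(
            {
                "factor": self.factor_names,
                "S1": self.S1,
                "S1_conf": self.S1_conf if self.S1_conf is not None else np.nan,
                "ST": self.ST,
                "ST_conf": self.ST_conf if self.ST_conf is not None else np.nan,
                "rank_total": [rank_t[n] for n in self.factor_names],
                "rank_first": [rank_f[n] for n in self.factor_names],
            }
        )


def _split_blocks(evals: EvaluationSet, design: SamplingDesign):
    Y = evals.Y
    if Y.shape[0] != design.n_rows:
        raise AlignmentError(
            f"output length {Y.shape[0]} does not match design rows {design.n_rows}"
        )
    f_A = Y[design.block_slice("A")]
    f_B = Y[design.block_slice("B")]
    f_AB = np.column_stack(
        [Y[design.block_slice(f"AB_{i}")] for i in range(design.D)]
    )
    f_BA = None
    if design.second_order:
        f_BA = np.column_stack(
            [Y[design.block_slice(f"BA_{i}")] for i in range(design.D)]
        )
    return f_A, f_B, f_AB, f_BA


def _variance(f_A: np.ndarray, f_B: np.ndarray) -> float:
    V = float(np.var(np.concatenate([f_A, f_B])))
    if V == 0.0:
        raise DegenerateOutputError(
            f"model output is constant ({f_A[0]!r}) across the design; "
            "sensitivity indices are undefined"
        )
    return V


def _first_order(f_A, f_B, f_AB, V) -> np.ndarray:
    return np.mean(f_B[:, None] * (f_AB - f_A[:, None]), axis=0) / V


def _total_order(f_A, f_B, f_AB, V) -> np.ndarray:
    return 0.5 * np.mean((f_A[:, None] - f_AB) ** 2, axis=0) / V


def estimate_first_order(evals: EvaluationSet, design: SamplingDesign) -> np.ndarray:
    """First-order indices S_i (Saltelli-2010 cross-block estimator), unclipped."""
    f_A, f_B, f_AB, _ = _split_blocks(evals, design)
    return _first_order(f_A, f_B, f_AB, _variance(f_A, f_B))


def estimate_total_order(evals: EvaluationSet, design: SamplingDesign) -> np.ndarray:
    """Total-effect indices S_Ti (Jansen estimator), unclipped."""
    f_A, f_B, f_AB, _ = _split_blocks(evals, design)
    return _total_order(f_A, f_B, f_AB, _variance(f_A, f_B))


def estimate_second_order(evals: EvaluationSet, design: SamplingDesign) -> np.ndarray:
    """Second-order interaction matrix S2[i, j]; requires a second-order design."""
    if not design.second_order:
        raise ValueError("second-order indices need a design with B_A^(i) blocks")
    f_A, f_B, f_AB, f_BA = _split_blocks(evals, design)
    V = _variance(f_A, f_B)
    S1 = _first_order(f_A, f_B, f_AB, V)
    D = design.D
    S2 = np.full((D, D), np.nan)
    for i in range(D):
        for j in range(i + 1, D):
            Vij = np.mean(f_BA[:, i] * f_AB[:, j] - f_A * f_B) / V
            S2[i, j] = S2[j, i] = Vij - S1[i] - S1[j]
    return S2


def bootstrap_confidence(
    evals: EvaluationSet,
    design: SamplingDesign,
    n_boot: int = 100,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """CI half-widths for (S1, ST) by row-coupled bootstrap over base samples.

    Each of ``n_boot`` resamples draws N base-sample indices with
    replacement; a base sample's A, B and A_B^(i) rows move together. The
    half-width is z * sd of the bootstrap distribution at the given level,
    deterministic under a fixed seed.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    f_A, f_B, f_AB, _ = _split_blocks(evals, design)
    N = design.N
    rng = np.random.default_rng(seed)
    s1_boot = np.empty((n_boot, design.D))
    st_boot = np.empty((n_boot, design.D))
    for b in range(n_boot):
        idx = rng.integers(0, N, size=N)
        a, bb, ab = f_A[idx], f_B[idx], f_AB[idx]
        V = float(np.var(np.concatenate([a, bb])))
        if V == 0.0:
            s1_boot[b] = st_boot[b] = 0.0
            continue
        s1_boot[b] = _first_order(a, bb, ab, V)
        st_boot[b] = _total_order(a, bb, ab, V)
    z = norm.ppf(0.5 + level / 2)
    return z * s1_boot.std(axis=0, ddof=1), z * st_boot.std(axis=0, ddof=1)


def interaction_gap(result: SensitivityResult) -> np.ndarray:
    """Elementwise S_Ti - S_i.

    Near-zero gap means the output depends on that factor nearly additively;
    a positive gap measures higher-order (interaction) contributions.
    Negative values — possible from Monte-Carlo noise — are preserved, not
    clipped; callers may flag them via ``result.out_of_range_factors``.
    """
    return np.asarray(result.ST) - np.asarray(result.S1)


def rank_factors(result: SensitivityResult, by: str = "total") -> list[str]:
    """Factor names sorted by descending index; ties broken lexicographically."""
    if by not in ("first", "total"):
        raise ValueError("by must be 'first' or 'total'")
    values = result.S1 if by == "first" else result.ST
    order = sorted(zip(result.factor_names, values), key=lambda t: (-t[1], t[0]))
    return [name for name, _ in order]


def analyze(
    evals: EvaluationSet,
    design: SamplingDesign,
    n_boot: int = 100,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> SensitivityResult:
    """Full analysis: S1, ST, optional S2, bootstrap CIs and rankings."""
    S1 = estimate_first_order(evals, design)
    ST = estimate_total_order(evals, design)
    S1_conf, ST_conf = bootstrap_confidence(evals, design, n_boot=n_boot, level=level, seed=seed)
    S2 = estimate_second_order(evals, design) if design.second_order else None
    return SensitivityResult(
        factor_names=list(design.factor_names),
        S1=S1,
        ST=ST,
        S1_conf=S1_conf,
        ST_conf=ST_conf,
        S2=S2,
    )
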