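"""Saltelli cross-sampling designs on a Sobol' low-discrepancy sequence.

The design that feeds the variance-based estimators consists of two base
blocks A and B, each of N rows in D dimensions, drawn by splitting a
2D-dimensional Sobol' sequence column-wise, plus D hybrid blocks A_B^(i) in
which column i of A is replaced by column i of B. First-order and
total-effect indices need A, B and the A_B^(i) blocks — N(D+2) rows in
total. The optional second-order scheme adds the mirrored B_A^(i) blocks,
giving N(2D+2) rows.

The first point of the unscrambled Sobol' sequence is the all-zeros vector,
which after scaling would pin every factor at its lower bound; it is skipped
by default (``skip=1``), and the skip policy is recorded on the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .errors import CapabilityError

__all__ = [
    "SamplingDesign",
    "sobol_sequence",
    "saltelli_design",
    "scale_to_bounds",
    "design_row_count",
]

DEFAULT_INTERVAL = (-10.0, 0.0)  # mM/h, the intake-bound uncertainty interval


def design_row_count(N: int, D: int, second_order: bool = False) -> int:
    """Rows in a Saltelli design: N(D+2), or N(2D+2) with second-order blocks."""
    if N < 1 or D < 1:
        raise ValueError("N and D must be positive")
    return N * (2 * D + 2) if second_order else N * (D + 2)


@dataclass
class SamplingDesign:
    """A Saltelli design with row provenance.

    ``matrix`` is R x D with R given by :func:`design_row_count`; rows are
    laid out block-contiguously as A, B, A_B^(0..D-1) and, when
    ``second_order``, B_A^(0..D-1). ``row_blocks`` labels each row with its
    block ("A", "B", "AB_i", "BA_i").
    """

    factor_names: list[str]
    factor_bounds: np.ndarray  # D x 2
    N: int
    second_order: bool
    matrix: np.ndarray  # R x D
    row_blocks: np.ndarray  # R, of str
    skip: int = 1
    _slices: dict = field(init=False, repr=False, default_factory=dict)

    @property
    def D(self) -> int:
        return len(self.factor_names)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def block(self, label: str) -> np.ndarray:
        """Rows of one block; label is 'A', 'B', 'AB_i' or 'BA_i'."""
        return self.matrix[self.block_slice(label)]

    def block_slice(self, label: str) -> slice:
        N, D = self.N, self.D
        if label == "A":
            return slice(0, N)
        if label == "B":
            return slice(N, 2 * N)
        kind, _, i = label.partition("_")
        i = int(i)
        if not 0 <= i < D:
            raise KeyError(label)
        if kind == "AB":
            return slice((2 + i) * N, (3 + i) * N)
        if kind == "BA" and self.second_order:
            return slice((2 + D + i) * N, (3 + D + i) * N)
        raise KeyError(label)

    def to_table(self) -> pd.DataFrame:
        """One row per parameterization, factor columns plus a block label."""
        df = pd.DataFrame(self.matrix, columns=self.factor_names)
        df["block"] = self.row_blocks
        return df

    def to_file(self, path: str) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_file(
        cls, path: str, N: int, second_order: bool, factor_bounds=None, skip: int = 1
    ) -> "SamplingDesign":
        df = pd.read_csv(path, sep="\t")
        names = [c for c in df.columns if c != "block"]
        matrix = df[names].to_numpy(dtype=float)
        if factor_bounds is None:
            factor_bounds = np.column_stack([matrix.min(axis=0), matrix.max(axis=0)])
        return cls(
            factor_names=names,
            factor_bounds=np.asarray(factor_bounds, dtype=float),
            N=N,
            second_order=second_order,
            matrix=matrix,
            row_blocks=df["block"].to_numpy(dtype=str),
            skip=skip,
        )


def sobol_sequence(n: int, d: int, skip: int = 0) -> np.ndarray:
    """First ``n`` points (after ``skip``) of the d-dimensional Sobol' sequence.

    Unscrambled base-2 sequence with the published direction numbers as
    shipped by scipy; deterministic for fixed (n, d, skip), all coordinates
    in [0, 1).
    """
    if n < 1 or d < 1:
        raise ValueError("n and d must be positive")
    if d > qmc.Sobol.MAXDIM:
        raise CapabilityError(
            f"Sobol' direction numbers available up to d={qmc.Sobol.MAXDIM}, got {d}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # unbalanced-n advisory
        gen = qmc.Sobol(d=d, scramble=False)
        if skip:
            gen.fast_forward(skip)
        return gen.random(n)


def scale_to_bounds(unit_points: np.ndarray, bounds) -> np.ndarray:
    """Affine map of unit-hypercube points onto per-column (low, high) bounds."""
    unit_points = np.asarray(unit_points, dtype=float)
    bounds = np.asarray(bounds, dtype=float).reshape(-1, 2)
    low, high = bounds[:, 0], bounds[:, 1]
    if np.any(low > high):
        bad = int(np.flatnonzero(low > high)[0])
        raise ValueError(f"factor {bad}: lower bound {low[bad]} exceeds upper {high[bad]}")
    return low + unit_points * (high - low)


def saltelli_design(
    N: int,
    D: int,
    second_order: bool = False,
    bounds: Optional[Sequence] = None,
    factor_names: Optional[list[str]] = None,
    skip: int = 1,
) -> SamplingDesign:
    """Generate the Saltelli cross-sampling design.

    A and B come from splitting a 2D-dimensional Sobol' sequence of N points
    column-wise; A_B^(i) equals A with column i replaced by B's column i.
    ``bounds`` defaults to the intake interval [-10, 0] mM/h for every
    factor. Generation is reproducible bit-for-bit for a fixed ``skip``.
    """
    if bounds is None:
        bounds = [DEFAULT_INTERVAL] * D
    bounds = np.asarray(bounds, dtype=float).reshape(D, 2)
    if factor_names is None:
        factor_names = [f"x{i}" for i in range(D)]
    if N & (N - 1):
        warnings.warn(
            f"N={N} is not a power of two; Sobol' balance properties degrade",
            UserWarning,
            stacklevel=2,
        )
    base = sobol_sequence(N, 2 * D, skip=skip)
    A, B = base[:, :D], base[:, D:]
    blocks = [A, B]
    labels = ["A"] * N + ["B"] * N
    for i in range(D):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
        labels += [f"AB_{i}"] * N
    if second_order:
        for i in range(D):
            BA = B.copy()
            BA[:, i] = A[:, i]
            blocks.append(BA)
            labels += [f"BA_{i}"] * N
    unit = np.vstack(blocks)
    return SamplingDesign(
        factor_names=list(factor_names),
        factor_bounds=bounds,
        N=N,
        second_order=second_order,
        matrix=scale_to_bounds(unit, bounds),
        row_blocks=np.array(labels),
        skip=skip,
    )
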