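"""Design evaluation under a master-worker contract.

Every design row is an assignment of intake lower bounds; its output is the
FBA optimum of the model under those bounds. Evaluation order never affects
results: rows are assigned to workers as contiguous chunks and reassembled
by position, so serial and parallel runs produce bitwise-identical output
vectors.

Each worker solves the rows of its chunk by hot-swapping lower bounds into a
single bounds vector rather than rebuilding the model — only lower bounds
differ between rows. Chunk assignment is static because FBA cost does not
depend on the bound values, so there is nothing for work-stealing to
balance.

A JSON checkpoint file can record completed chunks; resuming reproduces the
same EvaluationSet as an uninterrupted run.
"""

from __future__ import annotations

import json
import math
import os
from concurrent.futures import ProcessPoolExecutor
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .errors import CapabilityError, CapacityError, EvaluationError
from .fba import fba_optimize
from .model_io import MetabolicModel, apply_intake_bounds
from .saltelli import SamplingDesign
from .sobol import EvaluationSet

__all__ = [
    "partition_design",
    "max_batch_size",
    "evaluate_design",
    "evaluate_function",
]


def partition_design(total_rows: int, n_workers: int) -> list[tuple[int, int]]:
    """Split ``[0, total_rows)`` into ``n_workers`` contiguous ranges.

    Ranges are disjoint, cover the whole interval, and differ in size by at
    most one; earlier workers absorb the remainder.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be positive")
    base, rem = divmod(total_rows, n_workers)
    ranges, start = [], 0
    for k in range(n_workers):
        size = base + (1 if k < rem else 0)
        ranges.append((start, start + size))
        start += size
    return ranges


def max_batch_size(
    available_memory: int,
    D: int,
    bytes_per_value: int = 8,
    overhead_factor: float = 1.0,
) -> int:
    """Largest number of design rows that fits in ``available_memory`` bytes.

    One row holds D values of ``bytes_per_value`` bytes; ``overhead_factor``
    (>= 1) inflates the footprint for bookkeeping and transport copies.
    """
    if min(available_memory, D, bytes_per_value) <= 0 or overhead_factor < 1:
        raise ValueError("all inputs must be positive and overhead_factor >= 1")
    per_row = D * bytes_per_value * overhead_factor
    n = math.floor(available_memory / per_row)
    if n < 1:
        raise CapacityError(
            f"one design row needs {per_row:.0f} bytes but only "
            f"{available_memory} are available"
        )
    return n


def _evaluate_rows(
    model: MetabolicModel,
    factor_indices: np.ndarray,
    rows: np.ndarray,
    tol: float,
) -> tuple[list[float], list[int]]:
    """Solve FBA for each row; return objective values and failed row offsets."""
    values: list[float] = []
    failed: list[int] = []
    work = model.copy()
    for k, row in enumerate(rows):
        work.lower_bounds[factor_indices] = row
        res = fba_optimize(work, tol=tol)
        if res.optimal:
            values.append(res.objective_value)
        else:
            values.append(math.nan)
            failed.append(k)
    return values, failed


def _worker_chunk(args):
    model, factor_indices, rows, tol, start = args
    values, failed = _evaluate_rows(model, factor_indices, rows, tol)
    return start, values, failed


def _resolve_matrix(design) -> np.ndarray:
    if isinstance(design, SamplingDesign):
        return design.matrix
    return np.asarray(design, dtype=float)


def evaluate_design(
    model: MetabolicModel,
    design: Union[SamplingDesign, np.ndarray],
    factor_indices: Sequence[int],
    backend: str = "serial",
    n_workers: int = 1,
    failure_policy: str = "zero",
    tol: float = 1e-9,
    checkpoint: Optional[str] = None,
) -> EvaluationSet:
    """Evaluate every design row with FBA.

    Parameters
    ----------
    model
        Baseline model; its lower bounds at ``factor_indices`` are replaced
        row by row (all other bounds stay at baseline).
    design
        A :class:`SamplingDesign` or a plain R x D matrix of bound values.
    backend
        ``serial``, ``process_pool``, or ``message_passing`` (the latter is
        an optional plug-in contract, not bundled).
    failure_policy
        ``zero`` imputes Y=0 for non-optimal rows and counts them in
        ``n_failed``; ``abort`` raises on the first such row.
    checkpoint
        Optional JSON path recording completed chunks; an interrupted run
        resumes from it and yields the same EvaluationSet.

    Returns an :class:`EvaluationSet` whose ordering matches the design
    regardless of backend or worker count.
    """
    if failure_policy not in ("zero", "abort"):
        raise ValueError(f"unknown failure policy {failure_policy!r}")
    matrix = _resolve_matrix(design)
    factor_indices = np.asarray(factor_indices, dtype=int)
    if matrix.shape[1] != factor_indices.size:
        raise ValueError(
            f"design has {matrix.shape[1]} factors but {factor_indices.size} indices given"
        )
    # bound sanity against the baseline model (lower must stay below upper);
    # delegate the error message to apply_intake_bounds on the offending row
    ub = model.upper_bounds[factor_indices]
    over = np.any(matrix > ub[None, :], axis=1)
    if over.any():
        apply_intake_bounds(model, factor_indices, matrix[int(np.argmax(over))])

    total = matrix.shape[0]
    done: dict[int, tuple[list[float], list[int]]] = {}
    if checkpoint and os.path.exists(checkpoint):
        with open(checkpoint) as fh:
            saved = json.load(fh)
        if saved.get("total_rows") == total:
            done = {
                int(k): (v["values"], v["failed"]) for k, v in saved["chunks"].items()
            }

    if backend == "serial":
        chunks = [(0, total)] if total else []
        results = {}
        for start, stop in chunks:
            if start in done:
                results[start] = done[start]
            else:
                results[start] = _evaluate_rows(model, factor_indices, matrix[start:stop], tol)
                _save_checkpoint(checkpoint, total, results)
    elif backend == "process_pool":
        ranges = [r for r in partition_design(total, n_workers) if r[1] > r[0]]
        pending = [
            (model, factor_indices, matrix[start:stop], tol, start)
            for start, stop in ranges
            if start not in done
        ]
        results = dict(done)
        if pending:
            with ProcessPoolExecutor(max_workers=n_workers) as pool:
                for start, values, failed in pool.map(_worker_chunk, pending):
                    results[start] = (values, failed)
        _save_checkpoint(checkpoint, total, results)
    elif backend == "message_passing":
        raise CapabilityError(
            "message_passing backend is an optional plug-in; install one "
            "conforming to the evaluate_design contract or use process_pool"
        )
    else:
        raise ValueError(f"unknown backend {backend!r}")

    Y = np.empty(total)
    n_failed = 0
    for start in sorted(results):
        values, failed = results[start]
        if failed and failure_policy == "abort":
            raise EvaluationError(
                f"design row {start + failed[0]} produced a non-optimal FBA status"
            )
        vals = np.asarray(values, dtype=float)
        if failed:
            vals[np.asarray(failed, dtype=int)] = 0.0
            n_failed += len(failed)
        Y[start : start + len(values)] = vals
    return EvaluationSet(Y=Y, n_failed=n_failed)


def _save_checkpoint(path, total, results) -> None:
    if not path:
        return
    payload = {
        "total_rows": total,
        "chunks": {
            str(start): {"values": list(map(float, v)), "failed": list(map(int, f))}
            for start, (v, f) in results.items()
        },
    }
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        json.dump(payload, fh)
    os.replace(tmp, path)


def evaluate_function(
    f: Callable[[np.ndarray], np.ndarray],
    design: Union[SamplingDesign, np.ndarray],
) -> EvaluationSet:
    """Evaluate an analytic test function on design rows, bypassing FBA.

    ``f`` maps an R x D matrix to a length-R output vector (or a single row
    to a scalar). Useful for isolating estimator behaviour from LP behaviour.
    """
    matrix = _resolve_matrix(design)
    Y = np.asarray(f(matrix), dtype=float)
    if Y.shape != (matrix.shape[0],):
        Y = np.array([float(f(row)) for row in matrix])
    return EvaluationSet(Y=Y, n_failed=0)
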