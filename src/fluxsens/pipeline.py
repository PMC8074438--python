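"""End-to-end workflows: config -> factors -> design -> FBA sweep -> report.

Each runner loads the model, resolves the factor set (all intake-capable
exchange reactions, or an explicit id list), generates its design, evaluates
every row with FBA through the executor, and writes tab-separated result
tables plus a machine-readable run manifest. Every defaulted decision (skip
policy, failure policy, solver, estimator forms) is echoed into the manifest
so a run is auditable and reproducible from its outputs alone.
"""

from __future__ import annotations

import difflib
import json
import logging
import os
from dataclasses import dataclass
from typing import Optional

from . import __version__
from .errors import ConfigurationError
from .executor import evaluate_design
from .model_io import find_exchange_reactions, load_model
from .morris import elementary_effects, morris_trajectories
from .perturb import depletion_vs_half_pairs
from .saltelli import design_row_count, saltelli_design
from .sobol import analyze, interaction_gap

log = logging.getLogger("fluxsens")

__all__ = ["GsaConfig", "MorrisConfig", "PerturbConfig", "run_gsa", "run_morris", "run_perturbation"]


@dataclass
class GsaConfig:
    model_path: str
    out_dir: str
    model_format: str = "auto"
    factors: str = "all-exchanges"  # or a path to a file with one reaction id per line
    interval: tuple[float, float] = (-10.0, 0.0)
    n: int = 1024
    second_order: bool = False
    skip: int = 1
    backend: str = "serial"
    workers: int = 1
    failure_policy: str = "zero"
    seed: int = 0
    n_boot: int = 100
    level: float = 0.95
    baseline_policy: str = "keep-model-defaults"  # or close-all-other-intakes
    write_design: bool = False

    @classmethod
    def from_file(cls, path: str, **overrides) -> "GsaConfig":
        """Read a flat ``key = value`` text config."""
        kv = _read_flat_config(path)
        kv.update(overrides)
        return cls(**_coerce(cls, kv))


@dataclass
class MorrisConfig:
    model_path: str
    out_dir: str
    model_format: str = "auto"
    factors: str = "all-exchanges"
    interval: tuple[float, float] = (-10.0, 0.0)
    trajectories: int = 64
    levels: int = 4
    delta: Optional[float] = None
    backend: str = "serial"
    workers: int = 1
    seed: int = 0
    n_boot: int = 100


@dataclass
class PerturbConfig:
    model_path: str
    out_dir: str
    model_format: str = "auto"
    factors: str = "all-exchanges"
    interval: tuple[float, float] = (-10.0, 0.0)  # accepted for CLI symmetry; unused


def _read_flat_config(path: str) -> dict:
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    return kv


def _coerce(cls, kv: dict) -> dict:
    import typing

    hints = typing.get_type_hints(cls)
    out = {}
    for key, raw in kv.items():
        if key not in hints:
            raise ConfigurationError(f"unknown config key {key!r}")
        if isinstance(raw, str):
            hint = hints[key]
            if hint is int:
                raw = int(raw)
            elif hint is bool:
                raw = raw.lower() in ("1", "true", "yes")
            elif hint is float:
                raw = float(raw)
            elif "tuple" in str(hint):
                raw = tuple(float(t) for t in raw.replace(",", " ").split())
        out[key] = raw
    return out


def _resolve_factors(model, spec: str) -> list[int]:
    exchanges = find_exchange_reactions(model, intake_only=True)
    if spec == "all-exchanges":
        if not exchanges:
            raise ConfigurationError("model has no intake-capable exchange reactions")
        return exchanges
    wanted = []
    if os.path.exists(spec):
        with open(spec) as fh:
            names = [ln.strip() for ln in fh if ln.strip()]
    else:
        names = [t for t in spec.replace(",", " ").split() if t]
    for name in names:
        try:
            wanted.append(model.reaction_index(name))
        except KeyError:
            near = difflib.get_close_matches(name, model.reaction_ids, n=3)
            raise ConfigurationError(
                f"factor {name!r} not found in model; near matches: {near}"
            ) from None
    if not wanted:
        raise ConfigurationError(f"factor specification {spec!r} resolved to nothing")
    return wanted


def _apply_baseline_policy(model, factor_indices, policy: str):
    if policy == "keep-model-defaults":
        return model
    if policy == "close-all-other-intakes":
        out = model.copy()
        others = [
            j
            for j in find_exchange_reactions(model, intake_only=True)
            if j not in set(map(int, factor_indices))
        ]
        out.lower_bounds[others] = 0.0
        return out
    raise ConfigurationError(f"unknown baseline policy {policy!r}")


def _load(cfg):
    model = load_model(cfg.model_path, format=cfg.model_format)
    idx = _resolve_factors(model, cfg.factors)
    return model, idx


def run_gsa(cfg: GsaConfig) -> dict:
    """Full Sobol' workflow; returns the manifest dict (also written to disk)."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    model, idx = _load(cfg)
    model = _apply_baseline_policy(model, idx, cfg.baseline_policy)
    names = [model.reaction_ids[j] for j in idx]
    D = len(idx)
    design = saltelli_design(
        cfg.n, D,
        second_order=cfg.second_order,
        bounds=[cfg.interval] * D,
        factor_names=names,
        skip=cfg.skip,
    )
    log.info("design: N=%d D=%d rows=%d", cfg.n, D, design.n_rows)
    evals = evaluate_design(
        model, design, idx,
        backend=cfg.backend, n_workers=cfg.workers,
        failure_policy=cfg.failure_policy,
    )
    log.info("evaluated %d rows (%d imputed)", design.n_rows, evals.n_failed)
    result = analyze(evals, design, n_boot=cfg.n_boot, level=cfg.level, seed=cfg.seed)

    table = result.to_table()
    table.to_csv(os.path.join(cfg.out_dir, "sobol_indices.tsv"), sep="\t", index=False)
    gaps = table[["factor"]].copy()
    gaps["interaction_gap"] = interaction_gap(result)
    gaps.to_csv(os.path.join(cfg.out_dir, "interaction_gap.tsv"), sep="\t", index=False)
    with open(os.path.join(cfg.out_dir, "ranking.txt"), "w") as fh:
        fh.write("# by total-effect index\n")
        fh.writelines(f"{name}\n" for name in result.ranking_total)
        fh.write("# by first-order index\n")
        fh.writelines(f"{name}\n" for name in result.ranking_first)
    if cfg.write_design:
        design.to_file(os.path.join(cfg.out_dir, "design.tsv"))

    manifest = {
        "tool": f"fluxsens {__version__}",
        "analysis": "sobol",
        "N": cfg.n,
        "D": D,
        "scheme": "N(2D+2)" if cfg.second_order else "N(D+2)",
        "row_count": design.n_rows,
        "rows_expected": design_row_count(cfg.n, D, cfg.second_order),
        "rows_imputed": evals.n_failed,
        "factors": names,
        "interval": list(cfg.interval),
        "seed": cfg.seed,
        "skip": cfg.skip,
        "n_boot": cfg.n_boot,
        "confidence_level": cfg.level,
        "estimators": {"first_order": "saltelli2010", "total_order": "jansen"},
        "solver": "scipy-highs",
        "backend": cfg.backend,
        "workers": cfg.workers,
        "failure_policy": cfg.failure_policy,
        "baseline_policy": cfg.baseline_policy,
        "model": cfg.model_path,
        "out_of_range_factors": result.out_of_range_factors(),
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_morris(cfg: MorrisConfig) -> dict:
    """Morris screening workflow; returns the manifest dict."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    model, idx = _load(cfg)
    names = [model.reaction_ids[j] for j in idx]
    D = len(idx)
    design = morris_trajectories(
        cfg.trajectories, D,
        levels=cfg.levels, delta=cfg.delta,
        bounds=[cfg.interval] * D, seed=cfg.seed,
    )
    design.factor_names = names
    evals = evaluate_design(
        model, design.matrix, idx, backend=cfg.backend, n_workers=cfg.workers
    )
    result = elementary_effects(evals.Y, design, n_boot=cfg.n_boot, seed=cfg.seed)
    result.to_table().to_csv(os.path.join(cfg.out_dir, "morris.tsv"), sep="\t", index=False)
    manifest = {
        "tool": f"fluxsens {__version__}",
        "analysis": "morris",
        "trajectories": cfg.trajectories,
        "levels": cfg.levels,
        "delta": design.delta,
        "D": D,
        "row_count": design.n_rows,
        "factors": names,
        "interval": list(cfg.interval),
        "seed": cfg.seed,
        "solver": "scipy-highs",
        "backend": cfg.backend,
        "model": cfg.model_path,
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_perturbation(cfg: PerturbConfig) -> dict:
    """Single-flux 100%/50% perturbation workflow; returns the manifest dict."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    model, idx = _load(cfg)
    table = depletion_vs_half_pairs(model, idx)
    table.to_csv(os.path.join(cfg.out_dir, "perturbation.tsv"), sep="\t", index=False)
    manifest = {
        "tool": f"fluxsens {__version__}",
        "analysis": "perturbation",
        "D": len(idx),
        "factors": [model.reaction_ids[j] for j in idx],
        "fractions": [1.0, 0.5],
        "solver": "scipy-highs",
        "model": cfg.model_path,
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
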