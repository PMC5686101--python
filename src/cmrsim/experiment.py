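"""Experiment configuration and batch execution.

An :class:`ExperimentConfig` (usually loaded from a YAML file) describes
a grid of cells — every combination of a swept covariate value and a
population size — and the CMR protocol to run in each cell.  Results go
to three files in the output directory: ``batches.csv`` (one row per
cell and batch), ``summary.csv`` (one row per cell with mean/SD/CI) and
``manifest.json`` (the full configuration, seeds and package version,
enough to reproduce any cell in isolation).  Re-running with the same
configuration and seed reproduces identical files; completed cells found
in an existing summary are not recomputed.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import __version__
from .cmr import CMREstimate, CMRProtocol, estimate_cmr
from .engine import RunConfig
from .landscape import make_landscape
from .population import ReproductionConfig

#: Covariates run_experiment knows how to sweep.
SWEEPABLE = (
    "gene_length",
    "gene_count",
    "scale",
    "crossovers",
    "chromosomes_per_gene",
    "distance",
    "r1",
)

_DEFAULTS = dict(
    gene_length=1000,
    gene_count=1,
    r0=2,
    r1=5,
    distance=10,
    scale=1,
    h0=15.0,
    h1=10.0,
    chromosomes_per_gene=1,
    crossovers=1,
    dominance=0.999999999999999,
)


class ConfigError(ValueError):
    """Invalid experiment configuration; lists the offending keys."""


@dataclass(frozen=True)
class ExperimentConfig:
    """A full experiment: base parameters, sweep, sizes, protocol, seed."""

    population_sizes: Tuple[int, ...]
    seed: int
    outdir: str
    profile: str = "reduced"
    sweep_parameter: Optional[str] = None
    sweep_values: Tuple = ()
    gene_length: int = _DEFAULTS["gene_length"]
    gene_count: int = _DEFAULTS["gene_count"]
    r0: int = _DEFAULTS["r0"]
    r1: int = _DEFAULTS["r1"]
    distance: int = _DEFAULTS["distance"]
    scale: int = _DEFAULTS["scale"]
    h0: float = _DEFAULTS["h0"]
    h1: float = _DEFAULTS["h1"]
    chromosomes_per_gene: int = _DEFAULTS["chromosomes_per_gene"]
    crossovers: int = _DEFAULTS["crossovers"]
    dominance: float = _DEFAULTS["dominance"]
    n_batches: Optional[int] = None
    batch_size: Optional[int] = None
    max_generations: Optional[int] = None
    engine: str = "auto"

    def protocol(self) -> CMRProtocol:
        base = CMRProtocol.full() if self.profile == "full" else CMRProtocol.reduced()
        kwargs = {}
        if self.n_batches is not None:
            kwargs["n_batches"] = self.n_batches
        if self.batch_size is not None:
            kwargs["batch_size"] = self.batch_size
        if self.max_generations is not None:
            kwargs["max_generations"] = self.max_generations
        from dataclasses import replace

        return replace(base, **kwargs) if kwargs else base

    def validate(self) -> None:
        bad = []
        if self.profile not in ("full", "reduced"):
            bad.append("profile")
        if not self.population_sizes or any(N < 1 for N in self.population_sizes):
            bad.append("population_sizes")
        if self.sweep_parameter is not None and self.sweep_parameter not in SWEEPABLE:
            bad.append("sweep_parameter")
        if self.sweep_parameter is not None and not self.sweep_values:
            bad.append("sweep_values")
        for key in ("gene_length", "gene_count", "scale", "chromosomes_per_gene", "crossovers"):
            if getattr(self, key) < 1:
                bad.append(key)
        if not 0.0 <= self.dominance <= 1.0:
            bad.append("dominance")
        # geometry and recombination feasibility for every cell
        for value in self.sweep_values or (None,):
            params = self._cell_params(value)
            sd = params["scale"] * params["distance"]
            if sd <= params["scale"] * (params["r0"] + params["r1"]):
                bad.append(f"{self.sweep_parameter or 'distance'} (peaks overlap)")
            if sd > params["gene_length"]:
                bad.append(f"{self.sweep_parameter or 'distance'} (distance > gene_length)")
            block = params["gene_length"] // params["chromosomes_per_gene"]
            if params["crossovers"] > block - 1:
                bad.append("crossovers (exceed chromosome boundaries)")
        if bad:
            raise ConfigError(f"invalid configuration keys: {sorted(set(bad))}")

    def _cell_params(self, sweep_value) -> Dict:
        params = {k: getattr(self, k) for k in _DEFAULTS}
        if self.sweep_parameter is not None and sweep_value is not None:
            params[self.sweep_parameter] = sweep_value
        return params

    def cells(self) -> List[Tuple[object, int]]:
        values = list(self.sweep_values) if self.sweep_parameter else [None]
        return [(v, int(N)) for v in values for N in self.population_sizes]


def load_config(path, **overrides) -> ExperimentConfig:
    """Read a YAML experiment file; keyword overrides win over file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"invalid configuration keys: {sorted(unknown)}")
    missing = [k for k in ("population_sizes", "seed", "outdir") if k not in raw]
    if missing:
        raise ConfigError(f"invalid configuration keys: {missing} (required, absent)")
    for key in ("population_sizes", "sweep_values"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    cfg = ExperimentConfig(**raw)
    cfg.validate()
    return cfg


def _cell_seed(master_seed: int, cell_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed, spawn_key=(cell_index,))


def _fmt(x) -> str:
    if x is None:
        return ""  # matches what csv round-trips for absent values
    if isinstance(x, float):
        return format(x, ".12g")
    return str(x)


def _completed_cells(summary_path) -> set:
    done = set()
    if os.path.exists(summary_path):
        with open(summary_path, newline="") as fh:
            for row in csv.DictReader(fh):
                done.add((row["sweep_parameter"], row["sweep_value"], int(row["population_size"])))
    return done


SUMMARY_FIELDS = [
    "sweep_parameter",
    "sweep_value",
    "population_size",
    "cmr_mean",
    "cmr_sd",
    "ci95_low",
    "ci95_high",
    "n_batches",
    "batch_size",
    "censored",
]
BATCH_FIELDS = ["sweep_parameter", "sweep_value", "population_size", "batch", "batch_cmr"]


def run_experiment(config: ExperimentConfig, progress=None) -> List[CMREstimate]:
    """Execute every cell and write batches.csv, summary.csv, manifest.json.

    ``progress`` is an optional callable receiving status strings.  Cells
    already present in an existing summary.csv are skipped (resume).
    Returns the estimates computed in this invocation.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    summary_path = os.path.join(config.outdir, "summary.csv")
    batches_path = os.path.join(config.outdir, "batches.csv")
    manifest_path = os.path.join(config.outdir, "manifest.json")
    done = _completed_cells(summary_path)
    protocol = config.protocol()

    cells = config.cells()
    manifest = {
        "package": "cmrsim",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "protocol": asdict(protocol),
        "cells": [
            {
                "index": i,
                "sweep_value": v,
                "population_size": N,
                "seed_spawn_key": [i],
            }
            for i, (v, N) in enumerate(cells)
        ],
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    new_summary = not os.path.exists(summary_path)
    new_batches = not os.path.exists(batches_path)
    estimates: List[CMREstimate] = []
    with open(summary_path, "a", newline="") as sfh, open(batches_path, "a", newline="") as bfh:
        swriter = csv.writer(sfh)
        bwriter = csv.writer(bfh)
        if new_summary:
            swriter.writerow(SUMMARY_FIELDS)
        if new_batches:
            bwriter.writerow(BATCH_FIELDS)
        for i, (value, N) in enumerate(cells):
            key = (_fmt(config.sweep_parameter), _fmt(value), N)
            if key in done:
                if progress:
                    progress(f"cell {i}: sweep={value} N={N} already complete, skipping")
                continue
            est = run_cell(config, value, N, cell_index=i, protocol=protocol)
            estimates.append(est)
            for b, bc in enumerate(est.batch_cmrs):
                bwriter.writerow(
                    [_fmt(config.sweep_parameter), _fmt(value), N, b, _fmt(float(bc))]
                )
            swriter.writerow(
                [
                    _fmt(config.sweep_parameter),
                    _fmt(value),
                    N,
                    _fmt(est.mean),
                    _fmt(est.sd),
                    _fmt(est.ci95[0]),
                    _fmt(est.ci95[1]),
                    est.n_batches,
                    protocol.batch_size,
                    est.censored,
                ]
            )
            sfh.flush()
            bfh.flush()
            if progress:
                progress(
                    f"cell {i}: sweep={value} N={N} -> CMR {est.mean:.3g} "
                    f"({est.n_batches} batches of {protocol.batch_size} runs)"
                )
    return estimates


def run_cell(
    config: ExperimentConfig,
    sweep_value,
    population_size: int,
    cell_index: int,
    protocol: Optional[CMRProtocol] = None,
) -> CMREstimate:
    """Estimate the CMR for one (covariate value, N) cell.

    The cell's landscape and run seeds derive deterministically from the
    master seed and the cell index, so any cell can be reproduced alone.
    """
    protocol = protocol or config.protocol()
    params = config._cell_params(sweep_value)
    land_ss, run_ss = _cell_seed(config.seed, cell_index).spawn(2)
    landscape = make_landscape(
        n=params["gene_count"],
        L=params["gene_length"],
        r0=params["r0"],
        r1=params["r1"],
        D=params["distance"],
        S=params["scale"],
        h0=params["h0"],
        h1=params["h1"],
        c=params["chromosomes_per_gene"],
        rng=np.random.default_rng(land_ss),
    )
    cfg = RunConfig(
        landscape=landscape,
        reproduction=ReproductionConfig(
            mutation_rate=0.0,
            crossovers_per_chromosome=params["crossovers"],
            chromosomes_per_gene=params["chromosomes_per_gene"],
            dominance=params["dominance"],
        ),
        population_size=population_size,
        max_generations=protocol.max_generations,
        seed=int(run_ss.generate_state(1)[0] & 0x7FFFFFFF),
    )
    summary = {"sweep_parameter": config.sweep_parameter, "sweep_value": sweep_value}
    return estimate_cmr(
        cfg,
        protocol,
        engine=config.engine,
        config_summary=summary,
        on_unresolved="censor",
    )
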