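"""Critical mutation rate (CMR) estimation.

The CMR is the per-base mutation rate at which 95% of runs lose the
fitter, narrower peak (peak 0) within the generation cap.  Rates are
swept coarse-to-fine: the coarse grid walks d x 10^-e for d=1..9 from
1e-8 up to 1e-2 to find the order of magnitude, then a fine grid in
steps of 0.1 x 10^-e pinpoints the CMR.  Dispersion comes from batches:
each batch's CMR is the smallest swept rate at which at least 95% of the
batch's runs lost peak 0, and the headline CMR is the batch mean with an
SD and a Student-t 95% confidence interval.

A rate is abandoned early ("early advance") as soon as the number of
runs retaining peak 0 makes the 95%-loss criterion unattainable for the
full run target, which never changes the accept/reject decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .engine import RunConfig, run_simulation

#: run_one(rate, batch_index, run_index) -> True iff the run lost peak 0.
RunOracle = Callable[[float, int, int], bool]


def coarse_grid() -> np.ndarray:
    """Ascending rates d x 10^-e, d=1..9, e=8 down to 3, capped by 1e-2."""
    # decimal-string construction keeps grid values bit-identical to
    # literals like 3e-5
    rates = [float(f"{d}e-{e}") for e in range(8, 2, -1) for d in range(1, 10)]
    rates.append(1e-2)
    return np.array(rates)


def fine_grid(e: int) -> np.ndarray:
    """Rates 1.0, 1.1, ..., 9.9 x 10^-e (steps of 0.1 x 10^-e)."""
    return np.array([float(f"{d}e-{e + 1}") for d in range(10, 100)])


def decade_of(rate: float) -> int:
    """Exponent e such that rate lies in [1, 10) x 10^-e."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return -int(math.floor(math.log10(rate) + 1e-9))


def _required_losses(total: int, loss_threshold: float) -> int:
    return math.ceil(loss_threshold * total)


def max_tolerated_keepers(total: int, loss_threshold: float = 0.95) -> int:
    """Largest keeper count still compatible with the loss criterion; one
    more keeper makes >= 95% loss impossible and triggers early advance."""
    return total - _required_losses(total, loss_threshold)


@dataclass(frozen=True)
class BatchResult:
    """Outcome of (part of) the runs executed at one mutation rate."""

    mutation_rate: float
    runs_total: int
    runs_lost: int
    early_advanced: bool

    def __post_init__(self):
        if self.runs_lost > self.runs_total:
            raise ValueError("runs_lost cannot exceed runs_total")

    @property
    def loss_fraction(self) -> float:
        return self.runs_lost / self.runs_total if self.runs_total else 0.0


@dataclass(frozen=True)
class CMREstimate:
    """Per-batch CMR values and their mean, SD and 95% CI."""

    batch_cmrs: np.ndarray
    mean: float
    sd: float
    ci95: Tuple[float, float]
    config_summary: Dict
    censored: bool = False

    @property
    def n_batches(self) -> int:
        return int(self.batch_cmrs.size)


@dataclass(frozen=True)
class CMRProtocol:
    """Sweep design: how many batches of how many runs, the generation
    cap, and whether the fine grid is used after the coarse decade."""

    n_batches: int = 20
    batch_size: int = 100
    max_generations: int = 10_000
    use_fine_grid: bool = True
    early_advance: bool = True
    loss_threshold: float = 0.95

    @property
    def total_runs(self) -> int:
        return self.n_batches * self.batch_size

    @classmethod
    def full(cls) -> "CMRProtocol":
        """The full design: 20 batches x 100 runs, 10,000 generations."""
        return cls()

    @classmethod
    def reduced(cls) -> "CMRProtocol":
        """Desk-scale profile: 5 batches x 20 runs, 2,000 generations,
        coarse grid only."""
        return cls(n_batches=5, batch_size=20, max_generations=2_000, use_fine_grid=False)


class CMRNotFoundError(RuntimeError):
    """No swept rate reached the required loss fraction."""


def derive_run_seed(master_seed: int, batch: int, run: int) -> int:
    """Deterministic per-(batch, run) seed, shared across rates so the
    sweep uses common random numbers."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(batch, run))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def make_run_oracle(cfg: RunConfig, protocol: CMRProtocol, engine: str = "auto") -> RunOracle:
    """Wrap :func:`run_simulation` as a (rate, batch, run) -> lost oracle
    with common-random-number seeds derived from ``cfg.seed``."""

    def run_one(rate: float, batch: int, run: int) -> bool:
        rcfg = replace(
            cfg,
            reproduction=replace(cfg.reproduction, mutation_rate=rate),
            max_generations=protocol.max_generations,
            seed=derive_run_seed(cfg.seed, batch, run),
        )
        return run_simulation(rcfg, engine=engine).lost_peak0

    return run_one


def run_batch(
    rate: float,
    n_runs: int,
    cfg: RunConfig,
    seeds: Optional[Sequence[int]] = None,
    full_target: Optional[int] = None,
    loss_threshold: float = 0.95,
    engine: str = "auto",
) -> BatchResult:
    """Execute up to ``n_runs`` runs at one mutation rate.

    Runs use the given seeds (default: derived from ``cfg.seed``).  The
    rate is abandoned once keepers exceed what the loss criterion
    tolerates for ``full_target`` runs (default ``n_runs``), marking the
    result ``early_advanced``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = [derive_run_seed(cfg.seed, 0, i) for i in range(n_runs)]
    full_target = n_runs if full_target is None else full_target
    keeper_cap = max_tolerated_keepers(full_target, loss_threshold)
    lost = kept = executed = 0
    for i in range(n_runs):
        rcfg = replace(
            cfg,
            reproduction=replace(cfg.reproduction, mutation_rate=rate),
            seed=int(seeds[i]),
        )
        executed += 1
        if run_simulation(rcfg, engine=engine).lost_peak0:
            lost += 1
        else:
            kept += 1
            if kept > keeper_cap:
                return BatchResult(rate, executed, lost, early_advanced=True)
    return BatchResult(rate, executed, lost, early_advanced=False)


def coarse_sweep(
    loss_fraction_oracle: Callable[[float], float],
    grid: Optional[np.ndarray] = None,
    loss_threshold: float = 0.95,
) -> Optional[int]:
    """Ascend the coarse grid; return the decade exponent e (the CMR lies
    in [1, 10) x 10^-e) of the first rate whose loss fraction reaches the
    threshold, or ``None`` if no rate up to the grid maximum does."""
    grid = coarse_grid() if grid is None else grid
    for rate in grid:
        if loss_fraction_oracle(float(rate)) >= loss_threshold:
            return decade_of(float(rate))
    return None


def batch_cmr_sweep(
    run_one: RunOracle,
    grid: np.ndarray,
    n_batches: int,
    batch_size: int,
    loss_threshold: float = 0.95,
    early_advance: bool = True,
    full_target: Optional[int] = None,
) -> Tuple[np.ndarray, List[BatchResult]]:
    """Ascend ``grid``, recording for each batch the smallest rate at
    which at least ``loss_threshold`` of its runs lost peak 0.

    Early advance counts keepers across the batches still pending at a
    rate against the tolerance for ``full_target`` runs (default: all
    batches); once exceeded the rate is abandoned.  Returns per-batch
    CMRs (NaN where the grid was exhausted) and a per-rate log.
    """
    full_target = n_batches * batch_size if full_target is None else full_target
    keeper_cap = max_tolerated_keepers(full_target, loss_threshold)
    need_batch = _required_losses(batch_size, loss_threshold)
    cmrs = np.full(n_batches, np.nan)
    log: List[BatchResult] = []
    for rate in grid:
        rate = float(rate)
        pending = [b for b in range(n_batches) if np.isnan(cmrs[b])]
        if not pending:
            break
        keepers = lost_total = executed = 0
        aborted = False
        for b in pending:
            batch_losses = 0
            for i in range(batch_size):
                executed += 1
                if run_one(rate, b, i):
                    batch_losses += 1
                    lost_total += 1
                else:
                    keepers += 1
                    if early_advance and keepers > keeper_cap:
                        aborted = True
                        break
            if aborted:
                break
            if batch_losses >= need_batch:
                cmrs[b] = rate
        log.append(BatchResult(rate, executed, lost_total, early_advanced=aborted))
    return cmrs, log


def summarize_batches(
    batch_cmrs: np.ndarray, config_summary: Optional[Dict] = None, censored: bool = False
) -> CMREstimate:
    """Mean, SD and Student-t 95% CI over per-batch CMR values."""
    vals = np.asarray(batch_cmrs, dtype=float)
    if vals.size < 1 or np.isnan(vals).any():
        raise ValueError("batch CMR values must be complete and non-empty")
    mean = float(vals.mean())
    if vals.size == 1:
        sd, half = 0.0, 0.0
    else:
        sd = float(vals.std(ddof=1))
        half = float(stats.t.ppf(0.975, df=vals.size - 1) * sd / math.sqrt(vals.size))
    return CMREstimate(
        batch_cmrs=vals,
        mean=mean,
        sd=sd,
        ci95=(mean - half, mean + half),
        config_summary=dict(config_summary or {}),
        censored=censored,
    )


def fine_sweep(
    run_one: RunOracle,
    decade: int,
    n_batches: int = 20,
    batch_size: int = 100,
    loss_threshold: float = 0.95,
    early_advance: bool = True,
    max_escalations: int = 2,
    config_summary: Optional[Dict] = None,
) -> CMREstimate:
    """Pinpoint per-batch CMRs on the fine grid of ``decade``.

    If a batch reaches no qualifying rate within the decade, the sweep
    escalates to the next decade up (larger rates), at most
    ``max_escalations`` times; a batch still unresolved raises
    :class:`CMRNotFoundError`.
    """
    grids = [fine_grid(decade - j) for j in range(max_escalations + 1)]
    grid = np.concatenate(grids)
    cmrs, _log = batch_cmr_sweep(
        run_one,
        grid,
        n_batches,
        batch_size,
        loss_threshold=loss_threshold,
        early_advance=early_advance,
    )
    if np.isnan(cmrs).any():
        raise CMRNotFoundError(
            f"{int(np.isnan(cmrs).sum())} of {n_batches} batches reached no "
            f"95%-loss rate within decades 1e-{decade}..1e-{decade - max_escalations}"
        )
    return summarize_batches(cmrs, config_summary)


def estimate_cmr(
    cfg: RunConfig,
    protocol: CMRProtocol = CMRProtocol.full(),
    engine: str = "auto",
    config_summary: Optional[Dict] = None,
    on_unresolved: str = "raise",
) -> CMREstimate:
    """Estimate the CMR for one parameter combination.

    With the full protocol the coarse grid locates the decade (on the
    aggregated runs, with early advance) and the fine grid then yields
    the per-batch CMRs.  With ``use_fine_grid=False`` (reduced profile)
    the per-batch CMRs are read directly off the coarse grid.

    ``on_unresolved``: "raise" raises :class:`CMRNotFoundError` when a
    batch never reaches the loss criterion by the top of the grid;
    "censor" records the grid maximum for such batches and marks the
    estimate ``censored`` (the true CMR is at least the recorded value).
    """
    if on_unresolved not in ("raise", "censor"):
        raise ValueError("on_unresolved must be 'raise' or 'censor'")
    run_one = make_run_oracle(cfg, protocol, engine=engine)
    summary = dict(config_summary or {})
    summary.setdefault("population_size", cfg.population_size)
    summary.setdefault("gene_length", cfg.landscape.gene_length)
    summary.setdefault("gene_count", cfg.landscape.gene_count)
    summary.setdefault("scale", cfg.landscape.scale)
    summary.setdefault("crossovers", cfg.reproduction.crossovers_per_chromosome)
    summary.setdefault("chromosomes_per_gene", cfg.landscape.chromosomes_per_gene)
    summary.setdefault("max_generations", protocol.max_generations)
    summary.setdefault("n_batches", protocol.n_batches)
    summary.setdefault("batch_size", protocol.batch_size)

    if protocol.use_fine_grid:

        def fraction_at(rate: float) -> float:
            total = protocol.total_runs
            lost = kept = 0
            cap = max_tolerated_keepers(total, protocol.loss_threshold)
            for b in range(protocol.n_batches):
                for i in range(protocol.batch_size):
                    if run_one(rate, b, i):
                        lost += 1
                    else:
                        kept += 1
                        if protocol.early_advance and kept > cap:
                            return lost / total
            return lost / total

        decade = coarse_sweep(fraction_at, loss_threshold=protocol.loss_threshold)
        if decade is None:
            if on_unresolved == "censor":
                cmrs = np.full(protocol.n_batches, float(coarse_grid()[-1]))
                return summarize_batches(cmrs, summary, censored=True)
            raise CMRNotFoundError("no coarse rate up to 1e-2 reached the loss criterion")
        return fine_sweep(
            run_one,
            decade,
            n_batches=protocol.n_batches,
            batch_size=protocol.batch_size,
            loss_threshold=protocol.loss_threshold,
            early_advance=protocol.early_advance,
            config_summary=summary,
        )

    grid = coarse_grid()
    cmrs, _log = batch_cmr_sweep(
        run_one,
        grid,
        protocol.n_batches,
        protocol.batch_size,
        loss_threshold=protocol.loss_threshold,
        early_advance=protocol.early_advance,
    )
    censored = False
    if np.isnan(cmrs).any():
        if on_unresolved == "raise":
            raise CMRNotFoundError(
                f"{int(np.isnan(cmrs).sum())} of {protocol.n_batches} batches "
                "reached no qualifying rate on the coarse grid"
            )
        cmrs = np.where(np.isnan(cmrs), float(grid[-1]), cmrs)
        censored = True
    return summarize_batches(cmrs, summary, censored=censored)
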