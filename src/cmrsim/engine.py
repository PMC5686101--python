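"""Discrete-generation evolutionary loop.

Each generation: a uniform random permutation of the population is cut
into consecutive disjoint triples; within each triple the least fit
individual is replaced by a child of the other two with probability 0.5,
and each of the two fitter with probability 0.25 (ties in the ranking
broken uniformly at random).  The N mod 3 leftover individuals pass
through unchanged.  A run stops at the first generation at which any
gene has lost peak 0 — no individual carries a gene segment within the
peak-0 radius on either strand — or at the generation cap.

Two engines produce :class:`RunResult`: a pure-Python/numpy path built
from the op-level functions (reference semantics, supports tracing) and
a compiled numba kernel for sweeps.  Both are deterministic given the
configured seed; their streams differ, so results agree statistically
but not bitwise across engines.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import _kernels
from .landscape import LandscapeSpec, individual_fitness
from .population import (
    Individual,
    Population,
    ReproductionConfig,
    initialize_population,
    reproduce,
)

#: Rank-indexed replacement probabilities: fittest, middle, least fit.
REPLACEMENT_PROBS = (0.25, 0.25, 0.5)


@dataclass(frozen=True)
class RunConfig:
    """Everything one simulation run needs, including its seed."""

    landscape: LandscapeSpec
    reproduction: ReproductionConfig
    population_size: int
    max_generations: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        # every chromosome must offer enough internal boundaries
        L = self.landscape.gene_length
        c = self.landscape.chromosomes_per_gene
        min_block = L // c
        if self.reproduction.crossovers_per_chromosome > min_block - 1:
            raise ValueError(
                f"{self.reproduction.crossovers_per_chromosome} crossovers do not fit "
                f"in a chromosome of length {min_block}"
            )


@dataclass(frozen=True)
class RunResult:
    """Outcome of one run: whether, when and at which gene peak 0 was lost."""

    lost_peak0: bool
    loss_generation: Optional[int]
    lost_gene_index: Optional[int]
    seed: int
    generations_run: int
    engine: str


def rank_trio(fitnesses, rng: np.random.Generator) -> List[int]:
    """Indices of a trio ordered fittest first; ties broken uniformly at
    random via per-individual random keys."""
    keys = rng.random(3)
    return sorted(range(3), key=lambda i: (-fitnesses[i], keys[i]))


def choose_replaced_rank(rng: np.random.Generator) -> int:
    """Fitness rank (0 fittest) of the trio member to replace:
    P(0)=P(1)=0.25, P(2)=0.5."""
    u = rng.random()
    if u < 0.25:
        return 0
    if u < 0.5:
        return 1
    return 2


def tournament_replace(
    trio: List[Individual],
    cfg: ReproductionConfig,
    landscape: LandscapeSpec,
    rng: np.random.Generator,
    lam: Optional[float] = None,
) -> Tuple[List[Individual], int]:
    """One replication event on three individuals.

    Returns ``(new_trio, replaced_slot)``: the trio with the child in the
    replaced slot, and which slot was replaced.  The two survivors are
    the child's parents.
    """
    if len(trio) != 3:
        raise ValueError("tournament requires exactly three individuals")
    lam = cfg.dominance if lam is None else lam
    fits = [individual_fitness(ind, landscape, lam) for ind in trio]
    order = rank_trio(fits, rng)
    replaced = order[choose_replaced_rank(rng)]
    parents = [trio[i] for i in range(3) if i != replaced]
    child = reproduce(parents[0], parents[1], cfg, landscape, rng)
    out = list(trio)
    out[replaced] = child
    return out, replaced


def run_generation(pop: Population, cfg: RunConfig, rng: np.random.Generator) -> Population:
    """One discrete generation: permute, partition into trios, replace.

    Leftover individuals (N mod 3) pass through unchanged; population
    size is conserved and each individual joins at most one trio.
    """
    N = len(pop)
    members = list(pop.members)
    perm = rng.permutation(N)
    for t in range(N // 3):
        idx = perm[3 * t : 3 * t + 3]
        trio = [members[i] for i in idx]
        new_trio, _ = tournament_replace(trio, cfg.reproduction, cfg.landscape, rng)
        for slot, i in enumerate(idx):
            members[i] = new_trio[slot]
    return Population(members)


def peak0_present(pop: Population, landscape: LandscapeSpec, g: int) -> bool:
    """True iff some individual carries gene g within the peak-0 radius
    (Hamming distance strictly less than the radius) on either strand."""
    if not 0 <= g < landscape.gene_count:
        raise ValueError("gene index out of range")
    L = landscape.gene_length
    gene = landscape.genes[g]
    t0 = gene.peak0.target
    r0 = gene.peak0.radius
    seg = slice(g * L, (g + 1) * L)
    for ind in pop:
        if int(np.count_nonzero(ind.maternal[seg] != t0)) < r0:
            return True
        if int(np.count_nonzero(ind.paternal[seg] != t0)) < r0:
            return True
    return False


def _first_lost_gene(pop: Population, landscape: LandscapeSpec) -> Optional[int]:
    for g in range(landscape.gene_count):
        if not peak0_present(pop, landscape, g):
            return g
    return None


def _run_python(cfg: RunConfig, trace_path=None) -> RunResult:
    rng = np.random.default_rng(cfg.seed)
    pop = initialize_population(cfg.population_size, cfg.landscape, rng)
    writer = fh = None
    if trace_path is not None:
        fh = open(trace_path, "w", newline="")
        writer = csv.writer(fh)
        writer.writerow(
            ["generation"]
            + [f"peak0_carriers_gene{g}" for g in range(cfg.landscape.gene_count)]
            + ["mean_fitness", "max_fitness"]
        )
    try:
        for gen in range(1, cfg.max_generations + 1):
            pop = run_generation(pop, cfg, rng)
            if writer is not None:
                _write_trace_row(writer, gen, pop, cfg)
            lost = _first_lost_gene(pop, cfg.landscape)
            if lost is not None:
                return RunResult(True, gen, lost, cfg.seed, gen, "python")
        return RunResult(False, None, None, cfg.seed, cfg.max_generations, "python")
    finally:
        if fh is not None:
            fh.close()


def _write_trace_row(writer, gen: int, pop: Population, cfg: RunConfig) -> None:
    lam = cfg.reproduction.dominance
    land = cfg.landscape
    L = land.gene_length
    carriers = []
    for g, gene in enumerate(land.genes):
        seg = slice(g * L, (g + 1) * L)
        t0, r0 = gene.peak0.target, gene.peak0.radius
        count = sum(
            1
            for ind in pop
            if int(np.count_nonzero(ind.maternal[seg] != t0)) < r0
            or int(np.count_nonzero(ind.paternal[seg] != t0)) < r0
        )
        carriers.append(count)
    fits = [individual_fitness(ind, land, lam) for ind in pop]
    writer.writerow([gen] + carriers + [f"{np.mean(fits):.6g}", f"{np.max(fits):.6g}"])


def _run_compiled(cfg: RunConfig) -> RunResult:
    land = cfg.landscape
    g0 = land.genes[0]
    # the kernel assumes radii/heights uniform across genes, as built by
    # make_landscape; fall back to the reference path otherwise
    uniform = all(
        g.peak0.radius == g0.peak0.radius
        and g.peak1.radius == g0.peak1.radius
        and g.peak0.height == g0.peak0.height
        and g.peak1.height == g0.peak1.height
        and not g.peak0.target.any()
        for g in land.genes
    )
    if not uniform:
        return _run_python(cfg)
    t1 = np.ascontiguousarray(land.peak1_genome())
    kernel_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] & 0x7FFFFFFF)
    lost, gen, gene = _kernels.run_kernel(
        t1,
        land.gene_count,
        land.gene_length,
        g0.peak0.radius,
        g0.peak1.radius,
        float(g0.peak0.height),
        float(g0.peak1.height),
        float(cfg.reproduction.dominance),
        float(cfg.reproduction.mutation_rate),
        cfg.reproduction.crossovers_per_chromosome,
        land.chromosomes_per_gene,
        cfg.population_size,
        cfg.max_generations,
        kernel_seed,
    )
    if lost:
        return RunResult(True, int(gen), int(gene), cfg.seed, int(gen), "compiled")
    return RunResult(False, None, None, cfg.seed, cfg.max_generations, "compiled")


def run_simulation(cfg: RunConfig, engine: str = "auto", trace_path=None) -> RunResult:
    """Run one simulation to peak-0 loss or the generation cap.

    ``engine`` is ``"auto"`` (compiled when numba is available and no
    trace is requested), ``"compiled"`` or ``"python"``.  Results are a
    pure function of (cfg, engine).
    """
    if engine not in ("auto", "compiled", "python"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "auto":
        engine = "compiled" if (_kernels.HAVE_NUMBA and trace_path is None) else "python"
    if engine == "compiled":
        if trace_path is not None:
            raise ValueError("per-generation tracing requires the python engine")
        if not _kernels.HAVE_NUMBA:
            raise RuntimeError("numba is not available; use engine='python'")
        return _run_compiled(cfg)
    return _run_python(cfg, trace_path=trace_path)
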