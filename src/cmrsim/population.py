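"""Diploid genomes, mutation and gametogenesis.

An :class:`Individual` carries a maternal and a paternal sequence of
length n*L.  Reproduction forms one gamete from each parent by
meiosis-style recombination (per chromosome: a uniformly chosen starting
strand and k distinct crossover points), then mutates each gamete with a
binomial per-gene mutation draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence

import numpy as np

from .landscape import ALPHABET, N_SYMBOLS, LandscapeSpec, as_seq, seq_to_str

_FASTA_MAP = {0: "A", 1: "C", 2: "G", 3: "T"}
_FASTA_INV = {v: k for k, v in _FASTA_MAP.items()}


@dataclass(frozen=True)
class Individual:
    """A diploid genome: maternal and paternal sequences of equal length."""

    maternal: np.ndarray
    paternal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "maternal", as_seq(self.maternal))
        object.__setattr__(self, "paternal", as_seq(self.paternal))
        if self.maternal.size != self.paternal.size:
            raise ValueError("maternal and paternal sequences must have equal length")

    @property
    def genome_length(self) -> int:
        return int(self.maternal.size)


class Population:
    """An ordered, fixed-size collection of individuals."""

    def __init__(self, members: Sequence[Individual]):
        members = list(members)
        if len(members) < 1:
            raise ValueError("population must contain at least one individual")
        G = members[0].genome_length
        if any(m.genome_length != G for m in members):
            raise ValueError("all individuals must share genome length")
        self.members: List[Individual] = members

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, i) -> Individual:
        return self.members[i]

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.members)

    def to_array(self) -> np.ndarray:
        """Stack into a (N, 2, G) uint8 array (strand 0 maternal)."""
        N = len(self.members)
        G = self.members[0].genome_length
        out = np.empty((N, 2, G), dtype=np.uint8)
        for i, m in enumerate(self.members):
            out[i, 0] = m.maternal
            out[i, 1] = m.paternal
        return out

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "Population":
        return cls([Individual(arr[i, 0].copy(), arr[i, 1].copy()) for i in range(arr.shape[0])])


@dataclass(frozen=True)
class ReproductionConfig:
    """Per-reproduction parameters: per-base mutation probability M,
    crossovers per chromosome k, chromosomes per gene c, and the dominance
    weight lam (default just below 1 so both homologs always contribute)."""

    mutation_rate: float
    crossovers_per_chromosome: int = 1
    chromosomes_per_gene: int = 1
    dominance: float = 0.999999999999999

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.crossovers_per_chromosome < 1:
            raise ValueError("crossovers_per_chromosome must be >= 1")
        if self.chromosomes_per_gene < 1:
            raise ValueError("chromosomes_per_gene must be >= 1")
        if not 0.0 <= self.dominance <= 1.0:
            raise ValueError("dominance must lie in [0, 1]")


def initialize_population(
    N: int, landscape: LandscapeSpec, rng: np.random.Generator
) -> Population:
    """Half the population on top of peak 0, half on top of peak 1.

    ceil(N/2) individuals start homozygous on the concatenated peak-0
    targets (the extra individual of an odd N goes to the fitter peak),
    floor(N/2) on the peak-1 targets; the order is shuffled.
    """
    if N < 1:
        raise ValueError("population size must be >= 1")
    g0 = landscape.peak0_genome()
    g1 = landscape.peak1_genome()
    n0 = math.ceil(N / 2)
    members = [Individual(g0.copy(), g0.copy()) for _ in range(n0)]
    members += [Individual(g1.copy(), g1.copy()) for _ in range(N - n0)]
    order = rng.permutation(N)
    return Population([members[i] for i in order])


def mutate(seq, M: float, rng: np.random.Generator) -> np.ndarray:
    """Binomial mutation of one sequence.

    Draws K ~ Binomial(len(seq), M), samples K distinct positions
    uniformly, and sets each to one of the three other symbols with equal
    probability, so exactly K positions differ from the input.
    """
    seq = as_seq(seq)
    if not 0.0 <= M <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    out = seq.copy()
    K = int(rng.binomial(seq.size, M))
    if K == 0:
        return out
    pos = rng.choice(seq.size, size=K, replace=False)
    out[pos] = (out[pos] + rng.integers(1, N_SYMBOLS, size=K, dtype=np.uint8)) % N_SYMBOLS
    return out


def make_gamete(
    parent: Individual,
    landscape: LandscapeSpec,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombine a parent's two strands into one gamete.

    Each of the n*c chromosomes independently picks a uniform starting
    strand and k distinct crossover points among its internal boundaries
    (between adjacent bases, half-open 0-based convention); the copied
    strand alternates at each point.  Every output position equals the
    corresponding position of one parental strand.
    """
    spans = landscape.chromosome_spans()
    out = np.empty(parent.genome_length, dtype=np.uint8)
    strands = (parent.maternal, parent.paternal)
    for start, end in spans:
        Lc = end - start
        n_boundaries = Lc - 1
        if k > n_boundaries:
            raise ValueError(
                f"{k} crossovers requested but chromosome of length {Lc} has "
                f"only {n_boundaries} internal boundaries"
            )
        s = int(rng.integers(0, 2))
        points = np.sort(rng.choice(n_boundaries, size=k, replace=False)) + 1
        prev = 0
        for p in list(points) + [Lc]:
            out[start + prev : start + p] = strands[s][start + prev : start + p]
            s = 1 - s
            prev = p
    return out


def reproduce(
    parent_a: Individual,
    parent_b: Individual,
    cfg: ReproductionConfig,
    landscape: LandscapeSpec,
    rng: np.random.Generator,
) -> Individual:
    """Produce a child: one mutated gamete from each parent.

    The child's maternal strand is a gamete of ``parent_a``, the paternal
    strand a gamete of ``parent_b``; each strand is then mutated gene by
    gene (an independent Binomial(L, M) draw per gene segment).
    """
    L = landscape.gene_length
    k = cfg.crossovers_per_chromosome
    strands = []
    for parent in (parent_a, parent_b):
        g = make_gamete(parent, landscape, k, rng)
        for i in range(landscape.gene_count):
            seg = slice(i * L, (i + 1) * L)
            g[seg] = mutate(g[seg], cfg.mutation_rate, rng)
        strands.append(g)
    return Individual(strands[0], strands[1])


# ---------------------------------------------------------------------------
# FASTA round trip (symbols 0,1,2,3 <-> A,C,G,T)

def population_to_fasta(pop: Population, path) -> None:
    """Write 2N records; IDs encode individual index and strand, e.g.
    ``ind0007/maternal``."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, ind in enumerate(pop):
        for strand_name, seq in (("maternal", ind.maternal), ("paternal", ind.paternal)):
            letters = "".join(_FASTA_MAP[int(b)] for b in seq)
            records.append(
                SeqRecord(Seq(letters), id=f"ind{i:05d}/{strand_name}", description="")
            )
    seqio_write(records, str(path), "fasta")


def population_from_fasta(path) -> Population:
    """Invert :func:`population_to_fasta` losslessly."""
    from Bio.SeqIO import parse as seqio_parse

    strands = {}
    for rec in seqio_parse(str(path), "fasta"):
        name, strand = rec.id.split("/")
        idx = int(name[3:])
        arr = np.array([_FASTA_INV[ch] for ch in str(rec.seq)], dtype=np.uint8)
        strands[(idx, strand)] = arr
    n = 1 + max(i for i, _ in strands)
    return Population(
        [Individual(strands[(i, "maternal")], strands[(i, "paternal")]) for i in range(n)]
    )
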