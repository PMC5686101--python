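"""Two-peak fitness landscapes on Hamming space.

Each gene carries a pair of target sequences over a 4-letter alphabet:
peak 0 is narrow and high (the fitter allele class), peak 1 is broad and
low (the more mutationally robust allele class).  Fitness of a sequence
with respect to a peak decays linearly with Hamming distance from the
peak's target, reaching zero at the peak radius; outside both radii the
landscape is neutral (fitness 0).  A diploid individual's per-gene
fitness combines the fitter and less fit homolog through the dominance
weight ``lam`` (f = lam*f_max + (1-lam)*f_min), and the individual's
overall fitness is the minimum over its genes — a conservative epistasis
that makes every gene essential.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

#: The simulation alphabet.  Symbol i is written as the character str(i);
#: FASTA export maps 0,1,2,3 -> A,C,G,T.
ALPHABET = "0123"
N_SYMBOLS = 4

SequenceLike = Union[str, Sequence[int], np.ndarray]


def as_seq(x: SequenceLike) -> np.ndarray:
    """Coerce a '0123' string or integer sequence to a uint8 array.

    Raises ``ValueError`` for symbols outside the 4-letter alphabet.
    """
    if isinstance(x, str):
        arr = np.frombuffer(x.encode("ascii"), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(x, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("sequences must be one-dimensional")
    if arr.size and int(arr.max()) >= N_SYMBOLS:
        raise ValueError("sequence contains symbols outside the alphabet 0..3")
    return arr


def seq_to_str(seq: np.ndarray) -> str:
    """Render a uint8 sequence as a '0123' string."""
    return "".join(ALPHABET[int(b)] for b in seq)


def hamming(a: SequenceLike, b: SequenceLike) -> int:
    """Hamming distance between two equal-length sequences."""
    a = as_seq(a)
    b = as_seq(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return int(np.count_nonzero(a != b))


@dataclass(frozen=True)
class PeakSpec:
    """One fitness peak: a target sequence, an apex height and a radius.

    The radius is the Hamming distance from the target at which fitness
    reaches zero; positions strictly inside the radius have positive
    fitness.
    """

    target: np.ndarray
    height: float
    radius: int

    def __post_init__(self):
        object.__setattr__(self, "target", as_seq(self.target))
        if not self.height > 0:
            raise ValueError("peak height must be positive")
        if self.radius < 1:
            raise ValueError("peak radius must be >= 1")

    @property
    def length(self) -> int:
        return int(self.target.size)


@dataclass(frozen=True)
class GeneLandscape:
    """The two-peak landscape of a single gene.

    The peaks must not meet or overlap: the inter-peak Hamming distance
    must strictly exceed the sum of the radii, so a positive-fitness tie
    between the peaks is impossible.
    """

    peak0: PeakSpec
    peak1: PeakSpec
    gene_length: int

    def __post_init__(self):
        if self.peak0.length != self.gene_length or self.peak1.length != self.gene_length:
            raise ValueError("peak targets must have length equal to gene_length")
        d = hamming(self.peak0.target, self.peak1.target)
        if d <= self.peak0.radius + self.peak1.radius:
            raise ValueError(
                f"peaks meet or overlap: distance {d} <= combined radii "
                f"{self.peak0.radius + self.peak1.radius}"
            )

    @property
    def distance(self) -> int:
        """Hamming distance between the two peak targets."""
        return hamming(self.peak0.target, self.peak1.target)


@dataclass(frozen=True)
class LandscapeSpec:
    """Global landscape geometry: n genes of length L, scaled by S.

    Every gene has peak radii S*r0 and S*r1 and inter-peak distance S*D.
    ``chromosomes_per_gene`` partitions each gene into contiguous blocks
    for recombination (last block absorbs any length remainder).
    """

    genes: Tuple[GeneLandscape, ...]
    gene_length: int
    scale: int
    chromosomes_per_gene: int
    base_radii: Tuple[int, int]
    base_distance: int

    def __post_init__(self):
        if len(self.genes) < 1:
            raise ValueError("need at least one gene")
        if self.gene_length < 1:
            raise ValueError("gene_length must be >= 1")
        if self.scale < 1 or int(self.scale) != self.scale:
            raise ValueError("scale S must be an integer >= 1")
        if self.chromosomes_per_gene < 1:
            raise ValueError("chromosomes_per_gene must be >= 1")
        if self.chromosomes_per_gene > self.gene_length:
            raise ValueError("more chromosomes than bases in a gene")
        r0, r1 = self.base_radii
        for g in self.genes:
            if g.gene_length != self.gene_length:
                raise ValueError("all genes must share gene_length")
            if g.peak0.radius != self.scale * r0 or g.peak1.radius != self.scale * r1:
                raise ValueError("gene radii inconsistent with S*(r0, r1)")
            if g.distance != self.scale * self.base_distance:
                raise ValueError("gene peak distance inconsistent with S*D")

    @property
    def gene_count(self) -> int:
        return len(self.genes)

    @property
    def genome_length(self) -> int:
        return self.gene_count * self.gene_length

    def peak0_genome(self) -> np.ndarray:
        """Concatenated peak-0 targets across genes."""
        return np.concatenate([g.peak0.target for g in self.genes])

    def peak1_genome(self) -> np.ndarray:
        """Concatenated peak-1 targets across genes."""
        return np.concatenate([g.peak1.target for g in self.genes])

    def chromosome_spans(self) -> Tuple[Tuple[int, int], ...]:
        """Half-open (start, end) spans of every chromosome in genome
        coordinates: c contiguous equal blocks per gene, the last block of
        each gene absorbing the remainder."""
        L, c = self.gene_length, self.chromosomes_per_gene
        block = L // c
        spans = []
        for g in range(self.gene_count):
            off = g * L
            for b in range(c):
                start = off + b * block
                end = off + ((b + 1) * block if b < c - 1 else L)
                spans.append((start, end))
        return tuple(spans)


def make_landscape(
    n: int,
    L: int,
    r0: int = 2,
    r1: int = 5,
    D: int = 10,
    S: int = 1,
    h0: float = 15.0,
    h1: float = 10.0,
    c: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> LandscapeSpec:
    """Build an n-gene two-peak landscape.

    Each gene's peak-0 target is the all-"0" sequence; its peak-1 target
    is drawn independently per gene at exactly S*D uniformly chosen
    positions, each set to one of the three non-"0" symbols uniformly.

    Raises ``ValueError`` when the scaled peaks would meet or overlap
    (S*D <= S*(r0+r1)), when the distance is unachievable (S*D > L), or
    when h0 <= h1.
    """
    rng = np.random.default_rng() if rng is None else rng
    sd, sr0, sr1 = S * D, S * r0, S * r1
    if sd <= sr0 + sr1:
        raise ValueError(f"peaks meet or overlap: S*D={sd} <= S*(r0+r1)={sr0 + sr1}")
    if sd > L:
        raise ValueError(f"inter-peak distance S*D={sd} exceeds gene length {L}")
    if not h0 > h1:
        raise ValueError("peak 0 must be strictly higher than peak 1 (h0 > h1)")
    genes = []
    for _ in range(n):
        t0 = np.zeros(L, dtype=np.uint8)
        t1 = np.zeros(L, dtype=np.uint8)
        pos = rng.choice(L, size=sd, replace=False)
        t1[pos] = rng.integers(1, N_SYMBOLS, size=sd, dtype=np.uint8)
        genes.append(
            GeneLandscape(
                peak0=PeakSpec(t0, height=h0, radius=sr0),
                peak1=PeakSpec(t1, height=h1, radius=sr1),
                gene_length=L,
            )
        )
    return LandscapeSpec(
        genes=tuple(genes),
        gene_length=L,
        scale=S,
        chromosomes_per_gene=c,
        base_radii=(r0, r1),
        base_distance=D,
    )


def peak_fitness(d: int, peak: PeakSpec) -> float:
    """Fitness contribution of one peak at Hamming distance d: linear
    decay from ``height`` at d=0 to 0 at d=radius, 0 beyond."""
    if d >= peak.radius:
        return 0.0
    return peak.height * (1.0 - d / peak.radius)


def sequence_fitness(seq: SequenceLike, gene: GeneLandscape) -> Tuple[float, Optional[int]]:
    """Fitness of a single (haploid) gene sequence and which peak supplied it.

    Returns ``(fitness, peak_id)`` with peak_id 0 or 1, or ``None`` when the
    sequence lies outside both radii (both contributions zero).  A
    positive-fitness tie is impossible because the peaks cannot overlap.
    """
    seq = as_seq(seq)
    if seq.size != gene.gene_length:
        raise ValueError(f"sequence length {seq.size} != gene length {gene.gene_length}")
    f0 = peak_fitness(int(np.count_nonzero(seq != gene.peak0.target)), gene.peak0)
    f1 = peak_fitness(int(np.count_nonzero(seq != gene.peak1.target)), gene.peak1)
    if f0 == 0.0 and f1 == 0.0:
        return 0.0, None
    if f0 >= f1:
        return f0, 0
    return f1, 1


def gene_fitness(
    maternal: SequenceLike, paternal: SequenceLike, gene: GeneLandscape, lam: float
) -> float:
    """Diploid per-gene fitness: lam*f_max + (1-lam)*f_min over the two
    homologous sequences, in double precision."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("dominance weight lam must lie in [0, 1]")
    fm, _ = sequence_fitness(maternal, gene)
    fp, _ = sequence_fitness(paternal, gene)
    f_max, f_min = (fm, fp) if fm >= fp else (fp, fm)
    return lam * f_max + (1.0 - lam) * f_min


def individual_fitness(ind, landscape: LandscapeSpec, lam: float) -> float:
    """Overall fitness of a diploid individual: the minimum of its n
    per-gene fitnesses (every gene is essential)."""
    L = landscape.gene_length
    best = np.inf
    for g, gene in enumerate(landscape.genes):
        seg = slice(g * L, (g + 1) * L)
        f = gene_fitness(ind.maternal[seg], ind.paternal[seg], gene, lam)
        if f < best:
            best = f
    return float(best)


@dataclass(frozen=True)
class FootprintStats:
    """How much of a gene the two peaks occupy (counting 2*radius per peak,
    plus the inter-peak distance for the full footprint)."""

    peaks_fraction: float
    footprint_fraction: float
    neutral_gap: int
    combined_radii: int


def footprint_stats(r0: int, r1: int, D: int, S: int = 1, L: int = 1000) -> FootprintStats:
    """Landscape footprint arithmetic at scale S on a gene of length L.

    combined_radii = S*(r0+r1); neutral_gap = S*D - S*(r0+r1);
    peaks_fraction = (2*S*r0 + 2*S*r1)/L;
    footprint_fraction = (2*S*r0 + 2*S*r1 + S*D)/L.
    Each peak is counted as spanning two radii (either side of its apex).
    """
    combined = S * (r0 + r1)
    gap = S * D - combined
    peaks = (2 * S * r0 + 2 * S * r1) / L
    footprint = (2 * S * r0 + 2 * S * r1 + S * D) / L
    return FootprintStats(
        peaks_fraction=peaks,
        footprint_fraction=footprint,
        neutral_gap=gap,
        combined_radii=combined,
    )


# ---------------------------------------------------------------------------
# serialization — targets stored as '0123' strings for exact reproducibility

def landscape_to_dict(spec: LandscapeSpec) -> dict:
    return {
        "gene_length": spec.gene_length,
        "scale": spec.scale,
        "chromosomes_per_gene": spec.chromosomes_per_gene,
        "base_radii": list(spec.base_radii),
        "base_distance": spec.base_distance,
        "genes": [
            {
                "peak0": {
                    "target": seq_to_str(g.peak0.target),
                    "height": g.peak0.height,
                    "radius": g.peak0.radius,
                },
                "peak1": {
                    "target": seq_to_str(g.peak1.target),
                    "height": g.peak1.height,
                    "radius": g.peak1.radius,
                },
            }
            for g in spec.genes
        ],
    }


def landscape_from_dict(d: dict) -> LandscapeSpec:
    genes = tuple(
        GeneLandscape(
            peak0=PeakSpec(
                as_seq(g["peak0"]["target"]),
                height=g["peak0"]["height"],
                radius=g["peak0"]["radius"],
            ),
            peak1=PeakSpec(
                as_seq(g["peak1"]["target"]),
                height=g["peak1"]["height"],
                radius=g["peak1"]["radius"],
            ),
            gene_length=d["gene_length"],
        )
        for g in d["genes"]
    )
    return LandscapeSpec(
        genes=genes,
        gene_length=d["gene_length"],
        scale=d["scale"],
        chromosomes_per_gene=d["chromosomes_per_gene"],
        base_radii=tuple(d["base_radii"]),
        base_distance=d["base_distance"],
    )


def save_landscape(spec: LandscapeSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(landscape_to_dict(spec), fh, indent=1)


def load_landscape(path) -> LandscapeSpec:
    with open(path) as fh:
        return landscape_from_dict(json.load(fh))
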