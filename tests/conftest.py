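"""Shared fixtures and independent oracles.

The brute-force fitness helpers here deliberately avoid the package's
vectorized code paths: they walk sequences symbol by symbol so the main
implementation can be checked against an independent evaluation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from cmrsim.landscape import GeneLandscape, PeakSpec, make_landscape

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def canonical_landscape(rng):
    """The canonical single-gene setting: L=1000, r0=2, r1=5, D=10."""
    return make_landscape(n=1, L=1000, r0=2, r1=5, D=10, S=1, rng=rng)


@pytest.fixture
def tiny_landscape(rng):
    """Smallest convenient landscape for op-level tests: L=30."""
    return make_landscape(n=1, L=30, r0=2, r1=5, D=10, S=1, rng=rng)


# ---------------------------------------------------------------------------
# independent brute-force oracles

def brute_hamming(a, b) -> int:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y)


def brute_peak_fitness(d: int, height: float, radius: int) -> float:
    if d >= radius:
        return 0.0
    return height * (1.0 - d / radius)


def brute_sequence_fitness(seq, gene: GeneLandscape):
    f0 = brute_peak_fitness(
        brute_hamming(list(seq), list(gene.peak0.target)), gene.peak0.height, gene.peak0.radius
    )
    f1 = brute_peak_fitness(
        brute_hamming(list(seq), list(gene.peak1.target)), gene.peak1.height, gene.peak1.radius
    )
    if f0 == 0.0 and f1 == 0.0:
        return 0.0, None
    return (f0, 0) if f0 >= f1 else (f1, 1)


def brute_gene_fitness(maternal, paternal, gene: GeneLandscape, lam: float) -> float:
    fm = brute_sequence_fitness(maternal, gene)[0]
    fp = brute_sequence_fitness(paternal, gene)[0]
    hi, lo = max(fm, fp), min(fm, fp)
    return lam * hi + (1.0 - lam) * lo


def random_gene_landscape(L: int, r0: int, r1: int, D: int, rng) -> GeneLandscape:
    """A gene landscape with a *random* (not all-zero) peak-0 target, for
    enumeration tests over randomized peak placements."""
    t0 = rng.integers(0, 4, size=L, dtype=np.uint8)
    t1 = t0.copy()
    pos = rng.choice(L, size=D, replace=False)
    t1[pos] = (t1[pos] + rng.integers(1, 4, size=D, dtype=np.uint8)) % 4
    return GeneLandscape(
        peak0=PeakSpec(t0, height=15.0, radius=r0),
        peak1=PeakSpec(t1, height=10.0, radius=r1),
        gene_length=L,
    )
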