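"""Landscape construction, fitness evaluation and footprint arithmetic."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmrsim.landscape import (
    GeneLandscape,
    PeakSpec,
    as_seq,
    footprint_stats,
    gene_fitness,
    hamming,
    individual_fitness,
    landscape_from_dict,
    landscape_to_dict,
    load_landscape,
    make_landscape,
    peak_fitness,
    save_landscape,
    seq_to_str,
    sequence_fitness,
)
from cmrsim.population import Individual

from conftest import brute_gene_fitness, brute_sequence_fitness, random_gene_landscape

LAMBDA = 0.999999999999999


class TestMakeLandscape:
    def test_canonical_geometry(self, rng):
        spec = make_landscape(n=1, L=1000, r0=2, r1=5, D=10, S=1, h0=15, h1=10, rng=rng)
        gene = spec.genes[0]
        assert gene.distance == 10
        assert (gene.peak0.radius, gene.peak1.radius) == (2, 5)
        assert (gene.peak0.height, gene.peak1.height) == (15, 10)
        assert not gene.peak0.target.any()  # all-"0" target

    def test_scaled_geometry(self, rng):
        spec = make_landscape(n=1, L=1000, r0=2, r1=5, D=10, S=10, rng=rng)
        gene = spec.genes[0]
        assert gene.distance == 100
        assert (gene.peak0.radius, gene.peak1.radius) == (20, 50)

    def test_genes_are_independent(self, rng):
        spec = make_landscape(n=4, L=30, r0=2, r1=5, D=10, S=1, rng=rng)
        assert spec.gene_count == 4
        for gene in spec.genes:
            assert gene.distance == 10
        targets = [seq_to_str(g.peak1.target) for g in spec.genes]
        assert len(set(targets)) == 4  # generally distinct under this seed

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=1, L=1000, r0=2, r1=5, D=7, S=1),   # D == r0+r1: peaks meet
            dict(n=1, L=1000, r0=3, r1=5, D=7, S=2),   # overlap after scaling
            dict(n=1, L=50, r0=2, r1=5, D=10, S=10),   # S*D > L
            dict(n=1, L=1000, r0=2, r1=5, D=10, S=1, h0=10, h1=10),  # h0 <= h1
        ],
    )
    def test_rejects_invalid_geometry(self, kwargs, rng):
        with pytest.raises(ValueError):
            make_landscape(rng=rng, **kwargs)

    def test_differing_positions_uniform(self):
        # each position selected as differing with frequency S*D/L
        reps, L, D = 10_000, 40, 10
        rng = np.random.default_rng(777)
        counts = np.zeros(L)
        for _ in range(reps):
            spec = make_landscape(n=1, L=L, r0=2, r1=5, D=D, S=1, rng=rng)
            counts += spec.genes[0].peak1.target != 0
        p = D / L
        se = np.sqrt(p * (1 - p) / reps)
        freqs = counts / reps
        # overall frequency to 3 SE; per-position with a family-wise
        # (Bonferroni-style) 4 SE bound across the L simultaneous checks
        assert abs(freqs.mean() - p) < 3 * se / np.sqrt(L)
        assert np.all(np.abs(freqs - p) < 4 * se)


class TestPeakFitness:
    def test_apex_zero_point_and_linear_midpoint(self):
        peak = PeakSpec(np.zeros(10, np.uint8), height=15.0, radius=2)
        assert peak_fitness(0, peak) == 15.0
        assert peak_fitness(2, peak) == 0.0  # the radius is the zero point
        assert peak_fitness(1, peak) == 7.5
        assert peak_fitness(7, peak) == 0.0

    @given(d=st.integers(0, 60), radius=st.integers(1, 50), height=st.floats(0.1, 100))
    @settings(deadline=None)
    def test_bounded_and_nonincreasing(self, d, radius, height):
        peak = PeakSpec(np.zeros(5, np.uint8), height=height, radius=radius)
        f = peak_fitness(d, peak)
        assert 0.0 <= f <= height
        assert peak_fitness(d + 1, peak) <= f


class TestSequenceFitness:
    def test_on_peak_tops(self, tiny_landscape):
        gene = tiny_landscape.genes[0]
        assert sequence_fitness(gene.peak0.target, gene) == (15.0, 0)
        assert sequence_fitness(gene.peak1.target, gene) == (10.0, 1)

    def test_off_both_peaks_is_neutral(self, tiny_landscape):
        gene = tiny_landscape.genes[0]
        seq = np.full(30, 3, np.uint8)  # far from all-0s and from t1
        d0 = hamming(seq, gene.peak0.target)
        d1 = hamming(seq, gene.peak1.target)
        assert d0 >= gene.peak0.radius and d1 >= gene.peak1.radius
        assert sequence_fitness(seq, gene) == (0.0, None)

    def test_one_step_off_peak1(self, tiny_landscape):
        gene = tiny_landscape.genes[0]
        seq = gene.peak1.target.copy()
        # move one step towards peak 0 (revert one differing position)
        pos = int(np.nonzero(seq != gene.peak0.target)[0][0])
        seq[pos] = gene.peak0.target[pos]
        f, which = sequence_fitness(seq, gene)
        assert which == 1
        assert f == pytest.approx(10.0 * (1 - 1 / 5))  # = 8

    def test_length_mismatch(self, tiny_landscape):
        with pytest.raises(ValueError):
            sequence_fitness(np.zeros(7, np.uint8), tiny_landscape.genes[0])

    def test_within_radius_selects_that_peak(self, rng):
        # non-overlap forces the other peak's contribution to zero there
        gene = random_gene_landscape(L=12, r0=2, r1=3, D=8, rng=rng)
        for peak, which in ((gene.peak0, 0), (gene.peak1, 1)):
            for d in range(peak.radius):
                seq = peak.target.copy()
                pos = rng.choice(12, size=d, replace=False)
                seq[pos] = (seq[pos] + rng.integers(1, 4, size=d)) % 4
                if hamming(seq, peak.target) == d:  # mutation may hit t0/t1 overlap
                    assert sequence_fitness(seq, gene)[1] == which


class TestGeneAndIndividualFitness:
    def test_dominance_weighting_of_heterozygote(self, tiny_landscape):
        gene = tiny_landscape.genes[0]
        f = gene_fitness(gene.peak0.target, gene.peak1.target, gene, LAMBDA)
        expected = LAMBDA * 15.0 + (1.0 - LAMBDA) * 10.0  # 15 - 5e-15
        assert f == expected
        assert f < 15.0

    def test_equal_values_and_full_dominance(self, tiny_landscape):
        gene = tiny_landscape.genes[0]
        t1 = gene.peak1.target
        assert gene_fitness(t1, t1, gene, 0.37) == 10.0
        assert gene_fitness(gene.peak0.target, t1, gene, 1.0) == 15.0

    @given(lam=st.floats(0, 1))
    @settings(deadline=None, max_examples=25)
    def test_convex_combination_bounds(self, lam):
        rng = np.random.default_rng(5)
        gene = random_gene_landscape(L=10, r0=2, r1=3, D=7, rng=rng)
        m = rng.integers(0, 4, 10, dtype=np.uint8)
        p = rng.integers(0, 4, 10, dtype=np.uint8)
        fm = brute_sequence_fitness(m, gene)[0]
        fp = brute_sequence_fitness(p, gene)[0]
        f = gene_fitness(m, p, gene, lam)
        assert min(fm, fp) - 1e-12 <= f <= max(fm, fp) + 1e-12

    def test_min_over_genes(self, rng):
        spec = make_landscape(n=3, L=20, r0=2, r1=5, D=10, rng=rng)
        g0 = spec.peak0_genome()
        # genes 0,1 on peak-0 top; gene 2 pushed outside both radii
        m = g0.copy()
        m[2 * 20 :] = 3
        ind = Individual(m, m)
        assert individual_fitness(ind, spec, LAMBDA) == 0.0
        ind0 = Individual(g0.copy(), g0.copy())
        assert individual_fitness(ind0, spec, LAMBDA) == 15.0

    def test_all_on_peak1_tops(self, rng):
        spec = make_landscape(n=2, L=20, r0=2, r1=5, D=10, rng=rng)
        g1 = spec.peak1_genome()
        ind = Individual(g1.copy(), g1.copy())
        assert individual_fitness(ind, spec, LAMBDA) == 10.0

    def test_single_gene_equals_gene_fitness(self, tiny_landscape):
        gene = tiny_landscape.genes[0]
        ind = Individual(gene.peak0.target.copy(), gene.peak1.target.copy())
        assert individual_fitness(ind, tiny_landscape, LAMBDA) == gene_fitness(
            ind.maternal, ind.paternal, gene, LAMBDA
        )


class TestBruteForceEquivalence:
    """The implementation must agree with an independent evaluator at
    every point of the sequence space (small L, exhaustive)."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        L = 4
        gene = random_gene_landscape(L=L, r0=1, r1=1, D=3, rng=rng)
        for tup in itertools.product(range(4), repeat=L):
            seq = np.array(tup, dtype=np.uint8)
            assert sequence_fitness(seq, gene) == brute_sequence_fitness(seq, gene)


class TestFootprint:
    def test_canonical_and_scaled_percentages(self):
        s1 = footprint_stats(r0=2, r1=5, D=10, S=1, L=1000)
        assert s1.footprint_fraction * 100 == pytest.approx(2.4)
        assert s1.peaks_fraction * 100 == pytest.approx(1.4)
        assert s1.combined_radii == 7
        assert s1.neutral_gap == 3
        s2 = footprint_stats(r0=2, r1=5, D=10, S=2, L=1000)
        assert s2.footprint_fraction * 100 == pytest.approx(4.8)
        assert s2.peaks_fraction * 100 == pytest.approx(2.8)

    def test_zero_radii(self):
        s = footprint_stats(r0=0, r1=0, D=10, S=1, L=1000)
        assert s.peaks_fraction == 0.0
        assert s.footprint_fraction * 100 == pytest.approx(1.0)
        assert s.neutral_gap == 10


class TestSerialization:
    def test_roundtrip(self, rng, tmp_path):
        spec = make_landscape(n=2, L=25, r0=2, r1=5, D=10, S=2, c=3, rng=rng)
        path = tmp_path / "landscape.json"
        save_landscape(spec, path)
        loaded = load_landscape(path)
        assert landscape_to_dict(loaded) == landscape_to_dict(spec)
        # text format: targets stored as 0123 strings
        raw = json.loads(path.read_text())
        assert set(raw["genes"][0]["peak1"]["target"]) <= set("0123")

    def test_dict_roundtrip(self, tiny_landscape):
        d = landscape_to_dict(tiny_landscape)
        assert landscape_to_dict(landscape_from_dict(d)) == d


class TestSequenceHelpers:
    def test_string_array_coercion(self):
        assert np.array_equal(as_seq("0123"), np.array([0, 1, 2, 3], np.uint8))
        assert seq_to_str(as_seq("3210")) == "3210"
        with pytest.raises(ValueError):
            as_seq("0124")

    def test_hamming_counts_differences(self):
        assert hamming("0000", "0123") == 3
        with pytest.raises(ValueError):
            hamming("00", "000")
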