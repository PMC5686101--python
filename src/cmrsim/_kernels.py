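"""Compiled inner loop for whole simulation runs.

Implements the same algorithm as the op-level path in ``engine``/
``population`` (initialization, binomial mutation, per-chromosome
crossover, triple-tournament replacement, min-over-genes fitness with
dominance, per-generation peak-0 loss check) as a single numba kernel,
so that mutation-rate sweeps over thousands of runs stay fast.  The two
paths are stochastically equivalent but draw from different RNG streams.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _sample_distinct(m, k, buf):
    # Partial Fisher-Yates: after the call buf[0:k] holds k distinct
    # uniform draws from 0..m-1.  buf must have length >= m.
    for i in range(m):
        buf[i] = i
    for i in range(k):
        j = i + np.random.randint(0, m - i)
        tmp = buf[i]
        buf[i] = buf[j]
        buf[j] = tmp


@njit(cache=True)
def _gamete(mat, pat, out, n, L, c, k, buf):
    # One gamete from strands mat/pat: per chromosome, uniform start
    # strand and k distinct sorted crossover boundaries.
    block = L // c
    for g in range(n):
        gstart = g * L
        for b in range(c):
            cs = gstart + b * block
            if b < c - 1:
                ce = gstart + (b + 1) * block
            else:
                ce = gstart + L
            Lc = ce - cs
            strand = np.random.randint(0, 2)
            _sample_distinct(Lc - 1, k, buf)
            # insertion sort of the k chosen boundaries
            for i in range(1, k):
                key = buf[i]
                j = i - 1
                while j >= 0 and buf[j] > key:
                    buf[j + 1] = buf[j]
                    j -= 1
                buf[j + 1] = key
            p = 0
            for pos in range(Lc):
                if p < k and pos == buf[p] + 1:
                    strand = 1 - strand
                    p += 1
                if strand == 0:
                    out[cs + pos] = mat[cs + pos]
                else:
                    out[cs + pos] = pat[cs + pos]


@njit(cache=True)
def _mutate_gene(strand, start, L, M, buf):
    K = np.random.binomial(L, M)
    if K == 0:
        return
    _sample_distinct(L, K, buf)
    for i in range(K):
        pos = start + buf[i]
        strand[pos] = (strand[pos] + 1 + np.random.randint(0, 3)) % 4


@njit(cache=True)
def _peak_fit(d, r, h):
    if d >= r:
        return 0.0
    return h * (1.0 - d / r)


@njit(cache=True)
def _ind_fitness(d0_row, d1_row, n, r0, r1, h0, h1, lam):
    best = np.inf
    for g in range(n):
        fm = max(_peak_fit(d0_row[0, g], r0, h0), _peak_fit(d1_row[0, g], r1, h1))
        fp = max(_peak_fit(d0_row[1, g], r0, h0), _peak_fit(d1_row[1, g], r1, h1))
        if fm >= fp:
            fg = lam * fm + (1.0 - lam) * fp
        else:
            fg = lam * fp + (1.0 - lam) * fm
        if fg < best:
            best = fg
    return best


@njit(cache=True)
def _distances(seq, t1, n, L, d0_row, d1_row):
    for s in range(2):
        for g in range(n):
            c0 = 0
            c1 = 0
            off = g * L
            for p in range(L):
                v = seq[s, off + p]
                if v != 0:
                    c0 += 1
                if v != t1[off + p]:
                    c1 += 1
            d0_row[s, g] = c0
            d1_row[s, g] = c1


@njit(cache=True)
def run_kernel(t1, n, L, r0, r1, h0, h1, lam, M, k, c, N, max_gen, seed):
    """Simulate one run; returns (lost, loss_generation, lost_gene).

    t1: flat (n*L,) uint8 concatenated peak-1 targets (peak-0 targets are
    all zeros).  r0/r1 are the scaled radii shared by all genes.  Returns
    lost=0 with generation=max_gen and gene=-1 when peak 0 survives.
    """
    np.random.seed(seed)
    G = n * L
    seqs = np.zeros((N, 2, G), np.uint8)
    n0 = (N + 1) // 2
    # shuffled assignment of starting peaks
    order = np.empty(N, np.int64)
    for i in range(N):
        order[i] = i
    for i in range(N - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp
    for ii in range(n0, N):
        i = order[ii]
        for s in range(2):
            for p in range(G):
                seqs[i, s, p] = t1[p]

    d0 = np.zeros((N, 2, n), np.int64)
    d1 = np.zeros((N, 2, n), np.int64)
    fit = np.empty(N, np.float64)
    for i in range(N):
        _distances(seqs[i], t1, n, L, d0[i], d1[i])
        fit[i] = _ind_fitness(d0[i], d1[i], n, r0, r1, h0, h1, lam)

    child = np.empty((2, G), np.uint8)
    buf = np.empty(max(G, L), np.int64)
    perm = np.empty(N, np.int64)
    for i in range(N):
        perm[i] = i
    trio = np.empty(3, np.int64)
    keys = np.empty(3, np.float64)
    order3 = np.empty(3, np.int64)

    for gen in range(1, max_gen + 1):
        # fresh uniform permutation (Fisher-Yates over previous contents)
        for i in range(N - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = perm[i]
            perm[i] = perm[j]
            perm[j] = tmp
        for t in range(N // 3):
            for j in range(3):
                trio[j] = perm[3 * t + j]
                keys[j] = np.random.random()
            # rank the trio: fittest first, ties broken by random key
            for j in range(3):
                order3[j] = j
            for a in range(1, 3):
                key_j = order3[a]
                b = a - 1
                while b >= 0 and (
                    fit[trio[order3[b]]] < fit[trio[key_j]]
                    or (
                        fit[trio[order3[b]]] == fit[trio[key_j]]
                        and keys[order3[b]] > keys[key_j]
                    )
                ):
                    order3[b + 1] = order3[b]
                    b -= 1
                order3[b + 1] = key_j
            u = np.random.random()
            if u < 0.25:
                repl_slot = order3[0]
            elif u < 0.5:
                repl_slot = order3[1]
            else:
                repl_slot = order3[2]
            repl = trio[repl_slot]
            # parents: the two survivors, in trio order
            pa = -1
            pb = -1
            for j in range(3):
                if j != repl_slot:
                    if pa < 0:
                        pa = trio[j]
                    else:
                        pb = trio[j]
            _gamete(seqs[pa, 0], seqs[pa, 1], child[0], n, L, c, k, buf)
            _gamete(seqs[pb, 0], seqs[pb, 1], child[1], n, L, c, k, buf)
            for s in range(2):
                for g in range(n):
                    _mutate_gene(child[s], g * L, L, M, buf)
            for s in range(2):
                for p in range(G):
                    seqs[repl, s, p] = child[s, p]
            _distances(seqs[repl], t1, n, L, d0[repl], d1[repl])
            fit[repl] = _ind_fitness(d0[repl], d1[repl], n, r0, r1, h0, h1, lam)
        # end-of-generation loss check, lowest gene index reported first
        for g in range(n):
            present = False
            for i in range(N):
                if d0[i, 0, g] < r0 or d0[i, 1, g] < r0:
                    present = True
                    break
            if not present:
                return 1, gen, g
    return 0, max_gen, -1
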