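# Methods

## Model

The simulator evolves a constant-size population of N diploid
individuals in discrete, non-overlapping generations. Genomes are
sequences over a 4-letter alphabet partitioned into n genes of length
L; every gene carries a private two-peak fitness landscape in Hamming
space.

**Landscape.** Peak 0 of each gene is the all-"0" sequence (height h0 =
15, radius r0 = 2 by default); peak 1 is drawn once per gene at exactly
S·D positions chosen uniformly without replacement, each set to a
uniform non-"0" symbol (height h1 = 10, radius r1 = 5, D = 10). Peaks
must not meet or overlap (S·D > S·(r0+r1) is enforced), so a
positive-fitness tie between peaks cannot occur. Within a radius,
fitness decays linearly to zero at the radius; the decay shape is not
uniquely determined by an apex and a zero point, and the linear ramp is
this package's choice (configurable in principle via `PeakSpec`; all
points strictly inside the radius have positive fitness, and distance
exactly equal to the radius scores zero). "Carrying" a peak means
Hamming distance strictly less than the radius.

**Fitness.** A sequence's per-gene fitness is the larger of its two
peak contributions; a diploid's per-gene fitness is λ·f_max +
(1−λ)·f_min over its two homologs with dominance λ = 0.999999999999999,
so the worse homolog always contributes a detectable but negligible
amount (at λ = 1 one homolog would drift entirely unseen). The
individual's fitness is the minimum over its genes — a conservative
epistasis under which every gene is essential, preventing one intact
gene from masking the loss of others.

**Reproduction.** Each generation a uniform random permutation is cut
into consecutive trios (N mod 3 individuals idle that generation). The
trio is ranked by fitness, ties broken uniformly at random; the least
fit is replaced with probability 0.5 and each of the two fitter with
probability 0.25 — the fittest individual can die, which is what makes
loss of the fitter peak possible at all. The two survivors parent the
replacement. Gametes are formed meiosis-style: each gene is split into
c equal contiguous chromosome blocks (the last block absorbs any
remainder); per chromosome, a starting strand is chosen uniformly
(independent assortment) and k distinct crossover boundaries are chosen
uniformly among the block's internal boundaries, the copied strand
alternating at each. Mutation follows gamete formation: per gene, K ~
Binomial(L, M) distinct positions are resampled to one of the other
three symbols, so exactly K positions change.

**Termination.** After each generation the run checks every gene for
peak-0 presence and stops at the first generation at which any gene has
no carrier (recording the generation and the lowest lost gene index),
or at the generation cap (default 10,000). Checking once per generation
rather than per replacement event is a deliberate efficiency choice;
at most ⌊N/3⌋ replacements can intervene.

## CMR estimation

The critical mutation rate is the smallest swept per-base rate at which
at least 95% of runs lose peak 0 within the cap. Rates ascend a coarse
grid (d×10⁻ᵉ, d = 1…9, from 10⁻⁸ to 10⁻²) to locate the decade, then a
fine grid in steps of 0.1×10⁻ᵉ pinpoints the value. Runs are organised
in batches (20 × 100 by default); each batch's CMR is the smallest rate
at which ≥95% of that batch's runs lost, and the reported CMR is the
batch mean with SD and a Student-t 95% CI (19 df). A rate is abandoned
("early advance") as soon as accumulated keepers exceed what the 95%
criterion tolerates for the full run target — for 2,000 runs, the 101st
keeper. Early advance cannot flip the aggregate decision at a rate; it
can defer an individual batch's resolution to a slightly higher rate,
a small upward bias accepted for the large saving in run count.
Within a sweep, run seeds depend only on (batch, run index), not on the
rate — common random numbers that reduce between-rate variance.

Batches that reach the top of the grid without attaining 95% loss can
either raise an error or be censored at the grid maximum (recorded
value is then a lower bound and the estimate is flagged `censored`);
experiment orchestration uses censoring so sweeps always terminate.

Two protocol profiles are first-class. The **full** profile is 20
batches × 100 runs, a 10,000-generation cap, and the coarse+fine grid.
The **reduced** profile — 5 batches × 20 runs, a 2,000-generation cap,
coarse grid only — exists because a full estimate at large N multiplies
to days of CPU; reduced-profile estimates resolve the CMR to the coarse
grid's ~12% step size, which is ample for directional comparisons. The
package's own desk-scale measurements (reduced profile unless noted):
CMR ≈ 5×10⁻³ at (L=30, N=10) rising to ≈ 9×10⁻³ at N=60; ≈ 2×10⁻³ at
L=120; ≈ 3×10⁻⁴ at L=1000 (N=300), i.e. close to 1/L scaling; roughly
4-fold lower with n=4 genes than with one.

## Determinism and engines

Every stochastic choice draws from a generator seeded from the run
configuration; a master seed spawns per-cell and per-run seeds through
`numpy.random.SeedSequence`, so any experiment cell is reproducible in
isolation from the manifest. Two engines implement the identical
algorithm: a numpy/pure-Python reference path composed of the public
op-level functions (used for per-generation tracing and op-level
statistical tests) and a numba kernel used for sweeps (~5 µs per
generation at N=10, L=30). The engines consume randomness differently
and therefore match statistically, not bitwise; each is deterministic
given (configuration, engine).

## What the trend suite shows — and a known discrepancy

The acceptance trend suite estimates the CMR under the reduced profile
at L=30 and asserts directions: the CMR rises with population size and
with the peak scale S, and falls when gene length or gene number is
increased. These reproduce at desk scale with clear margins (e.g.
5.2×10⁻³ → 9.2×10⁻³ for N 10→60; 8.4×10⁻³ → 2×10⁻³ for L 30→120).
Ordering between adjacent population sizes is asserted non-strictly
because the coarse grid can tie neighbours.

The crossover trend is the exception. Under the meiosis-style
gametogenesis implemented here, raising crossovers per chromosome from
1 to 5 leaves the estimated CMR flat or slightly lower at every scale
we measured (L=30 with N from 10 to 500; L=1000 with N up to 300,
where both k=1 and k=5 resolve at 3×10⁻⁴ on the coarse grid). The
mechanism is intelligible: near the CMR, peak-0 persistence rides on
gametes that inherit a nearly clean peak-0 strand; extra crossover
points average mutational load across the two homologs, shrinking the
variance of gamete load and thus thinning the clean tail. Published
measurements with this class of model report the opposite direction at
large N, but hinge on recombination mechanics that are not fully
specified; the sign of the crossover effect evidently depends on those
mechanics. The corresponding trend test asserts the increasing
direction and currently fails; it is left failing rather than weakened,
as an honest record of the discrepancy.

A related observation: with M = 0, peak 0 is still lost in roughly a
quarter of runs at N=10 (L=30, 1,000 generations), because crossover
through peak0/peak1 heterozygotes produces off-peak mosaic gametes —
drift plus recombination erode carriers without any mutation. Both
engines agree on this rate. It is the small-N limit of the same force
that makes the CMR collapse at small population sizes.

## Synthetic data and scope

There is no external data; landscapes and populations are generated by
the package itself, and the generator's defaults are the canonical
study conditions (L=1000, n=1, r0=2, r1=5, D=10, S=1, k=1, c=1, h=15/10,
λ just under 1, half the population initialised on each peak top, the
extra individual of an odd N on peak 0). What passing tests show is
that the simulator realises this idealised model faithfully — linear
peaks, uniform random peak-1 placement, binomial mutation, constant
crossover counts. Real genomes differ in ways the model deliberately
ignores: fitness landscapes are not two isolated peaks, mutation is not
uniform across sites or symbols, crossover counts vary between meioses
and sexes (the bundled A. thaliana crossover table documents this
variation; it is reference data only), and generations overlap in most
species. Bundled mutation-rate tables are used solely to annotate
plots, never to drive simulations.

## Numerical choices and edge cases

- Fitness is evaluated in double precision; with λ = 1−10⁻¹⁵ a
  heterozygote on both peak tops scores 15 − 5×10⁻¹⁵, strictly below a
  peak-0 homozygote.
- Fitness-rank ties in trios are broken by uniform random keys to avoid
  positional artifacts.
- Equal sequences outside both radii report peak identity "none" rather
  than arbitrarily peak 0 or 1.
- Crossover boundaries use 0-based, half-open segment conventions; k
  must not exceed a chromosome's internal boundary count (validated).
- Grid rates are constructed from decimal strings so they compare
  bit-exactly with literals like 3e-5.
- The sweep's keeper tolerance is ⌈0.95·total⌉ complements: for a
  2,000-run target, 100 keepers are tolerated and the 101st aborts the
  rate, which keeps "95% lost" achievable exactly at the boundary.

## Limitations

- The crossover-count trend disagrees in sign with published large-N
  results, as discussed above.
- Reduced-profile estimates are quantised to the coarse grid and carry
  its ~12% resolution; censored estimates are lower bounds.
- The compiled and Python engines are statistically, not bitwise,
  interchangeable.
- Landscapes with per-gene heterogeneous radii or heights are supported
  by the data model and the Python engine but not by the compiled
  kernel (it falls back to the Python path automatically).
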