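# Methods

## Estimators

### Pairwise F_ST (Nei–Chesser bias-corrected gene diversities)

For one locus and one pair of populations (i, j) with n_i, n_j typed
diploid individuals, let p̃ be the sample allele frequencies,
h_i = 1 − Σ_u p̃_iu², p̄_u = (p̃_iu + p̃_ju)/2, and
ñ = 2 / (1/n_i + 1/n_j) the harmonic-mean sample size. With observed
heterozygote proportions Ĥ₀ (the average of the two populations'
observed-heterozygote fractions):

    Ĥ_S = ñ/(ñ−1) · ( h̄ − Ĥ₀ / (2ñ) ),          h̄ = (h_i + h_j)/2
    Ĥ_T = 1 − Σ_u p̄_u² + Ĥ_S/(2ñ) − Ĥ₀/(4ñ)

When only allele frequencies are available, Ĥ₀ is replaced by its
Hardy–Weinberg expectation, which reduces the corrections to

    Ĥ_S = 2ñ/(2ñ−1) · h̄,     Ĥ_T = 1 − Σ_u p̄_u² + Ĥ_S/(4ñ).

The genome-wide estimate is the **ratio of locus sums**
Σ_l (Ĥ_T,l − Ĥ_S,l) / Σ_l Ĥ_T,l ("ratio of averages"), which converges
to the true value by the law of large numbers; a locus monomorphic
across the pair contributes zero to both sums. A pair with no co-typed
polymorphic locus is reported as NaN with a warning. Sanity limits:
two large samples from identical (0.5, 0.5) frequencies give
|pwFst| < 10⁻³; fixed alternative alleles give 1.

### Population-specific F_ST (Weir–Goudet allele matching)

Per locus, the within-population matching of two distinct allele copies
drawn without replacement is

    M̂_Wi = Σ_u c_iu (c_iu − 1) / (2n_i (2n_i − 1)),

and M̂_B is the unweighted mean over pairs of typed populations of
Σ_u p̃_iu p̃_i'u. Genome wide,

    psF̂st(i) = Σ_l (M̂_Wi,l − M̂_B,l) / Σ_l (1 − M̂_B,l),

restricted to loci typed in population i with at least two typed
populations. Equivalently psF̂st(i) = 1 − Σ Ĥ_Si / Σ Ĥ_B with
Ĥ = 1 − M̂ (an exact identity, tested to 10⁻¹²). Negative values are
admissible and meaningful: they flag a population more heterozygous
than the between-pair average, as expected for the source of a range
expansion. Both estimators are verified against brute-force oracles
(direct per-locus formula evaluation; exhaustive enumeration of allele
copy pairs) to 10⁻¹⁰ on random small instances.

### Standard errors and covariance

Loci are treated as the units of replication. The covariance of the
psF̂st vector is the leave-one-locus-out jackknife

    Ω̂ = (L−1)/L · Σ_l (F̂⁽⁻ˡ⁾ − F̄)(F̂⁽⁻ˡ⁾ − F̄)ᵀ,

computed in O(LK) from the per-locus numerator/denominator components,
then projected onto the positive semi-definite cone by eigenvalue
clipping; SEs are the square roots of the diagonal. Calibration: over
50 replicate simulations of the one-directional scenario, the median
jackknife SE of every deme lies within a factor of two of the
across-replicate SD (the jackknife captures across-locus variation,
which is the relevant variance because the demographic schedule is
fixed and loci are independent given it). Duplicating every locus k
times shrinks the SE by ≈ 1/√k.

### Island-model migrant conversion

At drift–migration–mutation equilibrium in Wright's island model,
F_ST ≈ 1/(4Nem + 1), so `migrants_from_fst` returns 4Nem = 1/F_ST − 1
(0.02 ↦ 49). The default connectivity threshold of 0.02 on the maps
draws an edge wherever gene flow exceeds ≈ 49 effective migrants per
generation.

## Colonization simulator

25 demes, one ancestral (deme 1), under five expansion geometries:

* chains — one-directional (1→25); two-directional (chain 1–9 splitting
  at deme 9 into branches ending at demes 16 and 25); three-directional
  (branches 2–8, 9–16, 17–25 all rooted at deme 1);
* 5×5 grids with 8-neighborhoods — colonized from the middle of an edge
  (three expansion directions: along the edge both ways and inward) or
  from the center (eight directions). The origin cell is configurable
  (`grid_origin`).

State is the frequency q of the tracked allele at every locus × deme.
Per generation, in this order:

1. **Migration** — deterministic mixing with each occupied neighbor:
   q_i ← (1 − k_i m) q_i + m Σ_{j∈N(i)} q_j, with m = 0.01 per neighbor
   (exchange of 1% of Ne gene copies). Sampling the actual migrant pool
   binomially per directed edge is available
   (`stochastic_migration=True`); at the default scale it changes the
   results negligibly (< 0.5 percentage points on the MDS
   decomposition) and costs ~3× the runtime, so expectation mixing is
   the default.
2. **Drift** — one binomial draw of the deme's current gene-copy count
   (Ne = 10⁴ by default; the ancestral deme may differ, e.g. 10⁵).
   Fixed cells (q ∈ {0, 1}) are absorbing and skipped.
3. **New SNPs** — each occupied deme gains 10 derived SNPs per
   generation at frequency 0.01 there and 0 elsewhere, mimicking new
   mutations that survived their initial phase.
4. **Founding** — every 10 generations, each vacant deme adjacent to an
   occupied one is founded by a binomial sample of 1% of the source's
   Ne gene copies; with several occupied neighbors the lowest-index one
   is the source (deterministic; ties only arise on the grids). The
   new deme is at full size Ne from the next generation. An option
   (`founder_sized_first_generation`) instead lets the deme reproduce
   once at founder size before growing, adding a second
   ~1/(2·founders) variance event per founding; it is off by default.

Ancestral frequencies are drawn from the neutral equilibrium density
f(q) ∝ 1/(q(1−q)), discretized on the grid {1/Ne, …, (Ne−1)/Ne} (the
resolution of Ne gene copies), which makes the improper density proper
without an arbitrary continuous truncation. The event order within a
generation is a convention fixed for reproducibility; the study-scale
behavior is insensitive to it at m = 0.01.

After the final generation (260 for chains — the last deme is founded
at generation 240 — and 100 for grids), loci whose pooled frequency
across demes lies strictly in (0, 1) count as still polymorphic;
10,000 ancestral and 500 derived SNPs are sampled uniformly among them,
and 50 diploid individuals per deme are genotyped by drawing
Binomial(2, q_deme) copies of the tracked allele. The same seed yields
a bit-identical genotype table. Loci fixed at 0 or 1 in every occupied
deme are pruned during the run (they can never re-polymorphize), which
keeps the live-locus count and runtime bounded; a full-scale replicate
takes ≈ 20–40 s on one CPU.

### What the generator does and does not emulate

It reproduces serial founder effects, stepping-stone gene flow, drift,
and the birth of new variants — the mechanisms that make
population-specific F_ST trace expansion history. It deliberately
omits selection, linkage (loci are independent), long-range dispersal,
admixture from outside the lattice, and population-size change beyond
the one-generation founding growth. Tests passing on these data
therefore show that the estimators and representations recover a known
stepping-stone history; they do not certify behavior under admixture
or bottlenecks in the ancestral population, where heterozygosity-based
identification of the source is known to mislead.

## Visual representations

* **Classical MDS**: B = −½ J D² J, eigendecomposition; coordinates are
  eigenvectors scaled by √λ⁺; the cumulative contribution
  C_k = Σ_{j≤k} λ_j⁺ / Σ_j λ_j⁺ uses positive eigenvalues only
  (negative ones, from non-Euclidean inputs, are set to zero).
* **NJ tree**: Saitou–Nei neighbor joining (via scikit-bio), negative
  branch lengths retained but flagged; Newick export.
* **Colors**: F'_ST = (F_ST − min)/(max − min), rgb = (1 − F', 0, F');
  a degenerate (constant) range maps everything to red with a warning.
* **Connectivity**: undirected edges where pairwise F_ST < threshold
  (default 0.02). Maps are plain equirectangular lon/lat plots.
* Distance input to NJ/MDS clamps negative pairwise estimates to zero
  (distances must be non-negative); raw values stay available in the
  tables. Every plotted quantity is also written as TSV so tests and
  users can check data rather than pixels.

## GLS regression

psF̂st = Xβ + ε with ε ~ N(0, Ω̂), Ω̂ from the jackknife. The fit
whitens with the Cholesky factor of Ω̂ (after PSD repair: eigenvalue
clipping at zero plus a relative 10⁻¹⁰ diagonal jitter when needed) and
never forms an explicit inverse. Because Ω̂ is treated as known, Z =
β̂/se(β̂) is referred to the standard normal, and no residual scale is
estimated (this differs from regression software that rescales the
covariance by an estimated scale; the package's tests reconcile the
two). The collinearity screen is advisory: it repeatedly drops the
covariate with the most pairwise correlations beyond a threshold
(default: the two-sided significance critical |r| at α = 0.05) and
never alters a user's design matrix silently.

## Problem sizes used in the tests and the reproduction script

The reproduction script (`scripts/acceptance.py`) runs all five
scenarios at the full study scale (Ne = 10⁴, 10,000 + 500 sampled SNPs,
50 diploids per deme) with five seeded replicates each and reports
median MDS axis contributions; expected wall time 10–15 minutes on one
CPU. The test suite keeps its Monte Carlo checks at a reduced preset —
Ne = 10³ gene copies, a 2,000-SNP ancestral pool, 400 + 20 sampled
SNPs — chosen so that 50-replicate calibrations run in seconds each
while preserving the qualitative serial-founder structure (at this
scale founder bottlenecks are 10 copies, so the diversity gradient is
strong). One consequence of the smaller Ne is *faster relative
equilibration*: after 260 generations the oldest demes have exchanged
migrants for ≈ 2.5 Ne·m generations, so the ancestral deme's diversity
advantage over its first neighbors erodes and interior demes gain
heterozygosity through admixture of differentiated neighbors. The
founding *order* remains clearly recoverable (He declines monotonically
along the chain in replicate means; NJ leaf order and the first MDS
axis track it), but the strict "ancestral deme attains the exact
minimum psF_ST" event is no longer near-certain — at reduced scale, and
only marginally at full scale for the grid geometries, whose post-
colonization phase (80 generations of 8-neighbor mixing) erases most of
the founder signal. The acceptance test for that claim states the
strict criterion and documents this limitation; see the dot-chart SEs
for the honest uncertainty statement.

## Known limitations

* The Genepop reader supports diploid 2- and 3-digit dialects only (no
  haploid or mixed-width files).
* The jackknife treats loci as exchangeable units; with strong linkage
  a block jackknife would be needed.
* MDS contribution ratios at small panel sizes are biased toward
  uniformity (estimation noise spreads variance across axes); use the
  full SNP panel when comparing decompositions.
* GLS p-values are asymptotic normal; with few populations they are
  anti-conservative.
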