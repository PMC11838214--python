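# Methods

## Problem and model

We observe `m` bulk DNA-seq samples of one tumor, summarized as average copy
numbers `F ∈ R≥0^{m×(l+g+2r)}` for `l` SV breakpoint ends, `g` SNVs and `2r`
allele-specific segment copy numbers, together with the breakpoint/SNV-to-
segment map `Q` and the breakpoint-end pairing `G`. From scRNA-seq we take
an `n × 2r` integer matrix `Cᴿᴺᴬ` of allele-specific segmental copy numbers
for `n` clones (as produced by scRNA CNA callers; calling itself is out of
scope). The estimands are the mixture fractions `U`, integer clone genotypes
`C`, an RNA-clone assignment permutation `M`, and a rooted binary clonal
tree, minimizing

    |F − UC|₁ + |C′ − M Cᴿᴺᴬ|₁ + λ₁ R + λ₂ S .

`C′` is defined as the segment block of `C` (implemented by aliasing, not a
separate variable block). Model assumptions, in the order they bind:

- **Clone count `n` is user input**, odd and ≥ 3. Nodes are ordered:
  leaves `1..n′`, internal `n′+1..n−1`, root `n`, with `n′ = (n−1)/2`.
  The root is the normal clone: zero on all mutation columns, one on all
  allele-segment columns.
- **Tree**: binary adjacency `E` with no edge into the root, none out of
  leaves, in-degree exactly 1 elsewhere, out-degree ≤ 2, and ≥ 1 child for
  every non-leaf. The ancestry matrix `A` dominates `E`, propagates along
  edges in both directions (`A[k,j] ≥ A[k,i] + E[i,j] − 1` and
  `A[k,j] ≤ A[k,i] − E[i,j] + 1` for `k ≠ i`), and `A[i,i] = 0` forbids
  cycles; together with unit in-degree this makes `A` exactly the
  reachability closure of a spanning arborescence.
- **Every clone maps to exactly one RNA clone**: `M` is a permutation
  matrix. Permuting the rows of `Cᴿᴺᴬ` therefore never changes the optimum.
- **Loss-supported Dollo** for each SNV and breakpoint `k`: a binary
  presence indicator `y[i,k]` is tied to the copy number
  (`y ≤ C[i,k] ≤ c_max·y`); the gain tensor `W` satisfies
  `Σᵢⱼ W[i,j,k] = 1`, `W ≤ E`, and presence can only appear at the gain
  edge and persist down unbroken carrier lineages
  (`y[j,k] ≤ y[i,k] + W[i,j,k] + 1 − E[i,j]` on every potential edge).
  A mutation absent from all clones still carries a (vacuous) gain edge, so
  the per-edge mutation lists always partition the mutation set.
- **Allele coupling**: a binary allele assignment `D[b]` selects which
  allele of its segment carries mutation `b`; `C[i,b]` is bounded by the
  selected allele's segment copy number, with big-M `c_max` disabling the
  non-selected bound. This bound is applied to SNVs as well as breakpoints
  (mutation amplifications/losses track their segment's allele), while the
  ratio cost below remains breakpoint-only.
- **Tree cost** `R = Σ_edges Σ_seg-cols |C[i,·] − C[j,·]|`, linearized with
  per-edge nonnegative auxiliaries activated by `E` via big-M `c_max`
  (valid since segment copy numbers are bounded by `c_max`).
- **Ratio cost** `S`: for each sample and breakpoint, the observed ratio
  `π[i,b] = F[i,b] / (F[i,seg₁(b)] + F[i,seg₂(b)])` should match the ratio
  implied by `(U, C)`; `S` sums `|Σⱼ U[i,j]C[j,b] − π[i,b]·Σⱼ U[i,j](C[j,seg₁]+C[j,seg₂])|`.
  Entries with zero denominator (0/0) carry no information and are excluded
  rather than clamped; valid entries are clipped to `[0, c_max]`. An
  off-by-default flag exists for extending `S` to SNVs, but π is only
  defined through breakpoint indexing, so the default mirrors the model as
  specified.

## Regularization weights

`λ₁ = ½·(l+g+2r)·m / (2r·N)` with `N = n`, and `λ₂ = ½·(l+g+2r)/(l+g)`.
The denominator count `N` is genuinely open (the tree cost spans `n−1`
edges of `2r` columns); we take `N = n` so that λ₁ is the ratio of the
entry count of the bulk data-fit term to the size of `R`, which is the
stated intent of the formula. Both weights are overridable.

A consequence worth knowing: on noise-free data the planted solution has
data-fit 0 but `R > 0` (every copy-number event contributes a unit of edge
distance), so the *full* objective is never zero on any instance with CNA
events, and for clones with small total mixture fraction the optimizer may
lawfully prefer a slightly smoothed genotype over the planted one. Recovery
claims are therefore stated in terms of the deconvolution residual
`|F−UC| + |C′−MCᴿᴺᴬ| + λ₂S` and clone-matched RMSE, not the raw objective.

## Optimization

Coordinate descent with random restarts. Each restart draws `U₀` rows from
a uniform Dirichlet (the natural "random initialization" on the simplex)
and alternates, starting with the C-step (U is the randomly initialized
block, so genotypes must be estimated first):

1. **C-step** (MILP): all integer/binary blocks jointly, with `U` fixed.
2. **U-step** (LP): `U` with `C` fixed. The public contract of
   `solve_u_step` is `min |F−UC|₁` on the simplex; the descent driver
   additionally passes the λ₂S term (linear in `U` with `C` fixed) so the
   full objective is a true coordinate descent and is monotone
   non-increasing whenever both solves reach optimality.

Both subproblems run on HiGHS through `scipy.optimize.milp` behind a small
builder layer (`_milp.LinearModel`); the backend abstraction carries the
time limit (incumbent returned and flagged on timeout — the incumbent is
then used as the fixed matrix for the next half-step), a relative MIP gap
(default 1e-4), and L1 objectives via auxiliary variables. Reported
objectives and term breakdowns are recomputed from the rounded integer
solution, never read off auxiliary variables, so they are exact for the
matrices returned. Fixed iteration count (default 3) with an optional
1e-6-improvement early stop; best restart selected by final objective with
lowest-index tie-break. One integer seed drives the restarts (and, in the
CLI, the simulator and subsampling).

Defaults: `c_max = 10`, 3 restarts, 3 iterations, no time limit. Symmetry
among interchangeable internal nodes is left to the solver; on the intended
problem sizes (n ≤ 9, a few hundred binaries) HiGHS handles it directly.

## Synthetic-data generator

The generator reproduces the validation protocol's study conditions:

- **Tree**: uniform random attachment honoring the leaf/internal/root node
  ordering; exactly `n′` leaves.
- **Genome**: two chromosome templates with GRCh38 chr1/chr2 lengths,
  pre-partitioned into `r` contiguous equal-width segments (allocated to
  chromosomes proportionally to length). Fixing the segmentation up front
  (rather than inducing it from breakpoints) keeps `r` an explicit study
  condition and guarantees `Q` is well defined for every draw.
- **Events**: SV positions uniform (chromosome chosen by length), lengths
  ~ Poisson(5,745,000 bp) — the TCGA-BRCA average; types drawn
  amplification : inversion : deletion : translocation = 2:1:2:1.
  Amplifications/deletions shift the chosen allele's copy number by ±1 over
  the carrier subtree of a uniformly chosen tree edge; an allele at 0 can
  never be amplified again, so genotypes satisfy Dollo by construction.
  Inversions and translocations are copy-neutral but contribute breakpoint
  ends. SNVs sit at uniform positions on a uniformly chosen allele and edge.
  Breakpoint and SNV copy numbers equal their segment's assigned-allele copy
  number inside the carrier subtree (the allele-gating constraint holds with
  equality), zero outside.
- **Bulk noise**: `U*` rows ~ Dirichlet(1); `F₀ = U*C*`; per sample and
  segment a read depth ~ Poisson(50) (zeros redrawn) sets the binomial
  trial count for variant reads at the theoretical VAF (and BAF for the
  segment allele split); observed fractions are rescaled to the theoretical
  segment total copy number. `noise=False` returns `F₀` exactly.
- **scRNA profiles**: per clone and segment, a uniform 3–6 genes; per gene
  and allele, transcripts ~ Poisson(50·cn/2), so a diploid segment averages
  50 transcripts per gene. Averaging per allele and dividing by 25 anchors
  diploid at copy number 1 per allele; rounding yields the integer profile.
  No dropout or cell-level noise is modeled — passing tests demonstrate
  correct behavior under transcript-count noise only, not under real scRNA
  sparsity, doublets or caller segmentation error.
- A separate single-cell SNV read generator draws per-site total depth
  ~ Poisson(120) and alternate reads binomially at the clonal BAF
  (error-free, uniform-expression assumption).

Simulated F matrices are exactly `U*C*` before noise, and the planted
`(C*, E*, W*, D*)` is verified feasible against the C-step constraint set in
the test suite.

## Evaluation

Estimated clones are aligned to truth by Hungarian assignment on L1 genotype
distance (genotypes identify clones; frequencies vary per sample), and the
same permutation is applied jointly to `U` and `C`. Reported: RMSE of `U`
over all `m×n` entries, and RMSE of the SV (breakpoint) and SNV blocks of
`C`. We report root-mean-square error throughout; since `U` rows are simplex
points, `rmse_U ≤ √2`.

## Numerical choices and degenerate inputs

- Solver tolerance drift in U rows is clipped and renormalized to the
  simplex before reporting.
- `π` with zero denominator: excluded from `S` (flagged, not fatal).
- `Cᴿᴺᴬ` entries above `c_max` fail validation at the API (raise) and are
  clipped with a warning inside the model builder.
- Zero-depth segments in the noise model are redrawn.
- Brute-force oracles in the tests enumerate permutations × copy-number
  grids (C-step, n=3, c_max=2) and simplex lattices (U-step, step 0.01)
  independently of the MILP builder.

## Problem sizes used in the shipped checks

Unit and acceptance tests run at desk scale, chosen as the smallest sizes at
which every constraint group is active: 3–5 clones, 2–3 samples, 4 SVs,
4–8 SNVs, 3–6 segments; calibration checks use 10,000 draws. The clone-count
sweep (n ∈ {3, 5}, 3 replicates, noisy) demonstrates the qualitative trend
that clone-matched RMSE grows with clone count; only the direction of the
trend is asserted, never specific error values.

## Known limitations

- Clones present in bulk but absent from scRNA are not modeled (M is a
  bijection).
- `S` covers breakpoints only by default; the SNV extension is a flag.
- No multi-allelic SNVs, no phasing of real data, no subclonal WGD model.
- ILP scaling: the C-step grows as `n²(l+g)` binaries; large variant sets
  should be subsampled (`sv_cap` / `snv_cap` keep the highest-support
  variants, seeded ties).
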