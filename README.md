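# clonedeconv

Joint clonal deconvolution and phylogeny inference from multi-sample bulk
DNA-seq, guided by allele-specific copy-number profiles of tumor clones
called from single-cell RNA-seq — handling SNVs, copy-number alterations
(CNAs) and structural variants (SVs) in one optimization.

## Who this is for

Cancer genomics groups with the common data combination of bulk DNA-seq
(WGS/WES, several samples per patient) plus scRNA-seq, but no scDNA-seq.
Bulk DNA gives genome-wide SNV/CNA/SV calls with poor clonal resolution;
scRNA gives fine clonal structure but only coarse segmental copy numbers.
This package integrates the two: the scRNA clone profiles anchor the
deconvolution of the bulk variant matrix into clone genotypes, mixture
fractions and a clonal lineage tree.

## The model

Inputs: an `m x (l+g+2r)` matrix **F** of average variant copy numbers per
bulk sample (columns: `l` SV breakpoint ends, `g` SNVs, `2r` allele-specific
segment copy numbers), a breakpoint/SNV-to-segment map **Q**, a
breakpoint-end pairing **G**, and an `n x 2r` integer matrix **C**ᴿᴺᴬ of
allele-specific segmental copy numbers for the `n` scRNA clones.

We estimate the mixture-fraction matrix **U** (`m x n`, rows on the
simplex), the integer clone-genotype matrix **C** (`n x (l+g+2r)`), and a
permutation **M** assigning phylogeny clones to RNA clones, by minimizing

```
min   |F − U·C|₁  +  |C′ − M·Cᴿᴺᴬ|₁  +  λ₁·R  +  λ₂·S
U,C,M
```

where `C′` is the segment block of `C`, `R` is the L1 copy-number distance
summed over the edges of a rooted binary clonal tree (adjacency **E**,
ancestry **A**) inferred jointly with `C`, and `S` penalizes disagreement
between observed and implied breakpoint-to-segment mixture copy-number
ratios. Constraints enforce: a normal (mutation-free, diploid) root clone;
copy numbers bounded by `c_max`; a loss-supported Dollo model for every
SNV/SV (placement tensor **W**: gained on exactly one edge, lost only where
the carrying allele's segment is lost); and an allele assignment **D** that
gates each mutation's copy number by its segment's allele copy number.

The nonconvex joint problem is solved by coordinate descent: with `U` fixed,
`(C, C′, M, E, A, W, D)` is a MILP; with `C` fixed, `U` is an LP. Both are
solved with HiGHS (through SciPy). Random restarts draw `U₀` from a uniform
Dirichlet; the best final objective wins. `λ₁ = (l+g+2r)m / (2·2r·n)` and
`λ₂ = (l+g+2r) / (2(l+g))` by default (size ratios of the data-fit term to
each regularizer).

The package also ships the synthetic-data generator used to validate the
method (random clonal trees; SV lengths ~ Poisson(5,745,000 bp); event types
amplification : inversion : deletion : translocation at 2:1:2:1; bulk
Poisson(50) segment depths feeding binomial variant reads; per-gene
Poisson(50) diploid transcript counts for the scRNA profiles) and a
clone-matched RMSE evaluation harness.

## Worked example

Simulate a 3-clone patient with 2 bulk samples, 4 SVs, 8 SNVs and 6
segments, run the inference, and score it against the planted truth:

```
$ clonedeconv simulate --n-clones 3 --m-samples 2 --snvs 8 --svs 4 \
      --segments 6 --seed 7 -o demo/instance
instance written to demo/instance

$ clonedeconv infer --instance-dir demo/instance -n 3 -t 3 -r 3 \
      --c-max 6 --seed 7 -o demo/solution
objective 7.3843 (restart 2); outputs in demo/solution

$ clonedeconv evaluate --truth-dir demo/instance/truth \
      --solution-dir demo/solution -o demo/report.json
{"rmse_U": 0.03554108247272912, "rmse_C_snv": 0.0, "rmse_C_sv": 0.0}
```

The objective (7.38) is the realized value of the four-term sum above at the
best restart; with read-count noise at 50x it cannot reach zero. The report
says the inferred genotypes match the planted SNV and SV copy numbers
exactly (`rmse_C_* = 0`) and the mixture fractions are recovered to RMSE
0.036 after optimal clone matching. `demo/solution/` contains `U.tsv`,
`C.tsv`, `M.tsv`, the tree as Newick/DOT (`((clone_0)clone_1)normal;`),
per-edge mutation lists from **W**, and a JSON manifest (config, seed, input
hashes, solver gaps) sufficient to reproduce the run.

The same pipeline is available as a library: `simulate_instance`,
`descent.run`, `evaluation.rmse_report`.

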