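# Methods

## Model

The genome is a sequence of T fixed-width segments (default 200 bp per
segment; a trailing partial segment at a chromosome end is dropped). Each
segment t carries a hidden chromatin state hₜ ∈ {1..K} and an observation
xₜ ∈ {0..N−1}, the integer encoding of the combination of M binarized
marks (mark m contributes bit m, LSB first; the all-absent combination is
code 0). Conventions are column-stochastic throughout:

* A[i,j] = Pr[hₜ₊₁=i | hₜ=j]  (K×K, columns sum to 1)
* O[x,j] = Pr[xₜ=x | hₜ=j]    (N×K, columns sum to 1)
* π[i]   = Pr[h₁=i] for the first segment of each chromosome.

Chromosomes are independent sequences sharing (A, O, π). The emission is a
full categorical over all 2^M combinations — deliberately not a per-mark
independent Bernoulli product — so arbitrary mark interactions are
representable. The cost is an alphabet exponential in M, but observed
genomes are extremely sparse in combination space, so moments are held
sparsely (triple slices keyed by observed middle codes; pair matrices
switch to CSR above N = 2048) and the SVD switches to an iterative sparse
solver above N = 1024.

The sequence likelihood factors through observable operators
B_x = A·O_x (O_x = diag of row x of O):
P(x₁:T) = 1ᵀ B_{x_T} … B_{x_1} π. This identity is both the basis of the
moment estimator and an independent oracle for the forward recursion.

## Moment estimation

Singletons, chromosome-initial observations, pairs and triple slices are
pooled counts over all chromosomes divided by the total number of
pairs/triples (length-weighted pooling, not per-chromosome averaging).
Pairs and triples never span a chromosome boundary, and an optional
excluded-region mask splices sequences so that no pair or triple spans a
masked gap — masking must not fabricate transitions.

Optional smoothing shrinks the co-occurrence matrices toward the product
of singleton marginals:

* P₂,₁ ← (1−w)·P₂,₁ + w·P₁P₁ᵀ
* slice_x ← (1−w)·slice_x + w·(P₁[x]/Z)·P₁P₁ᵀ, with Z = Σ_{x observed} P₁[x]

The Z renormalization (middle-marginal restricted to observed slices)
keeps the total triple mass exactly 1 and preserves P₃,₁ = Σₓ slice_x to
machine precision; without it a small mass deficit appears whenever some
code occurs only at sequence ends. w = 0 (the default) is the identity.

## Spectral recovery

1. U = top-K left singular vectors of P₃,₁, with a deterministic sign
   gauge (largest-magnitude entry positive) so runs are bit-reproducible.
   A warning is logged when σ_K/σ₁ < 1e-10.
2. Cₓ = (UᵀP₃,ₓ,₁)(UᵀP₃,₁)⁺. The pseudoinverse cutoff defaults to
   max(N,K)·eps relative to σ_max and is overridable; a numerically
   rank-deficient UᵀP₃,₁ raises an error suggesting smoothing or smaller K.
3. Per state i the major observation x′(i) = argmaxₓ U[x,i]² selects which
   Cₓ supplies that state's eigenvector (leading eigenvalue by largest
   real part; if the imaginary part exceeds 1e-8 of the spectral radius a
   warning is issued and selection falls back to modulus). If two states
   select the same code, the later state takes its next-best unused code —
   K independent eigenvectors require distinct sources. The `weighted`
   strategy eigendecomposes Σₓ U[x,i]²Cₓ instead, which coincides with
   `max` when one code dominates the singular vector.
4. O[x,i] = (R⁻¹CₓR)[i,i]; the off-diagonal Frobenius mass of these
   matrices is reported as a diagnostic (0 on exact moments).
5. π = O⁺P₁ⁱⁿⁱᵗ and A = (O⁺P₃,₁)(O⁺P₂,₁)⁺. The initial-segment marginal
   and the π-free transition formula are the defaults because the
   all-positions marginal differs substantially from the initial
   distribution on long chromosomes, and inverting diag(π) amplifies noise
   when most states have near-zero initial mass. The classical
   alternatives (π = O⁺P₁, A = O⁺P₂,₁(O⁺)ᵀdiag(π)⁻¹) remain available via
   `legacy_recovery` for comparison; on exact moments with π bounded away
   from zero the two agree to 1e-8.
6. Negative entries produced by sign flips are repaired by entrywise
   absolute value followed by column renormalization (columns, matching
   the column-stochastic definitions; the alternative row normalization
   would break them). An all-zero column becomes uniform with a warning.
   Small negative eigenvalue artifacts inside Cₓ are *not* clipped; only
   final parameters are repaired.

Identifiability requires full-column-rank O, full-rank A, π > 0 and
distinct major observations; under these, recovery from population
moments is exact up to one common state permutation (verified to < 1e-8
in the acceptance suite, and to ~1e-15 in practice).

## Inference and EM

Forward–backward uses per-position scaling constants (not log space);
the log-likelihood is the sum of log scalings, safe for chromosome-scale
T. Decoding defaults to per-segment posterior argmax (the convention of
the EM-based annotators this tool interoperates with); Viterbi is a flag.
Ties break toward the lower state index.

Baum–Welch refinement accepts any initializer and stops when the total
log-likelihood (summed over chromosomes) improves by less than `tol`
(default 0.001) or at `max_iter` (default 200). A decrease beyond 1e-8 is
treated as an internal error since EM is provably monotone. Zero
emission probabilities are honored as hard zeros by default; an optional
`emission_floor` rescues degenerate initializers.

## Synthetic genomes

The simulator is the test bed for every other module and emulates the
regime of real binarized epigenomes:

* `make_imbalanced_params(K, M, null_mass)` builds a background state
  emitting code 0 with probability ≥ 0.95 (high but not a point mass, so O
  keeps full column rank) whose self-transition is tuned by bisection until
  the stationary mass of the background state matches `null_mass` within
  0.02. The default regime of interest is null_mass ≈ 0.9, matching
  Poisson-binarized human data; 0.5 emulates broad-peak binarizations.
  Non-null states get templated mark-block emissions (synthetic
  promoter-like, enhancer-like and transcribed-like patterns) and
  diagonally dominant transitions (self-transition 0.55–0.75). The
  diagonal dominance reflects that chromatin states persist across
  consecutive 200-bp segments, and it keeps A well conditioned — recovery
  works through A², so a near-singular transition design is statistically
  unidentifiable at any realistic sequence length.
* `make_random_params` draws Dirichlet columns and by default rejects
  draws until the identifiability preconditions hold.
* `sample_tracks` samples hidden paths and emissions per chromosome,
  returning binarized tracks plus the true segmentation; everything is
  deterministic given the seed.

What the simulator does *not* model: spatial autocorrelation of
binarization errors, replicate/input structure, copy-number artifacts,
unmappable regions, or mark-specific noise rates. Passing tests therefore
demonstrate correctness of the estimator under the model's own
assumptions and robustness to class imbalance and sampling noise — not
robustness to systematic binarization bias in real data.

## Evaluation

States are identifiable only up to relabeling, so `evaluate_recovery`
matches estimated to true states by minimizing total emission-column L1
distance (Hungarian assignment) before reporting max-abs and per-column L1
errors. It also counts how many estimated states sit closest to the true
background emission profile — the diagnostic for likelihood-based fits
spending extra states on the dominant class.

Enrichment statistics are segment-based (a segment overlaps a feature if
≥ 1 base intersects); expected counts are proportional to a state's
segment fraction, fold enrichment is log2(observed/expected). Recall is
element-level (fraction of feature elements touched by a prediction);
precision is segment-level. The GWAS χ² test is the classical uncorrected
statistic on the 2×2 (in/out of the tested states) × (SNPs/segments)
table; underflowed p-values print as 0. TSS distances use segment
midpoints against TSS interval midpoints. Conservation summaries drop
SNPs with MAF < 0.01 (dominated by mutation, not selection), report per
state the fraction with MAF < 0.1, the mean of per-segment score means,
and a Mann–Whitney U comparison between two states' MAF sets.

## Problem sizes

The test and acceptance workloads are sized for a single desktop CPU:
exact-moment checks at K=3, M=3; sampled recovery at 500,000 segments
(5 chromosomes, K=5, M=4, 85% background); likelihood oracles at T ≤ 50;
EM benchmarks at 20,000 segments with a 25-iteration budget, 5
simulations × (1 spectral + 5 random) initializations; enrichment oracles
on 1,000-segment fixture genomes. These sizes were chosen once as
representative desk-scale versions of the genome-scale setting.

## Known limitations

* Moment estimation treats pooled pair/triple frequencies as stationary;
  chromosomes far from stationarity at their starts contribute small
  finite-sample bias (negligible at genomic lengths).
* The major-observation eigendecomposition assumes reasonably separated
  leading eigenvalues; heavily noisy moments can produce markedly complex
  spectra (a warning is raised and modulus selection used). Smoothing or
  the `weighted` strategy usually stabilizes such cases.
* Recovery quality degrades when two states share nearly identical
  emission columns (O loses column rank) — an intrinsic identifiability
  limit, not an implementation one.
* `read_binarized` loads one chromosome into memory at a time; tracks are
  never memory-mapped.
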