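# chromspec

Spectral (method-of-moments) learning of chromatin-state hidden Markov
models from binarized epigenomic mark tracks.

## The problem

Chromatin-state annotation segments a genome into hidden states — promoter,
enhancer, transcribed, repressed/background — from the pattern of histone
modifications observed in fixed-width (200 bp) segments. The standard model
is an HMM whose observation at each segment is the *combination* of
present/absent marks: with M binarized marks the observation alphabet has
N = 2^M codes, so interactions between marks are modeled without an
independence assumption.

The usual estimator, Baum–Welch/EM, is iterative, initialization-dependent
and — because ~90% of the human genome sits in a background "null" state —
prone to spending several hidden states on the background class at the
expense of rarer functional states. `chromspec` instead estimates the
parameters in closed form from co-occurrence statistics:

* **Moments.** From all consecutive observation pairs and triples, estimate
  P₁[i] = Pr[xₜ=i], P₂,₁[i,j] = Pr[xₜ₊₁=i, xₜ=j],
  P₃,ₓ,₁[i,j] = Pr[xₜ₊₂=i, xₜ₊₁=x, xₜ=j] and P₃,₁ = Σₓ P₃,ₓ,₁.
  Pairs and triples never span chromosome boundaries; P₁ⁱⁿⁱᵗ is the
  distribution of each chromosome's first segment.
* **SVD.** U = top-K left singular vectors of P₃,₁ (a surrogate for the
  range of the emission matrix O).
* **Observable matrices.** Cₓ = (UᵀP₃,ₓ,₁)(UᵀP₃,₁)⁺. In the population
  limit Cₓ = (UᵀOA) Oₓ (UᵀOA)⁻¹, so all Cₓ share eigenvectors R = UᵀOA and
  the eigenvalues of Cₓ are the emission probabilities O[x,·].
* **Major observations.** For each state i, take the code
  x′ = argmaxₓ U[x,i]² and extract the leading eigenvector of C_{x′}
  (or of the U²-weighted sum of all Cₓ) as column i of R. Emissions follow
  from diag(R⁻¹CₓR); π = O⁺P₁ⁱⁿⁱᵗ; A = (O⁺P₃,₁)(O⁺P₂,₁)⁺, a form that never
  divides by near-zero entries of π. Sign-flip artifacts are repaired by
  absolute value + column renormalization.

The estimate is deterministic, needs no initialization, and can optionally
seed a few EM iterations (`baum_welch_refine`) when maximum-likelihood
polish is wanted. Exact inference (scaled forward–backward, Viterbi,
posterior decoding), a synthetic-genome simulator reproducing the
class-imbalanced regime, and segmentation validation statistics (fold
enrichment, precision/recall, TSS distance, GWAS-SNP enrichment with a χ²
test, MAF/conservation summaries) are included.

## Worked example

```python
import numpy as np
from chromspec import *

# 1. Simulate an imbalanced 4-state genome (90% background), 2 chromosomes.
params = make_imbalanced_params(K=4, M=4, null_mass=0.9, seed=1)
spec = SimulationSpec(params, ["H3K4me3", "H3K4me1", "H3K27ac", "H3K36me3"],
                      chromosome_lengths=[50_000, 50_000], seed=1)
tracks, truth = sample_tracks(spec)

# 2. Spectral estimation from the binarized tracks.
seqs = [encode_observations(m) for m in tracks]
est = spectral_learn(seqs, K=4)

# 3. How close are we to the generating truth?
report = evaluate_recovery(params, est)
print(f"emission max per-column L1 error:   {report['O_col_l1'].max():.4f}")
print(f"transition max per-column L1 error: {report['A_col_l1'].max():.4f}")

# 4. Decode and validate the segmentation.
ann = decode(est, seqs, method="posterior")
agree = np.mean([
    (ann.labels[c] == report["permutation"][truth.labels[c] - 1] + 1).mean()
    for c in ann.labels])
print(f"segment-level agreement with truth: {agree:.3f}")
```

Output:

```
emission max per-column L1 error:   0.0770
transition max per-column L1 error: 0.0671
segment-level agreement with truth: 0.990
```

Hidden states are identifiable only up to relabeling, so
`evaluate_recovery` first matches estimated to true states by emission
similarity (an assignment problem); the errors above are post-matching.
100,000 segments already pin every emission and transition column to
within 0.08 L1 even though 90% of segments carry no marks at all, and the
decoded segmentation labels 99% of segments correctly.

The same workflow is available from the shell:

```bash
chromspec simulate -k 4 -m 4 --segments 50000,50000 --null-mass 0.9 --seed 1 --out sim/
chromspec train    --indir sim/ -k 4 --out model/
chromspec annotate --indir sim/ --model model/model.txt --out ann/
chromspec enrich   --segments ann/segments.bed --features tss.bed --out reports/
```

Input tracks use the two-header-line binarized text format (cell type +
chromosome, tab-separated mark names, then one 0/1 row per 200-bp
segment); segmentations are written as BED.

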