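# Methods

## Model

The data are per-SNP regression outputs from *m* univariate GWAS run on
the same cohort: effect size β, standard error se and p-value for each of
*n* variants, one table per trait. Stacked into the effect matrix
**X** (*m* × *n*, raw β or *z* = β/se), the working model is a linear
mixture

X = A·S + E,

with *K* latent genomic factors: **S** (*K* × *n*) are factor loadings
over SNPs, **A** (*m* × *K*) per-trait mixing weights, and **E** sampling
noise whose per-entry scale is the GWAS standard error. Biologically, a
factor is a set of variants that move together across many traits —
shared pathway, shared tissue, or structured confounding; the model is
agnostic about which.

**PCA** estimates the K-dimensional principal subspace by singular value
decomposition of **X**: `snp_loadings` = top-*K* right singular vectors,
`trait_loadings` = U_K·diag(σ_K), `variance_explained_k` = σ²ₖ/Σσ².

**ICA** assumes the factor rows of **S** are mutually independent and
non-Gaussian (sparse per-variant effects make them super-Gaussian in
practice). The *K* right singular vectors, scaled by √n, already form an
uncentred white basis Z (Z·Zᵀ = n·I); a FastICA fixed-point iteration
with the log-cosh contrast (g = tanh) and symmetric decorrelation finds
the orthogonal rotation W maximising non-Gaussianity. Sources are
S = W·Z (unit root-mean-square rows) and A = U_K·diag(σ_K)·Wᵀ/√n, so
A·S equals the rank-K PCA approximation exactly; PCA and ICA share the
same singular spectrum and variance-explained values.

### Centering and scaling conventions

Two deliberate deviations from generic PCA/ICA practice, both asserted by
tests:

* **No demeaning.** Under the null, SNP effects are symmetric around zero
  (the designation of the effect allele is arbitrary), so the matrix is
  decomposed uncentred. A consequence is that ICA source rows are scaled
  to unit RMS rather than exactly standardised: their means are near zero
  by construction but are not removed, because removing them would break
  the exact A·S reconstruction of the PCA approximation (the uncentred
  singular vectors have O(1/n) row means). An opt-in `center_columns`
  flag exists for sensitivity analysis.
* **No per-SNP variance normalisation.** The magnitude of an allelic
  effect is biological information; columns are never rescaled.

### Determinism, ordering, signs

The SVD is deterministic; ICA is bit-reproducible for a fixed seed
(orthogonalised Gaussian initialisation from `default_rng(seed)`).
Components are ordered by the energy they carry in X (for ICA the
trait-loading column norm, since source rows have unit RMS; for PCA the
singular values). Each SNP-loading row's sign is fixed so its skewness is
positive; when |skewness| < 1e-8 the entry of largest magnitude is made
positive. Convergence is declared when every component direction changes
by less than `tol` (default 1e-6, criterion |1 − |⟨w_new, w_old⟩||) within
`max_iter` = 1000 iterations; up to 5 restarts from fresh random
rotations are attempted before a `ConvergenceError` carrying per-restart
diagnostics is raised. K = 1 ICA is rejected (nothing to unmix); Gaussian
inputs may legitimately fail to converge but never return non-finite
output.

## LD reduction

Nearby SNPs are correlated (linkage disequilibrium), so the raw SNP
dimension is redundant and local correlation would dominate any
decomposition. The front end follows field convention:

1. **Prune** (default r² < 0.3): greedy scan in (chromosome, position)
   order; keep a SNP iff its r² with every previously kept SNP within the
   window is below the ceiling. A windowed criterion (default 1 Mb) is
   used; traversal order makes the rule deterministic and row-order
   invariant.
2. **Clump** on the per-SNP minimum p across all traits (default: lead
   p < 1e-5, window 1 Mb, claim r² > 0.1): candidates in ascending p
   (ties broken by chromosome, position); each unclaimed candidate
   becomes a lead and claims unclaimed same-chromosome neighbours above
   the r² threshold. Members are listed in position order.
3. **Augment** the lead list with externally derived lead SNPs (e.g.
   from disease GWAS clumped at laxer thresholds) — a set union that
   preserves order and reports the novel-addition count.

Because pruning is p-value-blind, the block survivor need not be the
block's most significant SNP; with within-block r² above the claim
threshold, each causal block still yields exactly one lead as long as the
survivor tags the signal strongly enough to pass the lead threshold.

Residual dependence at r² < 0.1 is quantified by an eigenvalue-based
effective-test count: per LD block, M_eff = M − Σ(λᵢ − 1)·1[λᵢ > 1] over
the eigenvalues of the signed correlation matrix (Li–Ji family), summed
over blocks; M_eff ≤ M with equality iff the correlation matrix is the
identity. When an LD source provides only r², √r² is used, which makes
M_eff conservative (an upper bound on dependence).

## Reproducibility testing

Given decompositions of the same SNP set in two non-overlapping samples:

* **Global**: all-pairs Pearson correlations between SNP-loading rows,
  exact t-transform p-values, Bonferroni factor K_a·K_b (all unique
  comparisons). Components are matched one-to-one by maximising Σ|r|
  (linear sum assignment; exhaustive search is the test oracle).
* **Sparse**: loadings are standardised per row and thresholded at > 1
  (one-sided by default, matching the printed convention for z-scaled
  maps; an `absolute` flag gives the two-sided reading). The overlap of
  surviving SNP sets is tested with a two-sided Fisher exact test —
  exact under the working assumption that clumped lead SNPs at r² < 0.1
  are independent — with the same Bonferroni factor.
* **Benchmark**: the per-trait Pearson correlation of effect sizes
  across samples (r_SNP). The headline comparison is each matched
  component's |r| against the mean univariate r_SNP. A post-hoc
  correlation of |trait loading| against the univariate r vector
  (signed mode available) checks whether components are driven by
  reproducible traits.

## Per-SNP loading significance and embedding

Within a component, the bulk of loadings is treated as a Gaussian
reference: p = 2·Φ(−|x − μ|/σ) (two-sided default; one-sided flag), with
μ, σ the component's own loading mean and SD — invariant to affine
rescaling of the loading vector. Joined to SNP coordinates this gives
Manhattan-style tables and plots per component. Trait loadings are
embedded in 2-D by t-SNE (perplexity 30 by default, seed recorded,
deterministic per seed; requires m > 3·perplexity) to visualise
modality clustering.

## Synthetic data

The simulator generates paired discovery/replication summary statistics
with known truth. Choices and defaults:

| parameter | default | meaning / rationale |
|---|---|---|
| `m_traits` | 400 | traits, in 8 modality blocks of 50 (imaging-modality classes) |
| `n_snps` | 3000 | SNPs in LD blocks of `ld_block_size` = 10 |
| `k_true` | 6 | planted factors: 1 global + 5 modality-specific |
| `sparsity` π | 0.02 | P(SNP loads on a factor); spike-and-slab sources are super-Gaussian, so ICA identifiability holds by construction |
| `factor_scale` τ | 0.008 | causal effect SD in trait-SD units per allele; sized so mean univariate cross-sample r lands near 0.1, the weak regime typical of brain-imaging GWAS |
| `noise_sd` σ_e | 0 | extra non-sampling noise on betas (pipeline artifacts); sampling noise is always present |
| `maf_range` | (0.05, 0.5) | uniform MAF; se = 1/√(2·maf·(1−maf)·n_sample) (unit residual trait SD) |
| `n_sample_a/b` | 22000 / 11000 | discovery/replication cohort sizes |
| `within_block_r2` | 0.6 | genotype r² inside an LD block; blocks are 2 Mb apart so default clumping keeps ~1 lead per block |

Marginal (GWAS-observed) effects are the causal effects propagated
through the block at the tagging factor r = √r²; recovery is scored
against the marginal loadings because those are the sources actually
present in the data. Trait loadings follow a deterministic
modality-affinity matrix (global factor at 0.8 everywhere,
modality-specific factors at 1.5 on one block) perturbed per trait by
N(w, 0.1|w| + 0.01). Keeping more modality blocks (8) than specific
factors is essential: otherwise the global pattern is a linear
combination of the specific ones and the mixing matrix is
ill-conditioned, making two factors unidentifiable regardless of
sample size.

A two-seed design separates structure from noise: the factors, loadings
and MAFs derive from the config seed; sampling noise from a separate
noise seed, so a pair shares truth but not noise, like two disjoint
cohorts.

The design point was chosen by a closed-form signal-to-noise argument:
the expected per-trait cross-sample correlation is
v/√((v + se_a²)(v + se_b²)) with v the per-trait signal variance (a
simulator test checks this closed form), while factor detectability
requires the per-factor energy ‖A_k‖²·‖S_k‖² to clear the noise edge of
the singular spectrum (~se²(√m + √n)²) in the smaller sample. The
defaults satisfy both with a wide margin, which is why component
reproducibility (~0.8) exceeds mean univariate reproducibility (~0.08)
by far at this desk scale; on real biobank data the same qualitative
ordering holds with much smaller margins.

What the simulator does **not** emulate: realistic allele-frequency
spectra, population structure, relatedness, LD-correlated noise (noise
is drawn independently per SNP even within LD blocks), cross-trait
phenotypic correlation beyond the shared factors, and heavy-tailed
effect-size distributions. Passing recovery and benchmark tests
therefore demonstrates correctness of the machinery under the stated
generative model, not performance on real cohort data.

## Problem sizes

Unit tests run on matrices of tens of traits by hundreds of SNPs; the
end-to-end property checks use 300–400 traits × 3000–5000 SNPs, the
scale at which the factor structure is comfortably identified while the
full suite completes in about a minute. Oracle-equivalence checks are
exhaustive where feasible (every 2×2 table with total ≤ 30 for the
Fisher test; all permutations up to K = 6 for component alignment; 200
random block-LD instances for prune/clump).

## Known limitations

* Plain SVD replaces a probabilistic PCA noise model; the dimension K is
  user-fixed (chosen by scree inspection), not estimated automatically.
* Allele harmonisation resolves match/swap only; strand flips of
  palindromic (A/T, C/G) variants are indistinguishable from swaps and
  are surfaced as errors rather than guessed.
* The Fisher overlap test treats clumped lead SNPs as independent; the
  effective-SNP count quantifies, but does not correct, the residual
  dependence.
* t-SNE hyperparameters are conventions (perplexity 30), not estimates;
  embedding geometry should be read qualitatively.
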