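# gwasdecomp

Genomic PCA and ICA of multi-trait GWAS summary statistics.

## The problem

A genome-wide association study (GWAS) of one trait yields, for every
genotyped variant (SNP), an estimated per-allele effect size *β*, its
standard error and a p-value. Modern biobanks publish such summary
statistics for thousands of traits at once — for example thousands of
brain imaging-derived phenotypes (IDPs). Because brain traits are highly
polygenic and the underlying variants highly pleiotropic, the effect
sizes of many SNPs co-vary across traits: groups of variants that act
through a shared biological pathway imprint similar association patterns
on many phenotypes. Individual univariate GWAS cannot see this structure,
and their per-SNP estimates replicate poorly between independent samples.

`gwasdecomp` treats the stacked summary statistics as a single
*m* traits × *n* SNPs effect matrix **X** (raw *β* or standard-error-scaled
*z* = *β*/se) and decomposes it along the SNP dimension into *K* latent
genomic components:

```
X  ≈  A · S
```

where **S** (*K* × *n*) holds the SNP loadings of each component (a
"genomic factor": which variants move together) and **A** (*m* × *K*)
holds the trait loadings (which phenotypes each factor drives). PCA takes
the top-*K* right singular vectors of **X**; ICA rotates that subspace by
a FastICA fixed-point iteration (log-cosh contrast, symmetric
decorrelation) so the rows of **S** become maximally non-Gaussian, i.e.
statistically independent sparse sources. Two GWAS-specific conventions
are enforced: the matrix is **not demeaned** (effect sizes are already
centred on zero under the null, because the effect-allele direction is
arbitrary) and SNP columns are **not variance-normalised** (the magnitude
of allelic effects is biological signal).

Around the decomposition the package provides:

- **`gwasdecomp.io`** — reading and harmonising per-trait summary
  statistics (allele alignment with sign flips, −log10 p support,
  strict/lenient missing-SNP policy) and assembling/serialising the
  effect matrix;
- **`gwasdecomp.clumping` / `gwasdecomp.ld`** — LD pruning and
  min-p-across-traits clumping (PLINK-style greedy rules; defaults: prune
  r² < 0.3, 1 Mb window, lead p < 1e-5, clump r² > 0.1), lead-SNP
  augmentation from external disease GWAS, and an eigenvalue-based
  effective-independent-SNP count; LD can come from a square matrix, a
  PLINK-style long table, or a genotype dosage matrix;
- **`gwasdecomp.reproducibility`** — inter-sample component
  reproducibility (all-pairs Pearson correlations of SNP loadings with
  Bonferroni correction, optimal component matching, Fisher exact tests
  of thresholded-loading overlap) benchmarked against the per-trait
  univariate reproducibility r_SNP;
- **`gwasdecomp.loading_stats` / `gwasdecomp.embedding`** — per-SNP
  loading significance from the component's own normal reference
  (Manhattan-style tables/plots) and t-SNE embedding of trait loadings;
- **`gwasdecomp.simulate`** — a paired discovery/replication GWAS
  simulator with planted spike-and-slab factors, modality-structured
  trait loadings, block LD and MAF-dependent standard errors, plus ground
  truth for recovery scoring.

## Worked example

Simulate a discovery/replication pair of 400 imaging-trait GWAS sharing
six latent genomic factors, decompose both z-matrices at K = 6, and
benchmark component reproducibility against the univariate GWAS:

```python
import gwasdecomp as gd

cfg = gd.SimConfig(seed=0)                   # 400 traits x 3000 SNPs, K_true=6
pair = gd.simulate_pair(cfg)
Xa = pair.effect_matrix("a", "z_value")      # discovery (n = 22,000)
Xb = pair.effect_matrix("b", "z_value")      # replication (n = 11,000)

res_a = gd.GenomicICA(Xa).fit(6, seed=0)
print(res_a.summary())

res_b = gd.GenomicICA(Xb).fit(6, seed=0)
report = gd.benchmark_report(res_a, res_b, Xa, Xb)
print(report.summary_text())
```

```
Genomic ICA decomposition
============================================
traits (m):      400    SNPs (n):     3000    components (K): 6
input mode: z_value    column centering: False
ICA iterations: 9 (seed=0)
--------------------------------------------
comp  var_explained   cum_var     |A_k|
   1        0.04821    0.0482    4.1409
   2        0.02384    0.0720    3.2546
   3        0.02330    0.0953    3.1738
   4        0.01861    0.1140    3.1083
   5        0.01169    0.1256    2.8181
   6        0.00726    0.1329    2.1847
--------------------------------------------
variance explained by K=6 subspace: 0.1329

Inter-sample reproducibility report
==============================================
components: 6 matched pairs
  matched |r|: max 0.8464  mean 0.7904
univariate GWAS (n traits = 400):
  r: max 0.2183  mean 0.0817  sd 0.0527
components beating mean univariate r: 6/6
```

Reading this: the six planted factors each explain 0.7–4.8 % of the total
SNP-effect variance (`var_explained` is σ²ₖ/Σσ²; the weak per-component
fractions reflect the dominance of sampling noise in per-SNP GWAS
estimates). After optimally matching components across the two
independent samples, every component's SNP-loading correlation
(mean |r| = 0.79) far exceeds the mean per-trait univariate
reproducibility (r = 0.082) — the decomposition pools pleiotropic signal
that the univariate GWAS leave buried in noise.

The same pipeline is scriptable from the shell:

```bash
gwasdecomp run --config config.yaml     # simulate -> decompose -> reproduce
gwasdecomp simulate --out-dir sim --seed 0
gwasdecomp clump --stats-dir sim/sample_a --ld-matrix ld.tsv --out leads.tsv
gwasdecomp decompose --matrix effects_a --method ica --dim 10 --seed 0 --out ica_a
gwasdecomp plot --decomp ica_a --what manhattan --component 1 --out c1.png
```

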