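# Methods

## The model

`omifuse` discovers tumor subtypes by clustering patients on a fused
similarity matrix built from several omics layers (gene expression, isoform
expression, DNA methylation) measured on the same cohort. The pipeline is:

1. **Min–max rescaling.** Each feature is mapped to [0, 1] via
   `x' = (x − min x)/(max x − min x)`, with the extrema taken per feature
   across samples. This puts layers with very different dynamic ranges
   (RSEM abundances vs. methylation levels) on a common scale before any
   kernel is computed. Constant features map to all-zeros (with a logged
   warning) rather than being dropped, so feature indices stay stable.
2. **Kernel PCA per layer.** The sample Gram matrix of the cubic polynomial
   kernel `K(x_i, x_j) = (x_iᵀx_j + 1)³` is centered in feature space
   (`K' = K − 1ₙK − K1ₙ + 1ₙK1ₙ`, `1ₙ` the matrix of `1/n`) and
   eigendecomposed. All components with eigenvalue above a relative
   tolerance are retained and each sample is represented by the eigenvector
   entries scaled by `√λ`, so pairwise score distances reproduce the
   centered-kernel-induced distances. This reduces tens of thousands of
   features to at most `n − 1` score dimensions.
3. **Gaussian similarity kernels.** Per layer,
   `K(x_i, x_j) = exp(−γ‖x_i − x_j‖²)` over the KPCA scores. Each layer gets
   its own bandwidth.
4. **Average fusion.** The layer kernels are combined entrywise,
   `K_fuse = (K_gene + K_isoform + K_methyl)/3` by default; arbitrary convex
   weights are accepted. A convex combination of positive semidefinite
   matrices is positive semidefinite, so the fused matrix remains a valid
   kernel.
5. **Normalized spectral clustering.** With degree matrix `D` (row sums of
   `K_fuse`), the symmetric normalized Laplacian
   `L_sym = D^{−1/2}(D − K_fuse)D^{−1/2}` is eigendecomposed; the
   eigenvectors of its `k` smallest eigenvalues, row-normalized to unit
   length, embed the samples, and k-means on the embedding gives the
   partition. This is the standard relaxation of the trace minimization
   `min tr(YᵀL_sym Y)` subject to `YᵀY = I`.
6. **Evaluation.** A subtype partition is validated by how well it separates
   survival: the k-group log-rank test (the score test of a Cox model with
   group indicators) yields the headline p-value; Kaplan–Meier curves are
   written per cluster. Against known labels, agreement is measured by the
   Rand index and the Hubert–Arabie adjusted Rand index. The conventional
   0.05 threshold is a reporting annotation only — nothing inside the
   pipeline filters on it.

When `k` is not known, `select_k` scans a range (default 2–10 in the CLI),
clusters at each `k`, and picks the partition with the lowest log-rank
p-value, breaking ties toward the smaller `k`.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| polynomial degree | 3 | exponent of the KPCA kernel `(xᵀy + 1)³`; coefficient-free (slope 1), a scaled slope is available but not default |
| `eigval_tol_ratio` | 1e-10 | eigenvalues above this fraction of the largest are "non-zero" and kept |
| `gamma` | `"median"` | Gaussian bandwidth; the median heuristic sets `γ = 1/median(nonzero pairwise squared distances)` per layer, adapting to each layer's score scale; a fixed positive value may be supplied |
| fusion weights | equal (`1/m`) | convex weights over layer kernels |
| `n_restarts` | 20 | k-means restarts (k-means++ init); best inertia wins |
| `seed` | — | one seed drives every random draw through a spawned seed tree (one stream for the simulator, one for k-means); identical configs reproduce byte-identical artifacts |

## Cohort harmonization

Sample matching across layers and the clinical table uses the case-level
TCGA barcode prefix (first three dash-delimited fields). Only tumor samples
(sample-type codes 01–09, parsed from the fourth barcode field) are kept by
the filter step. When a case has several aliquots inside one input, the
lexicographically smallest full barcode wins — a deterministic convention,
not a claim about how any published cohort was collapsed. The harmonized
bundle's shared id for a case is the smallest full barcode observed in any
expression layer, so sample-type codes survive harmonization and
tumor-filtering commutes with it. Cases with missing survival time are
dropped at harmonization with a logged warning, since survival separation is
the primary evaluation.

## The synthetic cohort generator

Real multi-omics cohorts cannot be bundled, so the generator plants known
structure: `k` subtypes of near-equal size; per layer, `n_signal` features
whose subtype means are a random distinct assignment of
`{0, δ, 2δ, …, (k−1)δ}` and the rest pure noise; Gaussian noise of sd `σ`
everywhere; a per-layer shift making all abundances non-negative (as in
RSEM/beta-value data — tests on raw values must account for this shift).
Survival times are exponential with a subtype-specific hazard; censoring
times are independent `Uniform(0, q)` with `q` solved numerically so the
expected censored fraction equals `censor_rate`. Layers share the planted
labels but draw independent noise, so weakening `δ` per layer makes the
benefit of kernel fusion directly measurable.

Default study conditions: `n = 150`, `k = 3`, three layers of 200 features
with 30 signal features each, `δ = 1.0`, `σ = 0.5`, hazards
0.002/0.004/0.008 events/day (median survival roughly 347/173/87 days —
plausible spread for aggressive vs. indolent subtypes), 20% expected
censoring. Under these conditions the full pipeline recovers the planted
subtypes essentially perfectly (ARI ≈ 1) and the survival scan selects the
planted `k`. The weak-signal regime used to demonstrate the fusion benefit
lowers `δ` to 0.3, where each single layer alone clusters poorly
(mean ARI ≈ 0.6) while the fused kernel still recovers the subtypes
(mean ARI ≈ 0.99).

What the generator does **not** emulate: real marginal distributions of
expression data, batch effects, methylation beta bimodality, correlated
noise between layers, or non-proportional hazards. Passing tests therefore
show the pipeline's correctness and its behavior under idealized planted
structure, not performance on real tumors.

## Numerical choices

- Eigendecompositions are dense (`scipy.linalg.eigh`); cohorts are at most a
  few hundred samples, so the `n × n` path is exact and fast. No sparse or
  approximate solvers.
- Eigenvector sign is fixed by making the largest-magnitude entry of each
  eigenvector positive; k-means labels are relabeled 1..k by first
  occurrence. Both make outputs reproducible; labels carry no semantic
  order.
- Kernel centering is applied before the KPCA eigendecomposition (PCA in
  feature space requires centered features); an off-switch exists for
  strict-literal replication of uncentered variants.
- Zero-norm embedding rows (possible for a near-isolated sample) are left
  unnormalized, flagged in logs, and clustered by their raw coordinates.
- Kaplan–Meier ties: deaths at a time are processed before same-time
  censorings (both remain in the risk set for that time).
- Degenerate adjusted Rand case (both partitions a single identical
  cluster): defined as 1, the standard convention.
- The log-rank p-value is the chi-square upper tail of the k-group score
  statistic at `k − 1` df; an optional Cox partial-likelihood ratio test
  (`cox_test`) is provided for users wanting a literal Cox regression
  p-value — same asymptotics, occasionally different convergence behavior.

## Design choices where the design was open

- Min–max normalization is per feature across samples (not per sample):
  the goal is removing scale differences between platforms, which live on
  the feature axis.
- The Gaussian bandwidth uses the per-layer median heuristic by default
  because KPCA score scales differ between layers; fixed `γ` is accepted for
  replication attempts, and the value actually used is always recorded in
  the run log and kernel sidecar.
- Kernels are computed on KPCA scores, not raw expression — the pipeline
  order is represent → construct → fuse → cluster.
- Spectral clustering takes the *smallest* eigenvalues of `L_sym`
  (Laplacian/minimization convention); the maximization convention on the
  normalized affinity spans the same subspace.
- The k-means discretization uses 20 restarts with a fixed seed; stated,
  logged, configurable.

## Problem sizes

Tests and the acceptance script run the pipeline on cohorts of 60–150
samples with 80–200 features per layer, 10-cohort replications for the
fusion-benefit contrast, 500 replicates for null calibration of the log-rank
test, and 10,000 permutations for the chance-correction check of the ARI.
These sizes give stable estimates of every reported quantity while keeping a
full run in well under a minute per cohort.

## Known limitations

- No out-of-sample KPCA projection: the embedding is transductive, for one
  cohort at a time.
- No iterative cross-diffusion fusion (SNF-style message passing); fusion is
  deliberately a plain (weighted) average.
- No multivariate Cox adjustment for clinical covariates, no interval
  censoring.
- Dense `O(n²)`–`O(n³)` memory/compute limits cohorts to a few thousand
  samples.
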