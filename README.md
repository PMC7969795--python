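# omifuse

Multi-omics kernel fusion for cancer subtype discovery.

Tumors of one anatomical site are rarely one disease: molecularly distinct
subtypes respond differently to treatment and carry different prognoses.
`omifuse` is a library + CLI for finding such subtypes by integrating several
omics layers measured on the same patients — typically gene expression,
isoform expression, and DNA methylation — and validating the resulting
patient groups against survival. It is aimed at computational biologists
working with Firehose/TCGA-style expression matrices, and it ships a
synthetic-cohort generator with planted subtypes so the entire pipeline is
testable without any data download.

## The method

For each omics layer, with features min–max rescaled to [0, 1]:

1. **Kernel PCA** with the cubic polynomial kernel
   `K(xᵢ, xⱼ) = (xᵢᵀxⱼ + 1)³` — the centered Gram matrix is eigendecomposed
   and all components with non-negligible eigenvalues are kept, giving each
   sample a low-dimensional score vector.
2. **Gaussian similarity kernel** over the scores,
   `K(xᵢ, xⱼ) = exp(−γ‖xᵢ − xⱼ‖²)`, with γ set per layer by the median
   heuristic (or fixed by the user).
3. **Average fusion**: `K_fuse = (K_gene + K_isoform + K_methyl)/3` —
   a convex combination of PSD kernels, hence itself a valid kernel.
4. **Normalized spectral clustering**: with degree matrix `D`, the
   eigenvectors of the `k` smallest eigenvalues of
   `L_sym = D^{−1/2}(D − K_fuse)D^{−1/2}` are row-normalized and clustered
   by k-means, yielding subtype labels 1..k.
5. **Validation**: the k-group log-rank p-value (the Cox score test for a
   categorical subtype covariate) measures survival separation; Kaplan–Meier
   curves are written per cluster; Rand index and adjusted Rand index score
   agreement with reference labels when available. When `k` is unknown, a
   scan picks the `k` with the lowest p-value.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Run the full pipeline on the default synthetic cohort — 150 patients, 3
planted subtypes, three layers of 200 features, subtype hazards
0.002/0.004/0.008 events/day, 20% censoring:

```sh
$ omifuse run --simulate --k 3 --seed 7
{
  "adjusted_rand_index": 1.0,
  "k": 3,
  "logrank_df": 2,
  "logrank_statistic": 12.587680738266448,
  "n_samples": 150,
  "p_value": 0.001847650643917429,
  "rand_index": 1.0,
  "significant_at_0.05": true
}
```

Reading the numbers: the recovered 3-cluster partition matches the planted
subtypes exactly (`adjusted_rand_index` = 1.0 — chance level would be ≈ 0),
and the clusters separate survival (log-rank χ² = 12.59 on 2 df,
p ≈ 0.0018 < 0.05), as expected when the planted subtypes carry different
hazards. Add `--out results/` to write the assignment, per-layer and fused
kernels, per-cluster Kaplan–Meier tables, and a run log with every resolved
parameter (γ per layer, retained components, seeds).

The same pipeline runs on real Firehose-style TSVs:

```sh
omifuse run --gene G.tsv --isoform I.tsv --methyl M.tsv \
            --clinical C.tsv --k-range 2..10 --seed 0 --out results/
```

Samples are matched across files on the case-level barcode prefix, only
tumor aliquots (sample-type codes 01–09) are kept, and `--k-range` scans
cluster counts and selects the one with the lowest log-rank p-value.
Subcommands `simulate`, `cluster`, `scan-k`, and `evaluate` expose the
individual stages; all intermediates are TSV/JSON. The library API
(`omifuse.simulate_cohort`, `kpca_fit_transform`, `gaussian_kernel`,
`fuse_kernels`, `spectral_cluster`, `logrank_test`, …) mirrors the same
steps; everything is driven by YAML configs or keyword arguments.

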