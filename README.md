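# neighborhood-nmf

Spatially smoothed Poisson nonnegative matrix factorization for spatial
transcriptomics (and any nonnegative count data with 1D/2D/3D locations).

## The problem

Spatial transcriptomics assays measure a count matrix **V** (N cells or spots
× M genes) together with a location **x_i** for every cell. Standard NMF
decomposes **V ≈ W H** into K *gene signatures* (rows of **H**, nonnegative
weights over genes, constrained to sum to one) and their per-cell *activity
landscapes* (columns of **W**), but ignores where the cells sit. Hard spatial
clustering methods, conversely, assign each cell a single discrete label and
lose the overlapping, graded structure of real tissue.

Neighborhood NMF keeps the full factorization — a *soft* clustering in which
every cell carries a weight for every signature — while making nearby cells
share correlated signature activity. Counts are modeled as
V ~ Poisson(WH), fitted by minimizing the generalized Kullback–Leibler
divergence

    D(V‖WH) = Σ_{nm} [ V_nm log V_nm − V_nm log (WH)_nm − V_nm + (WH)_nm ],

and each iteration interleaves the standard multiplicative updates with a
Gaussian-kernel smoothing of the weights:

    H ← rnorm( H ⊗ (Wᵀ (V ⊘ WH)) )
    W ← W ⊗ ((V ⊘ WH) Hᵀ)
    W ← rnorm(S_φ(X)) W,        (S_φ(X))_ij = exp(−‖x_i − x_j‖² / φ²)

where `rnorm` rescales rows to sum to one. The smoothing step replaces every
cell's weight vector by a neighborhood average at length scale φ, which is
estimated from the data by a leave-self-out prediction grid search. The
number of signatures K is chosen by AIC = 2·D(V‖WH) + 2·(NK + KM). For
large or multi-slice data the kernel is built per spatially compact batch
(or per slice), bounding memory at the sum of squared batch sizes instead
of N².

Interpretation tools: TF-IDF-style reweighting
`H_ki · log(1 + H_ki / max_{j≠k} H_ji)` surfaces genes unique to each
signature; K-means on the rows of **W** yields hard cluster labels that use
the full soft-clustering profile of each cell; fold enrichment relates
signatures to cell-type annotations.

## Worked example

The package ships a generator that samples exactly the model it fits —
spatially smooth activity fields, sparse Dirichlet signatures, Poisson
counts — with the ground truth kept alongside:

```bash
nnmf simulate --n 1500 --m 120 --k 4 --phi-true 0.08 --seed 1 --out sim/
nnmf fit --counts sim/V.mtx --coords sim/coords.tsv --k 4 --phi 0.08 \
     --seed 1 --out fit/
nnmf report --fit-dir fit/ --out report/
```

The `fit` command prints a one-line summary:

```
fit K=4 phi=0.08 GKL=74100.2 iters=249 converged=True -> fit/
```

meaning the fit converged after 249 iterations at a generalized KL divergence
of ~74,100 between the counts and their rank-4 reconstruction. `fit/`
contains `W.tsv` (cells × signatures weights), `H.tsv` (signatures × genes,
rows summing to one), `meta.json` (φ, K, seed, tolerance, GKL trace),
`batches.tsv`, `labels.tsv` (1-based top-signature and K-means labels) and
`top_genes.tsv` — the per-signature gene ranking by rescaled weight, carrying
both the original and the rescaled weight for every listed gene. Comparing
the fitted signatures against the generator's truth in Python:

```python
from neighborhood_nmf import simulate_spatial_counts, fit_nnmf, match_signatures
ds = simulate_spatial_counts(seed=1)          # N=1500, M=120, K=4, phi=0.08
res = fit_nnmf(ds.V, ds.X.X, K=4, phi=0.08, seed=1)
perm, sims, mean_sim = match_signatures(res.H, ds.H_true)
print(round(mean_sim, 3))                     # 0.993
```

a mean cosine similarity of 0.993 between the fitted and planted gene
signatures after optimal matching.

Other subcommands: `nnmf select-phi` (length-scale grid search, writes the
error curve), `nnmf select-k` (AIC scan over `--k-grid 2:7`).

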