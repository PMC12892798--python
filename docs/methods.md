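# Methods

## Model

Counts are modeled as independent Poisson draws, `V_nm ~ Poisson((WH)_nm)`,
with `W ∈ R_{≥0}^{N×K}` the per-cell signature weights and
`H ∈ R_{≥0}^{K×M}` the gene signatures. The rows of `H` are constrained to
sum to one, which removes the multiplicative scale ambiguity of NMF and makes
each row a distribution over genes; the row sums of `W` then carry the cells'
total expression. Maximizing the Poisson likelihood is equivalent to
minimizing the generalized Kullback–Leibler divergence `D(V‖WH)` (with the
convention `0·log 0 = 0`).

Each fitting iteration applies, in order,

1. `H ← rnorm(H ⊗ (Wᵀ (V ⊘ WH)))`
2. `W ← W ⊗ ((V ⊘ WH) Hᵀ)`
3. `W^b ← rnorm(S^b_φ) W^b` for every batch `b`,

where `S_φ(X)_ij = exp(−‖x_i − x_j‖²/φ²)` (note the denominator is `φ²`, not
`2φ²`). Steps 1–2 are the multiplicative Poisson-NMF updates under the
row-sum constraint; because the rows of `H` sum to one, the usual denominator
of the `W` update is identically one, and the `H` update's row normalization
plays the role of its denominator. The pair is an expectation–maximization
scheme for the equivalent multinomial mixture parameterization, so without
smoothing the GKL objective is non-increasing; the test suite asserts this to
1e-8 per step. Step 3 replaces every weight vector by a convex combination of
its spatial neighbors' vectors; it is not a descent step for the GKL, so the
objective can rise transiently after smoothing, and the convergence check
monitors relative change of the objective (evaluated after the smoothing
step) rather than monotone decrease.

Elementwise ratios use `0/0 = 0`, implemented by dividing only where
`V > 0`, which also preserves exact zeros of `W` and `H` under the
multiplicative updates. A positive count over a zero reconstruction
(`V_nm > 0`, `(WH)_nm = 0`) raises an error rather than being clamped: it
means the model has collapsed and the divergence is infinite. `rnorm` maps
an all-zero row to an all-zero row; the fitting layer reports such dead
signatures (the fit's *effective rank*) instead of silently reviving them.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `K` | — | number of signatures; chosen by AIC when scanned |
| `phi` | estimated | kernel length scale, in coordinate units; `0` disables smoothing |
| `tol` | 1e-6 | stop when `|ΔGKL| / max(GKL, 1) < tol` |
| `max_iter` | 1000 | iteration cap; hitting it sets `converged=False`, no exception |
| `n_init` | 3 | warm-start restarts (plain NMF, best GKL wins) |
| `warm_iter` | 100 | plain-NMF iterations per warm-start run |
| `smooth_every` | 1 | apply the smoothing step every n-th iteration |
| `kernel_cutoff` | auto | sparse truncation radius in units of `phi` |

**Warm start.** The multiplicative updates find local optima, so the fit is
initialized with the best (smallest GKL) of `n_init` independent plain-NMF
runs of `warm_iter` iterations from uniform(0, 1) starts; `H` is row-
normalized immediately after the warm start, before the first smoothed
iteration. Fewer than three restarts triggers a warning. All randomness
flows through a single integer seed; two runs with the same seed and inputs
are bitwise identical.

**Length scale.** `φ` is estimated by a grid search minimizing the
leave-self-out neighborhood prediction error `‖V − rnorm(S_φ − I) V‖²`
(squared residuals). A literal signed-residual mode is available
(`mode="literal"`), but positive and negative residuals cancel there and the
curve is nearly flat, so squared error — the natural reading of "predict each
cell from its neighborhood" — is the default. Error ties break toward the
smaller φ. Once selected, φ is held fixed for the analysis.

**AIC.** `AIC(K) = 2·D(V‖WH) + 2·(NK + KM)`, computed on the smoothed fit's
factors (the fitted `W, H` are what the criterion scores). The rank scan
shares one warm-start seed family across K so AIC differences reflect K, not
initialization luck; ties break toward the smaller K.

**Batching.** For multi-slice data each slice is its own batch (kernels
never couple cells across slices); for single large slices,
`build_batches_groupondist` repeatedly picks a random unassigned anchor and
groups it with its nearest unassigned neighbors until fewer than a batch
remain (the last, smaller batch). Distance ties break by cell index, making
the partition deterministic given its seed. Smoothing with a single batch is
bitwise identical to unbatched smoothing. Batch partitions are strict; the
stored kernel entries drop from `N²` to `Σ_b N_b²` (e.g. a 50,627-cell slice:
2,563,093,129 entries as one batch, 1,282,581,925 split 24,594 + 26,033).
Kernels for batches above 6,000 cells are truncated at distance `3φ`
(dropped entries are below `e⁻⁹ ≈ 1.2e-4` before row normalization) and
stored sparse; smaller batches use the exact dense kernel. For 3D multi-slice
data the z coordinate must be expressed in the same unit as x and y before
fitting — e.g. a slice depth recorded in mm must be rescaled to match micron
xy coordinates; the CLI documents this and offers `--align-slices` (shift
each slice to a common min-x / max-y origin) as optional preprocessing, but
the library does not own registration.

**Interpretation.** Gene reweighting uses
`H_ki · log(1 + H_ki / max(max_{j≠k} H_ji, ε))` with `ε = 1e-12` flooring the
competitor maximum (a gene absent from every other signature gets a large,
finite boost). The reweighting is applied to the signature matrix `H`: it is
a per-gene contrast across signatures, and the ranked tables report both the
original and rescaled weight. K-means on the rows of `W` (k-means++ seeding,
best of 10 restarts) yields hard labels; all text outputs number signatures
and clusters from 1. Fold enrichment of a cell type within a signature is
the type's share of the signature's weight mass over the type's overall
frequency, computable from soft weights (default) or hard argmax labels; its
type-frequency-weighted mean is exactly 1 per signature.

## Synthetic data

`simulate_spatial_counts` samples the model itself: cells uniform on
`[0,1]^d`; K latent fields built by smoothing white noise with the
row-normalized Gaussian kernel at a known `phi_true`, standardized to a
log-scale standard deviation `field_sd` and exponentiated; signature rows
from a symmetric Dirichlet (`sparsity`, default 0.1 — sparse, well-separated
gene programs); `W` scaled so the mean per-cell depth is `mean_depth`; counts
Poisson. The exponential link keeps activities strictly positive and
right-skewed like real expression; `field_sd = 0.5` gives roughly a
sevenfold activity contrast between high- and low-activity regions, a
moderate domain contrast under which the length-scale scan's error curve
attains its minimum within a factor of two of `phi_true`. (Stronger
contrasts push the leave-self-out optimum toward smaller neighborhoods: at
the default geometry — 1,500 cells on the unit square, `phi_true = 0.08` —
the nearest-neighbor spacing is only about four times smaller than the field
scale, so with high-amplitude fields the bias term dominates early and the
scan prefers sub-`phi` neighborhoods.)

What passing recovery tests on this generator shows: the fitting machinery
identifies the planted factors and length scale when the model is correct.
What it does not show: robustness to segmentation errors, doublets,
overdispersion beyond Poisson, platform-specific capture bias, or
misaligned slices — none of which the generator emulates.

## Problem sizes and numerical choices

Recovery checks run at N = 1,500 cells, M = 120 genes, K = 4,
`phi_true = 0.08`, depth 200 (10 seeds for signature recovery; 10 replicates
for the AIC scan over K = 2..7); the planted-domain labeling comparison uses
800 cells, 6 Voronoi domains over 4 signatures, 5 seeds. Dense kernels are
exact; matching of estimated to true signatures uses the Hungarian algorithm
on cosine similarity (exact for all K). Degenerate inputs: all-zero count
rows stay all-zero through the updates without NaN; a cell isolated at tiny
φ in the length-scale scan gets a zero prediction and a logged warning;
coincident cells give kernel entries of exactly 1.

## Known limitations

- The smoothing step has no step-size control; at very large φ it can
  over-shrink the weight field toward its mean before the multiplicative
  updates compensate.
- AIC with `n_prm = NK + KM` counts every entry of `W` and `H` as a free
  parameter, ignoring the row-sum constraint on `H` and the effective
  smoothing-induced shrinkage of `W`; it is used as a relative, not an
  absolute, criterion.
- Overlapping batches are not supported: partitions are strict. An overlap
  would make the per-batch smoothing updates mutually inconsistent, and no
  reconciliation rule is defined here.
- The literal signed-residual mode of the length-scale scan is retained for
  completeness but is not a usable objective (residual cancellation).
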