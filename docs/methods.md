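# Methods

## The model

PCA of a peak-picked MSI cube `X` (N spectra × F peaks) is the SVD of the
column-centered matrix `X_c = X − 1μᵀ`: scores `U Σ` and loadings `V`
with `X_c = U Σ Vᵀ`. `msipca.fit` computes the same decomposition
incrementally, never holding more than one batch of `d` rows in memory.

Per batch the update is the sequential Karhunen–Loève step:

1. Running moments. With `N` rows seen, mean `μ` and squared-deviation
   accumulator `m2`, a batch with column mean `μ_b` and within-batch
   squared deviations `m2_b` pools as
   `μ' = (Nμ + dμ_b)/(N+d)` and
   `m2' = m2 + m2_b + (μ − μ_b)² · Nd/(N+d)` (the Chan pooled update,
   exact in exact arithmetic).
2. Center the batch by its own mean: `X_cb = X − 1μ_bᵀ`.
3. Stack `A = [diag(s)·V ; X_cb ; c]` where the single correction row
   `c = √(Nd/(N+d)) · (μ − μ_b)` carries the between-batch mean shift.
   On the first batch `A = X_cb`.
4. Thin SVD of `A`; keep the top-k singular values and right singular
   vectors as the new `s`, `V`.

After the last batch, `explained_variance_i = s_i²/(N−1)` and
`explained_variance_ratio_i = explained_variance_i / Σ_f m2_f/(N−1)`,
clamped to [0, 1]. Both numerators and the total use the `N−1`
denominator, so at `k = F` the ratios sum to exactly 1 in exact
arithmetic; a zero-variance cube reports ratio 0, not NaN.

The transform streams `(X − μ)·Vᵀ` batch by batch to a float32 score
file at matching row offsets. With `concurrency > 1`, batches are
computed in waves of that many worker threads; each batch's arithmetic
(float32 GEMM with fixed summation order) is unchanged, so the output is
bitwise identical to the sequential run and peak memory scales with the
concurrency level.

### Assumptions and complexity

Rows are exchangeable for the purposes of the moments (no weighting);
the update is order-dependent only at float32 rounding level, which the
batch-size-robustness tests bound at 1e−3 relative on singular values.
Per iteration the SVD of the (k+d+1) × F stack costs O(d·F²) time and
O(d·F) space; total fit memory is O(d·F + k·F), independent of N.

## Parameters

- `batch_size` (d), default `min(19·F, N)`. The 19×-peaks heuristic is
  the package default for fitting throughput; it always satisfies the
  first-batch feasibility requirement d ≥ k when k ≤ F. Exposed
  everywhere as a parameter.
- `k`, default F (all components). The first batch must have at least k
  rows; if the requested batch size is smaller, only the first batch is
  silently enlarged to k rows and later batches keep the planned size.
- `fraction`, default 0.065: the pixel fraction of the subsampling
  comparator (uniform, without replacement, seeded). The subsample's own
  mean centers all pixels at transform time.
- `tolerance` (+ unit, Da or ppm): imzML binning half-window. Centroids
  in overlapping windows go to the nearest peak center, ties to the
  lower index; overlap triggers a warning, not an error.

## Numerical choices

- Batch data, the SVD input, loadings and scores are float32 (halves RAM
  and speeds vectorized kernels). The accumulators `N`, `μ`, `m2` are
  float64: float32 accumulation of integer-scale counts degrades beyond
  ~1.6×10⁷ rows, and cubes of 2.5×10⁸ spectra are in scope; the cost is
  two float64 rows.
- Sign convention: each loading row's largest-|entry| element is made
  positive (ties to the lowest feature index). Any fixed convention
  works because comparisons sign-align first (`align_signs`: flip
  components with negative dot against the reference).
- r² is the squared Pearson correlation of two loading vectors —
  symmetric and scale-free, which is how it is used (a similarity, not a
  regression fit). A zero-variance vector makes r² undefined; it is
  reported as missing (NaN) and excluded from group means, never as 0.
- Degenerate cases: all-constant cubes give zero singular values and
  zero ratios; tied singular values keep SVD output order; the last
  partial batch is processed as-is (the stack always has ≥ k+1 rows).
- Byte order is fixed little-endian and declared in the sidecar; the
  reader rejects any cube whose binary length differs from
  `n_spectra × n_peaks × 4`.
- The batch reader reopens the file for each batch and returns a fresh
  array, so consumed batches are immediately reclaimable; the memory
  contract is stated as peak resident footprint, not mechanism.

## Synthetic data

The generator emulates what a peak-picked MSI cube looks like to PCA:
`X = b + Σ λ_i u_i v_iᵀ + σ ε` with spatially smooth per-region pattern
vectors `u_i` (Gaussian random fields low-pass filtered at ~1/8 of the
region's short side, mean-centered, then QR-orthonormalized), orthonormal
loadings `v_i`, geometric spectrum `λ_i = λ₀ γ^(i−1)`, and i.i.d. Gaussian
noise. Centering `u_i` before orthonormalization makes the per-feature
variance decompose exactly as `Σ λ_i² v_if²/(N−1) + σ²`, which the law-of-
large-numbers test checks at 5%.

Defaults, chosen once as realistic MSI-like conditions: σ = 1 (unit
noise), baseline b = 3σ so most intensities are positive without
clipping (clipping would distort the planted covariance; PCA does not
need nonnegativity), λ₀ = 20σ√N so the leading pattern is strong and
γ = 0.7. The accuracy-study cube is 50,000 × 100, rank 15, γ = 0.7,
seed 42. What the generator does **not** emulate: raw profile spectra,
isotope envelopes, peak-picking artifacts, Poisson counting statistics,
or intensity-dependent noise — so passing tests demonstrate algorithmic
correctness on low-rank-plus-noise structure, not robustness to every
real-detector artifact.

## Benchmark instrumentation

Resident memory is sampled from `/proc/<pid>/statm` every 15 ms in a
background thread; a resting baseline taken before the workload is
subtracted from the in-flight peak (Linux-only by construction). Wall-
clock RSS depends on hardware and allocator behavior, so the asserted
memory contracts use `tracemalloc` peak allocations instead, which are
deterministic: fit peaks must be flat (±25%) across cube lengths at a
fixed batch size and proportional (±25% of the expected factor) across
batch sizes. RSS traces are exercised for smoke and monotonicity only.

## Problem sizes used in validation

The test suite and examples run on synthetic cubes between 100 × 5 and
100,000 × 40, with the accuracy benchmark at 50,000 × 100 — sizes chosen
so the dense oracle comparisons stay cheap while every out-of-core code
path (multi-batch fits, partial last batches, enlarged first batches,
threaded transforms, multi-region rendering) is exercised. The format
arithmetic is additionally checked against multi-hundred-megabyte and
~34 GB cube geometries without materializing them.

## Known limitations

- Profile-mode (non-centroided) data and peak picking are out of scope;
  cubes arrive peak-picked.
- No whitening, randomized-SVD, or single-row online PCA variants.
- `exact_pca` and `subsampled_pca` deliberately load the whole cube;
  they are comparators, not production paths.
- The RSS sampler requires a Linux `/proc` filesystem.
- Scores/loadings stored as float32 limit agreement between
  implementations for trailing, near-noise components; this is inherent
  to the 32-bit pipeline, not to the incremental update.
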