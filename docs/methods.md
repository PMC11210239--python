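# Methods

## Model and assumptions

Two omics blocks `X (n×p)` and `Y (n×q)` share `n` samples.  Both are
column-standardized (z-score per feature, population sd; constant columns
are dropped with a warning) — the covariance objective, the Z-score
membership rule and the profile distances all assume comparable feature
scales.  One component maximizes `cov(Xg, Yd)` over unit-norm weight
vectors, penalized by l1 terms and by the quadratic forms of normalized
hypergraph Laplacians built per block.  The covariance term is normalized
by `1/p` for both blocks by default (`cov_scale="p"`); `1/n`, the
conventional covariance scale, is available and only rebalances the
effective penalty strength.

Modeling assumptions: module signal is rank-one per component (shared
latent factor), features supporting a module are mutually correlated (so
KNN hyperedges align with module structure), and noise is approximately
Gaussian after standardization.

## Hypergraph construction

One hyperedge per feature: the feature plus its `k−1` nearest neighbor
features, Euclidean distance on row-z-scored profiles (correlation
distance optional; z-scoring is skipped for constant profiles, with a
warning).  Neighbor ties break by ascending feature index via a stable
sort, making construction deterministic.  Hyperedge weights are uniform
1.0 by default; a heat-kernel option `exp(−mean pairwise d²/σ²)` exists.
From the incidence matrix `H`: `Dv = diag(H w)`, `De = diag(1ᵀH)`,
`S = H W De⁻¹ Hᵀ`, `L = I − Dv^{−1/2} S Dv^{−1/2}`.  `S` is a Gram
matrix, hence PSD, so `eig(L) ⊆ [0, 1]` — this bound matters for the
solver (below).  The default hyperedge size is `k = 2` (the feature and
its single nearest neighbor), the smallest non-trivial coupling and the
operating point used throughout; `k` counts total vertices per hyperedge,
and the simple-graph builder used by the SNPLS comparator uses the same
convention (`k−1` neighbors, mutualized) so that equal `k` couples equal
feature pairs in both constructions.

Each block gets its own hypergraph from its own profiles; there are no
cross-omics hyperedges.  Laplacians are built once from the original
standardized blocks and reused across all modules (`rebuild_laplacians`
flips this): the graph encodes the original correlation structure, which
deflation would progressively erase.

## Solver

Warm start: PLS power iteration (`g ∝ Xᵀv`, `u = Xg`, `d ∝ Yᵀu`,
`v = Yd`) from a seeded random column of Y, run to direction change
`< 1e−8` or 500 sweeps; it converges to the leading singular pair of
`XᵀY`.

Block update for `g` (and symmetrically `d`): with
`t = (1/p)·XᵀYd` and `S̃ = Dv^{−1/2} S Dv^{−1/2}`,

```
z_j = t_j + 2β₁·(S̃ g)_j,      g_j ← sign(z_j)(|z_j| − λ₁)₊ / (2(β₁+γ₁+δ₁)),
```

all coordinates evaluated at the incoming `g` (ascending order), then
projection to the unit sphere.  Evaluated this way, the sweep is an exact
majorize–minimize step of the sphere-constrained block problem: the
graph quadratic is majorized at the current iterate using the curvature
bound `eig(L) ≤ 1`, and the resulting linear-plus-l1 objective on the
sphere is minimized in closed form by soft-threshold-then-normalize.
The block objective therefore cannot increase.  For the simple-graph
Laplacian (spectrum in `[0, 2]`) the update adds the curvature excess
`max(0, λ_max(L) − 1)` times the current iterate inside `z`, preserving
the guarantee.  A backtracking guard (halving toward the candidate on
the sphere, accept only non-increase) protects against floating-point
edge cases; the objective trace is non-increasing by construction.

The stabilizers `δ₁, δ₂ > 0` (default 1.0) only rescale pre-normalization
coordinates — the unit-norm projection cancels any positive value — and
likewise the ridge terms `γ` are constant on the sphere; both are kept
for fidelity to the update rule's printed form and exposed in the
configuration.  The graph-coupling coefficient in `z` is `β` (matching
the objective's gradient); a `literal_printed_coupling` flag substitutes
`λ` for users who want the literal published update.

Convergence: relative objective change `< tol` (default `1e−6`) or
`max_iter` (default 100) sweeps, or neither block able to improve.  The
problem is non-convex; `n_restarts` (default 1) adds seeded random unit
starts after the PLS warm start and keeps the feasible run with the
lowest final objective (a fully shrunk run never outranks a feasible
one).  A single PLS-initialized run suffices at realistic sizes; the
restarts matter mainly for tiny, heavily penalized problems where
several KKT points coexist.

If a sweep shrinks an entire block to zero, the component is degenerate:
both blocks zero raises an error advising smaller `λ`; one-sided zeros
are returned flagged, yield an empty module, and skip deflation.

## Module extraction

Feature membership: weights are z-scored with sample sd (ddof = 1) and
features with `|z| > T` (default `T = 1`; one-sided `z > T` optional)
enter the module.  Sample membership: `u* = u/‖u‖`, `v* = v/‖v‖`,
`s = u* + v*` is z-scored and thresholded the same way (a `raw` rule
thresholds `s` directly without z-scoring).  The absolute threshold is
the default because weights are signed and a module's features can
anti-correlate with its latent.

Diagnostics: `PCC(u, v)` (NaN-flagged when a latent has zero variance)
and the module error `(p/n)Σ(X − upᵀ)² + (p/n)Σ(Y − vqᵀ)²`; the printed
`p/n` weighting of both terms is the default, with a symmetric
`(p/n, q/n)` alternative.  Deflation subtracts `u·(Xᵀu/uᵀu)ᵀ` from X
(and the analogous term from Y), making successive latent scores exactly
orthogonal and the block a telescoping sum of rank-one terms plus a
final residual.  Extraction runs `K = 20` rounds by default, stopping
early on numerical rank collapse.

Hyperparameter search scores each combination of
`(λ₁, λ₂, β₁, β₂) ∈ {0.01, 0.05, 0.1, 0.5, 1}⁴` (and optionally `k`) by
the mean `|PCC|` over non-degenerate modules — the aggregation is a
package choice since one score per combination is needed — optionally at
reduced `K` for speed, then refits at full `K`.

## Baselines

PLS, SPLS and SNPLS are exact restrictions of the same solver (all
penalties zero; `β = γ = 0`; simple-graph Laplacian), so nesting is exact
and bit-reproducible at equal seeds.  SNPLS here means "sparse PLS with
a simple-graph Laplacian penalty" within this solver, not a re-
implementation of the original external algorithm.  The comparison table
reports, per method, mean module error, mean `|PCC|`, and the objective
as the sum of final per-module objective values (noted in the run
metadata, since other aggregations are conceivable).

## Synthetic data

`X = s·Σ_k u_k g_kᵀ + E` with orthonormal latents `u_k` (QR of a Gaussian
matrix), disjoint supports with equal positive weights `1/√|S|`, and
i.i.d. Gaussian noise (Student-t(4), variance-matched, as a robustness
option).  SNR is defined per entry as planted-block signal variance over
noise variance, giving `s = noise_sd·√(snr·n·|S|)` and planted column
variance `(snr+1)·noise_sd²`; `snr = 0` is the null condition.  Defaults
(n=100, p=300, q=250, one 15+15 module, snr=2) are the study conditions
used by the tests and the acceptance script.

The generator emulates shared sparse latent factors with correlated
support features; it does not emulate bounded methylation beta values,
LD-like correlation blocks outside supports, batch effects, or heavy
feature-wise variance heterogeneity — passing tests demonstrate correct
mechanics and calibration, not performance on those real-data
complications.

Recovery matching is greedy by combined-support Jaccard (ties by module
index), verified in tests against exhaustive enumeration; metrics are
support precision/recall/F1 per block and the mean |correlation| between
matched latent scores and the planted factors.

## Numerical choices and problem sizes

- Normalization `S/√(Dv_i·Dv_j)` is computed as a single division so
  simple rational cases stay exact in floating point.
- Objective descent is asserted at tolerance `1e−8` per sweep; deflation
  orthogonality at `1e−10`; telescoping reconstruction at `1e−8`.
- Test and validation runs use 20-seed batches at the study conditions
  and 2–5 modules per fit, which keeps the whole suite in the seconds
  range while exercising every code path; the acceptance script uses
  10-seed batches and a 10-module comparison run.

## Known limitations

- Single latent component per module; no orthogonality constraints
  beyond score deflation.
- The grid search is exhaustive (625 combinations at default grids) and
  is best run with reduced `K`.
- Degenerate (fully shrunk) components end the useful module sequence in
  practice; the pipeline keeps emitting empty modules to honor the
  K-module contract rather than re-tuning penalties mid-run.
- `evaluate` on written tables recomputes support metrics only; latent
  scores are not persisted to TSV, so latent correlations are reported
  as zero there (use the Python API for full recovery reports).
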