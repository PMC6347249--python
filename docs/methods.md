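# Methods

## The selection model

The data is a non-negative matrix `A` with n rows (cells) and d columns
(features), typically n < d.  Let `A_k = U_k diag(σ) V_k^T` be its best
rank-k approximation.  The rank-k subspace leverage score of column
`a_i`,

    tau_i = a_i^T (A_k A_k^T)^+ a_i ,

equals the squared i-th row norm of `V_k`, and equivalently the squared
norm of the minimum-norm least-squares solution of `A_k x ≈ a_i`.  All
three forms are implemented: the `V_k` row-norm route is the production
path (O(ndk), sparse-friendly, never forms an n × n matrix); the
pseudoinverse and least-squares forms are dense test oracles, and the
suite asserts elementwise agreement to 1e−8 across random matrices.
Scores lie in [0, 1] and sum to k.

The selection walks columns in descending-score order, breaking ties by
ascending column index (stable sort), and stops at the first prefix
whose retained scores sum **strictly** past k − ε.  Strictness is taken
literally: a prefix landing exactly on k − ε keeps adding.  If the stop
fires with fewer than k columns, the set is padded to size k
(`forced_fill`), since a useful submatrix must be able to carry rank k.
The realized error ε̃ = k − Σ_{selected} tau is recorded; ε̃ < ε on
every non-padded run.  Greedy selection by descending score maximizes
the retained mass among all equal-size subsets, which the tests confirm
by exhaustive enumeration on small d.

### Interpretations

Under the (degenerate) Gaussian reading — columns i.i.d. from
N(0, A_k A_k^T) — the exponent of a column's likelihood is −tau_i/2, so
dropping the unselected columns changes the total log-likelihood by
exactly ε̃/2 plus a normalization constant.  The implementation checks
this identity at runtime by computing both sides independently and
requiring the residual below 1e−6.

## Runtime bound verification

The selected submatrix C satisfies

    (1−ε) A_k A_k^T ⪯ U_k U_k^T C C^T U_k U_k^T ⪯ A_k A_k^T ,

its relaxation with (1+ε) on the right, and
(1−ε)‖A_k‖_F² ≤ ‖C‖_F² ≤ ‖A‖_F².  The verifier works in the
k-dimensional `U_k` basis: with G = U_k^T C C^T U_k and D = diag(σ²),
each Loewner statement reduces exactly to a k × k eigenvalue condition
(both sides of the projected n × n statement vanish off the leading
subspace), so verification is O(k³) after one pass over C.  The report
stores the most-negative eigenvalue of each difference matrix as the
slack; a check passes when slack ≥ −tol with tol = 1e−8·σ₁², scaled by
σ₁² so pass/fail is invariant to the data's overall scale.  The
Frobenius check uses relative tolerance 1e−10.  Feeding the verifier a
non-conforming selection (e.g. dropping the top-leverage column) drives
the lower slack genuinely negative, which the tests use as a
corruption control.

## Power-law profile and size formulas

Sorted leverage profiles of real expression matrices decay roughly as
`tau at rank i ∝ i^(−a)` with a > 1.  The fit is ordinary least squares
of log score on log rank (1-based) over the top n_top strictly positive
scores; no weighting or intercept constraint.  The decay exponent is
stored positive (the log-log slope is −a) and R² on the log-log scale is
reported so users can judge the decay assumption rather than just
accept the fit.  Under exact decay the selection size has the closed
form

    |Θ| = max( (2k/ε)^{1/(a−1)}, (2k(a−1)/ε)^{1/(a−1)} − 1, k ) ,

while randomized leverage-score sampling needs
t ≥ (2/ε²)(k + mγ)(1 + ε/3) ln(16k/δ) columns for the same two-sided
bound with failure probability δ (m = number of zero-leverage columns,
γ = smallest nonzero score).  Both formulas are exposed, plus a
predicate comparing them.

The synthetic `power_law_profile` rescales i^(−a) to sum to k; when the
rescale would push the top score past the tau ≤ 1 ceiling, leading
scores are clipped at 1 and the tail renormalized, and the profile
flags that it is power-law only in its tail.

## Clustering-concordance harness

Because real data has no labeled ground truth, a feature selection is
scored by how well clustering on the submatrix reproduces clustering on
the complete matrix.  Pipeline per matrix: each cell's counts are
normalized to a probability mass function (cells with zero total count
have no PMF and are rejected, or — inside the harness — dropped from
both labelings for that comparison and counted in the report); pairwise
Jensen-Shannon distances are computed in **base 2** and as the square
root of the divergence, so D_JS is a metric in [0, 1] — this choice
matters because the similarity is S = 1 − D_JS and neither the base nor
the root is canonical; spectral clustering uses the
symmetric-normalized Laplacian dialect (embed in the leading k_embed
eigenvectors of Deg^{−1/2} S Deg^{−1/2}, default k_embed = n_clusters,
no row renormalization by default — a flag enables it) followed by
seeded k-means++ with 10 internal restarts.  Concordance is the
adjusted Rand index, computed from the pair-counting contingency-table
formula (scikit-learn's implementation is the independent cross-check
in the tests), averaged over T = 10 k-means restarts that share seeds
between the complete-data and submatrix workflows.  The dense n × n
distance matrix bounds the harness to roughly n ≤ 10,000 cells.

## Synthetic data

`simulate_counts` emulates the gross traits of single-cell count
matrices: Poisson counts, a small block of informative features that
are highly expressed in exactly one cluster each, and a large
background of low-rate noise features, which together give a steeply
decaying leverage profile.  Defaults — 200 cells, 3 clusters assigned
round-robin (exactly reproducible cluster sizes), 30 informative + 500
noise features, Poisson mean 50 when a feature is "on" in its cluster
and 0.5 elsewhere — are desk-scale choices giving a clear but not
trivial planted structure: leverage recovery and clustering concordance
pass with margin, pure-noise selections sit at chance.  Poisson is the
count model because nothing in the selection method depends on the
noise law; negative binomial over-dispersion, dropout/zero-inflation,
library-size variation and batch structure are deliberately absent, so
passing tests demonstrate correctness of the machinery, not robustness
to those real-data effects.

## Numerical choices

- SVD: dense LAPACK for dense input; ARPACK `svds` with a fixed
  deterministic start vector for sparse input, so factors are
  reproducible run to run.  Sign convention: each right singular vector
  is flipped so its largest-magnitude entry is positive, making
  serialized outputs comparable byte-for-byte.
- Rank deficiency: requesting k with σ_k ≤ 1e−10·σ₁ raises, naming the
  achievable rank.
- Ties at the selection threshold: the stable descending sort decides;
  this is a policy of this implementation, not a property of the
  method.
- Baselines: `count` is the column sum (mean-thresholding gives the
  same ordering at fixed n and is subsumed); `variance` uses the
  population convention (divide by n); `dispersion` is variance/mean
  with 0/0 := 0 so all-zero columns rank last.  Indices in
  machine-readable outputs are 0-based and reports say so; printed
  narratives may use 1-based labels.
- Randomized leverage sampling draws with replacement (the standard
  sketching convention); duplicates are collapsed in first-draw order
  for submatrix extraction, and the raw draw sequence is retained for
  callers that reweight by multiplicity.
- No automatic rank selection: the elbow heuristic is applied by eye,
  so `eigenvalue_scan` surfaces the spectrum of A A^T plus the largest
  consecutive-ratio index as a hint only.
- Centering is off by default (selection on raw counts); an explicit
  `center_columns` step provides the mean-centered, empirical-variance
  reading of the Frobenius bound.

## Problem sizes

The test and acceptance workloads run on small matrices by design: the
oracle-equivalence and bound suites use random Poisson matrices up to
30 × 100 across 50 draws and a (k, ε) grid, exhaustive-subset
optimality checks use d ≤ 12, and the concordance experiment uses the
200 × 530 simulation defaults with T = 10 restarts.  These sizes
exercise every code path; the algorithms themselves scale as O(ndk) for
scoring plus O(n²d) for the dense-distance clustering harness.

## Known limitations

- The concordance harness materializes dense PMF and distance matrices;
  very large cell counts need chunked or sparse JS computation that is
  not implemented.
- The custom-subspace scorer recomputes a factorization up to the
  largest requested component rather than reusing a cached one.
- The power-law fit is descriptive; no standard errors on the exponent
  are reported.
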