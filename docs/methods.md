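# Methods

## Model and target of inference

Each observation is a matrix predictor `X (p x T)` — `p` variables (rows)
measured at `T` time points or channels (columns) — with a scalar response
`Y`.  Vectorisation is always column-major over `p x T`:
`vec(X) = (X_.1', ..., X_.T')'`, so the cell (variable `j`, time `t`) sits
at index `t*p + j`.  The inverse regression of the predictors on the
response is modelled as linear in a `k x r` matrix `f_Y` of known,
mean-zero functions of `Y`, with a Kronecker-factorised coefficient:

    vec(X) = vec(mu) + (alpha ⊗ beta) vec(f_Y) + vec(eps),
    E(eps) = 0,  Var(eps | Y) = Delta (pT x pT, constant in Y).

`alpha (T x r)` carries the column/time structure, `beta (p x k)` the
row/variable structure.  Writing `alpha = Gamma1 gamma1` and
`beta = Gamma2 gamma2` with semi-orthogonal `Gamma1 (T x d1)`,
`Gamma2 (p x d2)` of the factor ranks, the first-moment SDR subspace is

    S_FMSDR = Delta^-1 span(Gamma1 ⊗ Gamma2),   dim = d1*d2,

and the sufficient score of a new matrix is
`(Gamma1 ⊗ Gamma2)' Delta^-1 vec(X - Xbar)`.  Throughout, `d1` and `d2`
are treated as known; their estimation (e.g. by information criteria) is
out of scope.

Assumptions worth keeping in mind: the mean factorisation is exact in the
model (misspecification shows up as bias in both factors); the MLE and
PFC estimators additionally assume `X | Y` Gaussian with constant
covariance; all estimators centre the predictors, so a constant offset
matrix is irrelevant.

## Estimators

**K-PIR (ls).**  Column-centre the data and response functions, fit the
unconstrained multivariate OLS `B = (F'F)^-1 F'X` (computed from the
sufficient statistics `F'F`, `X'F`, `X'X`, so cost is independent of `n`
after one pass), and project `B'` onto the Kronecker manifold by the Van
Loan–Pitsianis (VLP) nearest-Kronecker-product approximation: rearrange
the `(T*p) x (r*k)` matrix into a `(T*r) x (p*k)` matrix whose rows are
the row-major vecs of its `p x k` blocks; the best rank-1 approximation of
the rearrangement (full SVD; the dimensions here are small) gives
`vec(alpha)` and `vec(beta)`.  The residual covariance uses divisor
`n - rank(F)`.

**K-PIR (mle).**  Block ascent on the Gaussian log-likelihood: at fixed
`Delta`, maximise over the stacked free parameters `(vec alpha, vec beta)`
with L-BFGS and the analytic gradient (the gradient of the quadratic form
contracts through the same rearrangement operator); then update `Delta`
with the closed-form score solution (divisor `n`).  Initialisation is the
least-squares solution.  The two divisor conventions (ls: `n - rank(F)`;
mle: `n`) are both kept deliberately; they agree asymptotically.  Stopping:
relative change of `Delta` and of `alpha ⊗ beta` both below `1e-6`
(defaults `tol1 = tol2 = 1e-6`, `max_iter = 100`; in the study designs the
outer loop converges in ~10–20 iterations).  The log-likelihood trace is
recorded and is non-decreasing up to optimiser tolerance.  The likelihood
needs `Delta^-1`, so fitting is refused for `n <= pT` unless an explicit
diagonal ridge is supplied; a non-positive-definite iterate is repaired by
adding `1e-8 * tr(Delta)/pT` (logged as a warning).  The scale redundancy
`(c*alpha, beta/c)` is left free inside the optimiser (the objective is
invariant) and resolved on output only.

**K-PFC.**  Principal fitted components: with `Delta_fit = X'P_F X / n`
and `Delta_res = X'X/n - Delta_fit`, the covariance MLE folds the
spectrum of `Delta_res^-1/2 Delta_fit Delta_res^-1/2` beyond the first
`d = d1*d2` eigenvalues back into the covariance; when `d = k*r` it
reduces to `Delta_res` exactly.  The mean-subspace estimate is the span of
`Delta_mle^1/2` times the top-`d` eigenvectors of
`Delta_mle^-1/2 Delta_fit Delta_mle^-1/2` (re-orthonormalised), and the
coordinate matrix `gamma` is the GLS of `B'` on the basis in the
`Delta_mle^-1` metric.  The three variants factorise different objects:

* K-PFC1: VLP of the fitted mean `Gamma gamma`;
* K-PFC2: VLP of `Gamma` itself; each factor is projected to the nearest
  semi-orthogonal matrix (polar decomposition, required by the model's
  semi-orthogonality constraint), `gamma` is re-estimated against
  `Gamma1 ⊗ Gamma2`, and the product is reported;
* K-PFC3: additionally VLP of `gamma`, giving explicit
  `alpha = Gamma1 gamma1`, `beta = Gamma2 gamma2`.

For `d1 = d2 = k = r = 1` the `gamma` split is exact and K-PFC2 and
K-PFC3 coincide (asserted in the tests).

**Sparse K-CISE.**  The sparse basis solves a penalised Rayleigh problem
for the top-`d` eigenspace of the whitened kernel
`A = Sigma_x^-1/2 Delta_fit Sigma_x^-1/2` under an orthonormality
constraint.  The solver is a penalised orthogonal iteration: multiply by
`A`, rescale each column to unit norm, soft-threshold the entries
coordinate-wise, and re-orthonormalise by thin QR, iterating to subspace
convergence.  Two deliberate choices:

* *Per-entry (not per-row) thresholding.*  Row-wise group thresholding can
  only remove whole coordinates of `vec(X)`; the entry-level zero patterns
  of the Kronecker factors (a time point used by one mean column but not
  another) are unreachable that way, and the planted designs this package
  validates against have exactly such patterns.
* *Column normalisation before thresholding.*  The columns of `A Gamma`
  scale with their Rayleigh quotients; a single threshold applied to raw
  columns removes weak-eigenvalue directions wholesale before sparsifying
  strong ones.  Normalising makes the threshold act on each direction's
  dimensionless coordinate profile.

The threshold is chosen on a 20-point grid (`0` plus three log-decades up
to the largest normalised entry) by a likelihood-scale BIC,
`n * (-tr(Gamma' A Gamma)) + log(n) * #nonzero-entries`; candidates that
threshold a column away entirely are discarded.  A singular `Sigma_x`
(possible when `pT >= n`) receives a diagonal ridge `1e-6 * tr/pT` before
the inverse square root (logged).  The sparse basis is then split into its
Kronecker factors by VLP; factor entries below `1e-8` of the factor's
largest entry are snapped to exact zeros, and zero rows of the time and
variable factors are the dropped time points and markers.

**Comparators.**  (2D)^2 PCA takes separate eigenbases of the sample row
(`p x p`) and column (`T x T`) covariances; (2D)^2 PCR regresses `Y` on
the retained two-sided components by OLS with intercept.  LSIR slices the
response (the classes, for binary `Y`; 10 equal-frequency slices
otherwise), estimates the separable within-slice covariance factors by the
moment formulas `Sigma2 ∝ E(X-M_s)(X-M_s)'`, `Sigma1 ∝ E(X-M_s)'(X-M_s)`,
extracts the leading between-slice direction (SVD of the weighted centred
slice means) with its rank-1 Kronecker factors `a, b`, and reports the
single FMSDR direction `(Sigma1^-1 a) ⊗ (Sigma2^-1 b)`.  LSIR is a
moment sketch of the full algorithm in the literature; it returns no
covariance estimate, so the harness reports `E1/E2` for it as missing.

## Conventions

* **vec order**: column-major over `p x T` everywhere, including the CSV
  wide layout (`v{i}_t{j}` columns run time-major).  File indices are
  1-based, in-memory indices 0-based.
* **Scale/sign of `(alpha, beta)`**: the product is invariant to
  `(c*alpha, beta/c)`; the stored representative has `||beta||_F = 1` with
  the largest-magnitude entry of `beta` positive.
* **Eigen/singular vectors**: each column is flipped so its
  largest-magnitude component is positive; ties in eigenvalue order are
  broken stably (a zero covariance matrix keeps the identity basis).
* **Mean-product orientation (K-PFC2/3)**: these variants assemble the
  mean from sign-normalised subspace quantities, so the overall sign of
  the reported product is fixed by the same largest-entry-positive rule
  rather than inherited from the regression coefficients.
* **Binary coding**: `build_binary` returns the centred indicator of the
  positive class (`y - ybar` by default).  The binary study harness uses
  the control group (`Y = 0`) as the positively-coded reference level —
  the convention under which the published two-group estimation errors
  were reported — which flips the sign of regression-based mean estimates
  but leaves every subspace and covariance quantity unchanged.  Because
  K-PIR/K-PFC1 inherit the regression sign while K-PFC2/3 are re-oriented
  by the convention above, their `E1` values against the same truth are
  not comparable in sign-sensitive terms; the harness documents this
  asymmetry rather than hiding it.
* **Selection scoring**: basis columns are identified only up to order,
  so `selection_rates` matches estimated factor columns to the truth by
  the best permutation before counting entry-wise false
  positives/negatives.  FPR averages over truly-zero entries, FNR over
  truly-nonzero ones, and the total error rate divides all
  misclassifications by the factor size.

## Synthetic-data generators

`generate_continuous`: `y ~ N(0,1)`; Fourier design with `2s = r*k`
frequency pairs; `Gamma1, Gamma2` partial identities and
`gamma1, gamma2` padded identities `[I_d, 0]`, so the factors are 0/1
matrices of the requested ranks with exactly `d` unit entries — the
choice under which the reduced-rank estimation errors scale with the
shrinking signal norm, matching the published study.  `Delta` defaults to
the identity (the simplest positive-definite matrix with unit diagonal,
which is all the study design specifies); an AR(1) option is available.
Quantities that depend on the *shape* of `Delta` — notably the `E2`
covariance errors, their variability `V2`, and the size of the
likelihood/PFC efficiency gains over least squares — are therefore not
comparable across `Delta` choices, and the identity default makes those
gains small by construction.

`generate_binary`: two balanced Gaussian groups with means `alpha_i ⊗
beta` (`alpha_0 = 0`, `alpha_1[t] = 1/(T-t+1)` so later time points carry
more signal, `beta = p^-1/2 * 1`), separable AR(1) x AR(1) marginal
covariance, and the within-group covariance derived from the variance
decomposition `Sigma_x = Delta + Cov(E(vec X | Y))`.  The mean shift can
be scaled (`shift_scale`); the decomposition bounds how large a shift the
configuration admits, and an infeasible request raises.

`generate_sparse`: quadratic response basis `(y, y^2)` (the constant is
annihilated by centring and absorbed by `mu`, so it is never built);
`alpha (T x 2)` with unit entries at (1,1) and (2,2), `beta = e1`;
`Delta = I` with the noise standard deviation multiplied by `scale`.

What the generators do **not** emulate about real cohort or imaging data:
non-Gaussian and heavy-tailed predictors, missing visits and unbalanced
sampling, response-dependent covariance, model misspecification of the
mean factorisation, and measured-confounder structure.  Passing the
Monte-Carlo checks therefore certifies the estimators under their own
model, not robustness beyond it.

## Numerical choices

* Matrix square roots by symmetric eigendecomposition with an eigenvalue
  floor of `1e-12` times the largest eigenvalue.
* `Delta`-inverses via Cholesky only; positive-definiteness failures
  raise (likelihood) or trigger the documented ridge repairs.
* Rank-1 VLP factors from the full SVD of the rearranged matrix — the
  rearranged dimensions in all supported problems are tiny, so no
  iterative solver is used.
* The zero-snap tolerance for sparse supports is relative (`1e-8` of the
  largest entry); QR after thresholding can only repopulate a zero entry
  through cross-column support overlap, and entries that stay below the
  tolerance are restored to exact zeros so reported supports are exact.
* Degenerate inputs: an all-zero matrix VLP-factorises to zero factors
  with zero residual and a degenerate flag; equal slice means make the
  LSIR direction degenerate (flagged, warned); constant scores yield AUC
  0.5 with a degenerate flag.

## Study-harness sizes

The bundled Monte-Carlo harness (`run_table`, `scripts/acceptance.py`,
and the end-to-end tests) uses 100–500 replicates per scenario with the
study sample sizes (`n = 500`–`5000` continuous, total `n = 500`–`2000`
binary, `n = 100`/`500` sparse), chosen so a full reproduction completes
in minutes on a single core; per-replicate seeds are spawned from the
master seed so methods are compared on identical data and runs are
bit-reproducible.  In the binary tables, `n` denotes the **total** sample
size (balanced groups).

## Known limitations

* `d1, d2` (and `k, r`) must be supplied; no order-selection is provided.
* `fit_lsir` estimates a single direction (`d = 1`); multi-directional
  sliced inverse regression is not implemented.
* The MLE requires `n > pT` (or an explicit ridge) and, like any
  estimated-weights GLS, need not beat least squares in finite samples
  when the true error covariance is close to spherical.
* The sparse solver's BIC constant (`log n` per nonzero entry) governs
  the selection operating point; alternative constants trade false
  negatives against false positives, and no data-driven calibration of
  the constant itself is attempted.
* Only two-factor (matrix) predictors are supported; higher-order tensor
  decompositions are out of scope.
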