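# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical choices, and the known limitations of `bayesconn`.

## Model and inference

**Likelihood.** Each subject's cleaned ROI time series X (T × d) is treated
as i.i.d. rows from N(0, K⁻¹).  Columns are standardized internally
(partial correlations are scale-invariant, so this only conditions the
numerics).  Temporal autocorrelation is ignored by the likelihood; see
Limitations.

**Prior.** K | G ~ W_G(δ, D) with density ∝ |K|^((δ−2)/2) exp(−tr(DK)/2)
restricted to matrices supported on the skeleton G.  Defaults δ = 3 and
D = I are weakly informative: for the complete graph this is a Wishart with
d + 2 degrees of freedom, and the implied prior on each partial correlation
is proper and centred at zero.  Edges are independent Bernoulli(0.5) a
priori, i.e. a uniform distribution over all 2^(d(d−1)/2) skeletons.  All
three hyperparameters are configurable (`PriorSpec`).

**Sampler.** The chain targets the joint posterior over (G, K):

1. *Edge move.*  A pair (i, j) is drawn uniformly.  Conditioning on every
   element of K except (K_ij, K_jj), the block factorises as an independent
   Gamma Schur complement and (when the edge is present) a Gaussian K_ij,
   so the ratio of block normalising constants — the conditional Bayes
   factor (CBF) for edge inclusion — is available in closed form.  The
   marginal acceptance ratio for toggling the edge still contains the
   intractable prior ratio I_G(δ, D)/I_{G'}(δ, D); it is replaced by an
   unbiased single-sample estimate, the CBF evaluated on an auxiliary exact
   G-Wishart prior draw under the graph containing the edge (an
   exchange-algorithm construction; exact because the auxiliary draw is an
   exact sample, not a short chain).  After the accept/reject decision the
   (K_ij, K_jj) block is re-drawn from its exact conditional.
2. *Precision refresh.*  K | G, data ~ W_G(δ + T, D + X'X) is re-drawn
   exactly with the direct sampler: an unconstrained Wishart draw followed
   by iterative covariance completion (IPF) onto the graph.

Correctness is validated against exhaustive enumeration at d = 3, where
every graph is decomposable and I_G has a closed form via the
clique/separator factorisation (tests/oracles.py); sampled edge
probabilities agree within Monte-Carlo error.

**Summaries.**  Per subject: posterior edge probabilities, expected partial
correlations E[ρ_ij] (averaging −K_ij/√(K_ii K_jj) over retained samples,
zero contributions when the edge is absent), expected network density, and
diagnostics (per-edge acceptance rates, density trace).  Group level:
entrywise mean/SD matrices, per-subject density vectors, and a two-tailed
two-sample t-test on densities — Welch's form by default because equal
group variances are not guaranteed; the pooled form is a flag.

**Chain defaults.**  20 000 iterations, 5 000 burn-in, thinning 5 — ample
for single-subject analyses at d = 14.  The replicated simulation studies
and the test suite use shorter chains (400–8 000 iterations depending on
d): posterior summaries are then noisier but remain valid and i.i.d.
across subjects, which is all that the calibration-style checks require;
problem sizes used by each study are stated in the code that runs it.
Seed policy: one root seed per run; per-subject chain seeds are derived
deterministically (fixed offsets or the subject's own simulation seed), so
identical configurations give bit-identical outputs.

## Synthetic cohorts

The generator emulates the target design point: d = 14 subcortical ROIs
(7 homotopic left/right pairs), T = 110 volumes at TR = 2.38 s, 72
group-A and 39 group-B subjects.

- **Skeleton.**  All 7 homotopic edges forced on; every other pair present
  independently with probability 0.2.  That default makes the template's
  expected density (7 + 84·0.2)/91 ≈ 0.26, matching the posterior expected
  densities the pipeline itself reports at this design point.
- **Strengths.**  Homotopic partial-correlation targets: 0.55 (thalamus),
  0.41 (caudate), 0.30 for the remaining five pairs; extra edges get a
  random magnitude in [0.10, 0.25] (sign positive with probability 0.8).
  The precision matrix is built as K = I − R (R holding the targets), so
  the implied partials equal the targets exactly; if K is not positive
  definite the minimal diagonal load is added in closed form (eigenvalues
  shift linearly), which shrinks every partial by 1/(1+c); a shift larger
  than 0.02 raises an error naming the most extreme target edges.
- **Group effect.**  Group B shares group A's skeleton with every partial
  correlation multiplied by (1 − group_effect).  The default shrinkage of
  0.1 maps the strongest pairs from 0.55/0.41 to ≈0.50/0.37 — i.e. a mild,
  realistically sized group difference; set 0 for identical groups.
  Shrinkage toward the identity preserves positive definiteness.
- **Nuisance structure.**  Observed series = clean Gaussian signal
  + drift_amplitude × (slow sinusoid with period ≥ 120 s + linear trend)
  + confound_coupling × (random linear mix of the confound set).  The
  confound set is 6 AR(1) motion-like traces (coefficient 0.9), AR(1)
  white-matter and CSF means, and backward-difference temporal derivatives
  of all eight (first row zero-padded), 16 regressors total.  Default
  amplitudes 0.5 put the contamination at half the clean-signal SD.

What the generator does **not** emulate: hemodynamic autocorrelation,
image-space artifacts, head-motion spikes, inter-subject variability in the
true network, and physiological noise spectra.  Passing tests therefore
demonstrate the pipeline's statistical machinery under its own model
assumptions, not robustness to the full complexity of real fMRI.

## Preprocessing

- **Confound regression** is ordinary least squares of each ROI column on
  the confound design plus an intercept (always included), implemented by
  QR projection.  Exactly duplicated columns are dropped; residual rank
  deficiency is an error that names the collinear columns.  Note the
  unavoidable geometry: projecting out k regressors from T samples removes
  a k/T fraction of the clean signal's variance in expectation, so
  "recovery" of the clean signal is exact only up to that projection.
- **High-pass filtering** interprets the cutoff in seconds (default 100 s;
  a cutoff expressed in Hz above the Nyquist rate of TR = 2.38 s data is
  not realisable).  The default method projects out a discrete-cosine
  drift basis with periods longer than the cutoff: measured on 110-volume
  series it attenuates periods ≥ 120 s by > 96 % while preserving a 20 s
  component within 1 %.  An FSL-style Gaussian-weighted running-line
  detrend (σ = cutoff / 2TR volumes) is available behind a switch; its
  rolloff is much softer (≈ 19 % attenuation at 120 s), which is why it is
  not the default.
- **Order.**  Regression then filtering is the default.  The two orders
  coincide (to machine precision) exactly when the confound columns carry
  no sub-cutoff power — e.g. when they are themselves high-pass filtered
  first, which makes the sequential projections equal the projection off
  the joint span.  With raw drift-bearing confounds the orders genuinely
  differ (the residuals live in different subspaces); the pipeline treats
  the order as an explicit configuration choice rather than pretending the
  operations commute.

## Numerical choices

- IPF completion tolerance 1e-8 **relative** to the largest covariance
  entry (near-singular Wishart draws can produce covariances of order
  10³, where an absolute tolerance would demand ~10⁻¹¹ relative accuracy
  and stall); cap 200 000 sweeps.  Non-convergence raises, and is unseen
  in practice at the cap.
- Sampler kernels are numba-compiled; numba's RNG is seeded explicitly per
  chain (independent of numpy's Python-level state), giving bit-exact
  reproducibility for a fixed seed.
- Degenerate density test (both groups zero-variance, equal means) returns
  t = 0, p = 1 with a flag instead of dividing by zero.
- Edge ranking ties break by (row, column) index order.

## Limitations

- The i.i.d. Gaussian likelihood ignores temporal autocorrelation of BOLD;
  with autocorrelated real data the effective sample size is below T and
  posterior probabilities are correspondingly overconfident.
- Inference is strictly per subject; there is no hierarchical pooling
  across subjects, and group analysis operates on per-subject posterior
  summaries only.
- The density t-test compares a single global summary; edgewise group
  differences and multiple-comparison control are out of scope.
- The exchange-based edge move costs one exact G-Wishart draw per
  proposal, which dominates runtime at d = 14; chain lengths for large
  replicated studies are chosen accordingly.
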