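# bayesconn

Bayesian estimation of ROI-level resting-state functional connectivity with
Gaussian graphical models, plus a synthetic-cohort generator that makes the
whole pipeline testable end to end without any imaging data.

## Who this is for

Researchers analysing resting-state fMRI at the region-of-interest level who
want connectivity expressed as **partial correlations on an explicitly
estimated conditional-independence skeleton**, rather than as thresholded
marginal correlations or a point estimate from the graphical lasso.  The
package was built around a subcortical design point — 14 ROIs (left and
right nucleus accumbens, amygdala, caudate, hippocampus, putamen, pallidum,
thalamus), 110 volumes at TR = 2.38 s, two groups of 72 and 39 subjects —
but every dimension is configurable.

## The model

For one subject, let the cleaned ROI time series be rows x_t ∈ R^d,
modelled as i.i.d. N(0, Σ) with precision K = Σ⁻¹.  Zeros in K encode
conditional independence, so connectivity is a pair:

- a **binary skeleton** G (which regions are conditionally dependent), and
- **partial correlations** ρ_ij = −K_ij / √(K_ii K_jj) on the edges of G.

The prior is G-Wishart, K | G ~ W_G(δ, D) (δ = 3, D = I by default),
with independent Bernoulli(0.5) edge priors — i.e. a uniform prior over
skeletons.  Because estimating 91 connections from 110 volumes is badly
underdetermined for a saturated model, restricting the partial correlations
to a sampled skeleton regularises the estimates without shrinking the
strengths of the edges that are present.

Posterior sampling alternates

1. single-edge add/delete Metropolis–Hastings moves on G, with the
   intractable G-Wishart normalising-constant ratio handled exactly by an
   exchange-style auxiliary draw and conditional Bayes factors, and
2. conjugate refreshes K | G, data ~ W_G(δ + T, D + X'X) via the direct
   (covariance-completion) G-Wishart sampler.

Each subject is summarised by the posterior edge-probability matrix, the
expected partial-correlation matrix, and the **posterior expected network
density** E[|E|] / (d(d−1)/2).  Groups are compared with a two-tailed
Welch t-test on the per-subject densities.  For d ≤ 3 the sampler is
validated against exhaustive enumeration over all graphs with closed-form
normalising constants.

## Worked example

```python
import numpy as np
from bayesconn import (
    CohortSpec, McmcSettings, PriorSpec,
    default_roi_set, simulate_cohort, preprocess_subject, run_mcmc,
    compare_groups, rank_homotopic_dominance,
)

roi_set = default_roi_set()
spec = CohortSpec(n_group_a=8, n_group_b=8, T=110, seed=7)
cohort = simulate_cohort(spec, roi_set)

prior = PriorSpec()                      # delta=3, identity scale, edge prior 0.5
settings = McmcSettings(n_iterations=4000, burn_in=1000, thinning=2, seed=7)

summaries = {"a": [], "b": []}
for rec in cohort.subjects:
    clean = preprocess_subject(rec.series, rec.confounds, cutoff_seconds=100.0,
                               tr_seconds=spec.tr_seconds)
    s = run_mcmc(clean, prior, settings)
    summaries[rec.group].append(s)

result = compare_groups(summaries["a"], summaries["b"], roi_set)
print(f"density A: {result.test.mean_a:.2f} (SD {result.test.sd_a:.2f})")
print(f"density B: {result.test.mean_b:.2f} (SD {result.test.sd_b:.2f})")
print(f"t = {result.t_statistic:.2f}, p = {result.p_value:.2f}")
report = rank_homotopic_dominance(result.mean_partials_a, roi_set)
for e in report.ranked[:3]:
    print(f"{e.label_i} -- {e.label_j}: {e.value:.2f} (homotopic: {e.is_homotopic})")
```

prints (about a minute on one CPU):

```
density A: 0.27 (SD 0.02)
density B: 0.24 (SD 0.02)
t = 3.01, p = 0.01
L_Thalamus -- R_Thalamus: 0.52 (homotopic: True)
L_Caudate -- R_Caudate: 0.39 (homotopic: True)
L_Accumbens -- R_Hippocampus: 0.32 (homotopic: False)
```

Group A was generated with homotopic partial correlations of 0.55
(thalamus), 0.41 (caudate) and 0.30 elsewhere; group B with every partial
correlation shrunk by 10%.  The posterior group means land close to those
targets, the two strongest edges are the thalamus and caudate homotopic
pairs, and the small density difference between groups reflects the reduced
detectability of group B's weaker edges.  The third-ranked edge here is one
of the randomly planted non-homotopic template edges.

The same pipeline is scriptable from the shell:

```
bayesconn simulate --out cohort/ --seed 7 --n-group-a 8 --n-group-b 8
bayesconn preprocess --cohort-dir cohort/ --out clean/ --cutoff-seconds 100
bayesconn infer --cohort-dir cohort/ --clean-dir clean/ --out summaries/ \
    --iterations 4000 --burn-in 1000 --seed 7
bayesconn compare --cohort-dir cohort/ --summaries-dir summaries/ --out group/
```

or as one reproducible run from a JSON/YAML config:
`bayesconn run-all --config config.json`.  Externally extracted ROI time
series can be dropped into the same TSV + manifest layout that `simulate`
writes, so the inference stages are usable on real data.

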