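"""Reusable simulation studies built on the full pipeline.

These drive simulate -> preprocess -> infer -> compare in memory (no disk
artifacts) and are used for calibration questions: type-I error of the
density test under no group effect, power under a known shrinkage, and
recovery of the homotopic template structure.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .cohort import Cohort, CohortSpec, simulate_cohort
from .group import GroupResult, compare_groups
from .gwishart import PriorSpec
from .mcmc import McmcSettings, PosteriorSummary, run_mcmc
from .preprocess import preprocess_subject
from .rois import RoiSet, default_roi_set

#: Short-chain settings used inside replicated studies; posterior summaries
#: are noisier than with the full-length default chain but remain unbiased
#: and i.i.d. across subjects, which is what calibration needs.
REPLICATE_SETTINGS = McmcSettings(n_iterations=400, burn_in=100, thinning=1, seed=0)


def reduced_roi_set(n_pairs: int = 3) -> RoiSet:
    """A small homotopic ROI set (d = 2 * n_pairs) for reduced studies."""
    labels = tuple(f"L_roi{k}" for k in range(n_pairs)) + tuple(
        f"R_roi{k}" for k in range(n_pairs)
    )
    pairs = tuple((k, k + n_pairs) for k in range(n_pairs))
    return RoiSet(labels=labels, homotopic_pairs=pairs)


def infer_cohort(cohort: Cohort, prior: PriorSpec | None = None,
                 settings: McmcSettings | None = None,
                 preprocess: bool = True,
                 ) -> tuple[list[PosteriorSummary], list[PosteriorSummary]]:
    """Preprocess and run per-subject inference over a whole cohort.

    Per-subject MCMC seeds derive from the subject's own simulation seed so
    the study is a pure function of the cohort spec.
    """
    prior = prior or PriorSpec()
    settings = settings or REPLICATE_SETTINGS
    out_a: list[PosteriorSummary] = []
    out_b: list[PosteriorSummary] = []
    for rec in cohort.subjects:
        series = rec.series
        if preprocess:
            series = preprocess_subject(rec.series, rec.confounds,
                                        tr_seconds=cohort.spec.tr_seconds)
        sub_settings = replace(settings, seed=(settings.seed + rec.seed) & 0x7FFFFFFF)
        summary = run_mcmc(series, prior, sub_settings)
        (out_a if rec.group == "a" else out_b).append(summary)
    return out_a, out_b


def run_cohort_study(spec: CohortSpec, roi_set: RoiSet | None = None,
                     prior: PriorSpec | None = None,
                     settings: McmcSettings | None = None) -> GroupResult:
    """One full in-memory pipeline pass for a cohort spec."""
    roi_set = roi_set or default_roi_set()
    cohort = simulate_cohort(spec, roi_set)
    summaries_a, summaries_b = infer_cohort(cohort, prior, settings)
    return compare_groups(summaries_a, summaries_b, roi_set)


def density_rejection_rate(n_replicates: int, spec: CohortSpec,
                           roi_set: RoiSet | None = None,
                           alpha: float = 0.05,
                           settings: McmcSettings | None = None,
                           base_seed: int = 0) -> float:
    """Fraction of replicate cohorts whose density t-test rejects at alpha.

    With ``spec.group_effect == 0`` this estimates the test's type-I error;
    with a positive shrinkage it estimates power.  Replicate r uses cohort
    seed ``base_seed + r``.
    """
    roi_set = roi_set or reduced_roi_set()
    rejections = 0
    for r in range(n_replicates):
        rep_spec = replace(spec, seed=(base_seed + r) & 0x7FFFFFFF)
        result = run_cohort_study(rep_spec, roi_set, settings=settings)
        if result.p_value < alpha:
            rejections += 1
    return rejections / n_replicates
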