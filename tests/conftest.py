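import numpy as np
import pytest

from bayesconn.cohort import CohortSpec, simulate_cohort
from bayesconn.group import compare_groups
from bayesconn.mcmc import McmcSettings
from bayesconn.rois import default_roi_set
from bayesconn.studies import infer_cohort, reduced_roi_set


@pytest.fixture(scope="session")
def roi14():
    return default_roi_set()


@pytest.fixture(scope="session")
def roi6():
    return reduced_roi_set(3)


@pytest.fixture(scope="session")
def default_cohort_study(roi14):
    """One in-memory pipeline pass over a cohort at the default design point
    (T=110, d=14, default group effect), 10 subjects per group.

    Shared by the homotopic-dominance and group-aggregation tests; chain
    length is reduced relative to the single-subject default because 20
    chains are run and only group-level summaries are asserted.
    """
    spec = CohortSpec(n_group_a=10, n_group_b=10, T=110, seed=42)
    cohort = simulate_cohort(spec, roi14)
    settings = McmcSettings(n_iterations=4000, burn_in=1000, thinning=2, seed=0)
    summaries_a, summaries_b = infer_cohort(cohort, settings=settings)
    result = compare_groups(summaries_a, summaries_b, roi14)
    return {
        "cohort": cohort,
        "summaries_a": summaries_a,
        "summaries_b": summaries_b,
        "result": result,
    }


@pytest.fixture(scope="session")
def null_cohort_study(roi14):
    """As above but with zero group effect: all 20 subjects share one
    generating model.  Used for recovery and calibration-style checks."""
    spec = CohortSpec(n_group_a=10, n_group_b=10, T=110, group_effect=0.0, seed=42)
    cohort = simulate_cohort(spec, roi14)
    settings = McmcSettings(n_iterations=3000, burn_in=1000, thinning=2, seed=0)
    summaries_a, summaries_b = infer_cohort(cohort, settings=settings)
    return {
        "cohort": cohort,
        "summaries": summaries_a + summaries_b,
    }
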