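"""Group-level aggregation of per-subject posterior summaries.

Mirrors the study-level readout this pipeline targets: group-mean expected
partial-correlation matrices, per-subject posterior expected network
densities, a two-tailed two-sample t-test on densities, and a ranking of
edges by mean partial-correlation strength with a homotopic-dominance flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, SchemaError
from .mcmc import PosteriorSummary
from .rois import RoiSet


@dataclass
class DensityTestResult:
    t_statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    equal_var: bool
    degenerate_variance: bool = False


@dataclass
class RankedEdge:
    i: int
    j: int
    label_i: str
    label_j: str
    value: float
    is_homotopic: bool


@dataclass
class DominanceReport:
    """Edges ranked by |mean partial correlation|, with a flag for whether
    the top-k are all homotopic pairs."""

    ranked: list[RankedEdge]
    top_k: int
    top_k_all_homotopic: bool
    n_nonzero: int


@dataclass
class GroupResult:
    mean_partials_a: np.ndarray
    mean_partials_b: np.ndarray
    sd_partials_a: np.ndarray
    sd_partials_b: np.ndarray
    density_a: np.ndarray
    density_b: np.ndarray
    test: DensityTestResult
    strongest_edges: list[tuple[tuple[str, str], float, float]]
    labels: tuple[str, ...] | None = None

    @property
    def t_statistic(self) -> float:
        return self.test.t_statistic

    @property
    def p_value(self) -> float:
        return self.test.p_value


def _check_common_labels(summaries: Sequence[PosteriorSummary]) -> tuple[str, ...] | None:
    labels = summaries[0].labels
    d = summaries[0].n_rois
    for s in summaries[1:]:
        if s.n_rois != d or s.labels != labels:
            raise SchemaError("subjects disagree on ROI set (labels or dimension)")
    return labels


def group_mean_matrix(summaries: Sequence[PosteriorSummary],
                      which: str = "expected_partials") -> tuple[np.ndarray, np.ndarray]:
    """Entrywise mean and SD over subjects of a posterior summary matrix."""
    summaries = list(summaries)
    if not summaries:
        raise ParameterError("need at least one subject")
    _check_common_labels(summaries)
    stack = np.stack([getattr(s, which) for s in summaries])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    return 0.5 * (mean + mean.T), 0.5 * (sd + sd.T)


def density_test(density_a: Sequence[float], density_b: Sequence[float],
                 equal_var: bool = False) -> DensityTestResult:
    """Two-sample, two-tailed t-test on posterior expected densities.

    Welch's unequal-variance form by default; the pooled form is available
    with ``equal_var=True``.  If both groups have zero variance and equal
    means the result is reported as t=0, p=1 with a degenerate flag instead
    of dividing by zero.
    """
    a = np.asarray(density_a, dtype=float)
    b = np.asarray(density_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least two subjects")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    if sd_a == 0.0 and sd_b == 0.0:
        if mean_a == mean_b:
            return DensityTestResult(0.0, 1.0, mean_a, sd_a, mean_b, sd_b,
                                     equal_var, degenerate_variance=True)
        t = np.inf if mean_a > mean_b else -np.inf
        return DensityTestResult(float(t), 0.0, mean_a, sd_a, mean_b, sd_b,
                                 equal_var, degenerate_variance=True)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return DensityTestResult(float(t), float(p), mean_a, sd_a, mean_b, sd_b,
                             equal_var)


def rank_homotopic_dominance(mean_matrix: np.ndarray, roi_set: RoiSet,
                             top_k: int | None = None) -> DominanceReport:
    """Rank ROI pairs by |mean partial correlation|, descending; ties broken
    by (row, column) index order.  Flags whether the top-k edges are all
    homotopic (k defaults to the number of homotopic pairs)."""
    M = np.asarray(mean_matrix, dtype=float)
    d = roi_set.n_rois
    if M.shape != (d, d):
        raise SchemaError(f"matrix shape {M.shape} does not match d={d}")
    if top_k is None:
        top_k = max(len(roi_set.homotopic_pairs), 1)
    pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
    pairs.sort(key=lambda e: (-abs(M[e[0], e[1]]), e[0], e[1]))
    ranked = [
        RankedEdge(i, j, roi_set.labels[i], roi_set.labels[j],
                   float(M[i, j]), roi_set.is_homotopic(i, j))
        for i, j in pairs
    ]
    n_nonzero = sum(1 for e in ranked if e.value != 0.0)
    top = ranked[:top_k]
    all_homotopic = n_nonzero >= top_k and all(e.is_homotopic for e in top)
    return DominanceReport(ranked=ranked, top_k=top_k,
                           top_k_all_homotopic=all_homotopic, n_nonzero=n_nonzero)


def compare_groups(summaries_a: Sequence[PosteriorSummary],
                   summaries_b: Sequence[PosteriorSummary],
                   roi_set: RoiSet | None = None,
                   equal_var: bool = False) -> GroupResult:
    """Assemble the full group-level readout from per-subject summaries."""
    summaries_a = list(summaries_a)
    summaries_b = list(summaries_b)
    if not summaries_a or not summaries_b:
        raise ParameterError("both groups need at least one subject")
    labels = _check_common_labels(summaries_a + summaries_b)
    mean_a, sd_a = group_mean_matrix(summaries_a)
    mean_b, sd_b = group_mean_matrix(summaries_b)
    dens_a = np.array([s.expected_density for s in summaries_a])
    dens_b = np.array([s.expected_density for s in summaries_b])
    test = density_test(dens_a, dens_b, equal_var=equal_var)
    d = mean_a.shape[0]
    pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
    pairs.sort(key=lambda e: (-mean_a[e[0], e[1]], e[0], e[1]))
    if labels is None:
        labels_t = tuple(f"roi{i}" for i in range(d))
    else:
        labels_t = labels
    strongest = [
        ((labels_t[i], labels_t[j]), float(mean_a[i, j]), float(mean_b[i, j]))
        for i, j in pairs
    ]
    return GroupResult(
        mean_partials_a=mean_a, mean_partials_b=mean_b,
        sd_partials_a=sd_a, sd_partials_b=sd_b,
        density_a=dens_a, density_b=dens_b,
        test=test, strongest_edges=strongest, labels=labels,
    )
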