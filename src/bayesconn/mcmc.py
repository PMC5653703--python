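"""Per-subject posterior inference over (binary skeleton, partial correlations).

The model: T rows of an ROI time series are treated as i.i.d. zero-mean
Gaussian with precision K, K | G ~ W_G(delta, D), and independent Bernoulli
edge priors on G.  The sampler alternates single-edge add/delete
Metropolis–Hastings moves — with the intractable G-Wishart normalising
constant handled by an exchange-style auxiliary draw and conditional Bayes
factors — with exact conjugate refreshes of K | G, data.  Posterior
summaries are the per-edge inclusion probability, the expected partial
correlation, and the expected network density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .errors import ConvergenceError, DataError, ParameterError, SettingsError
from .gwishart import PriorSpec, check_graph


@dataclass(frozen=True)
class McmcSettings:
    """Chain length controls: total iterations, burn-in discarded from the
    front, thinning stride over the remainder, and the root seed."""

    n_iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise SettingsError("n_iterations must be positive")
        if not (0 <= self.burn_in < self.n_iterations):
            raise SettingsError(
                f"burn_in ({self.burn_in}) must be < n_iterations ({self.n_iterations})"
            )
        if self.thinning < 1:
            raise SettingsError("thinning must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior summaries for one subject.

    ``edge_probability`` and ``expected_partials`` are symmetric d x d;
    ``expected_density`` is the mean over retained graph samples of
    |E| / (d(d-1)/2).  ``diagnostics`` holds per-edge acceptance rates and
    the retained density trace.
    """

    edge_probability: np.ndarray
    expected_partials: np.ndarray
    expected_density: float
    n_retained_samples: int
    diagnostics: dict = field(default_factory=dict)
    labels: tuple[str, ...] | None = None

    @property
    def n_rois(self) -> int:
        return self.edge_probability.shape[0]

    def reorder(self, perm: Sequence[int]) -> "PosteriorSummary":
        """Consistently permute ROI order in every summary matrix."""
        p = np.asarray(perm)
        labels = None if self.labels is None else tuple(self.labels[i] for i in p)
        diag = dict(self.diagnostics)
        if "edge_acceptance_rate" in diag:
            diag["edge_acceptance_rate"] = diag["edge_acceptance_rate"][np.ix_(p, p)]
        return PosteriorSummary(
            edge_probability=self.edge_probability[np.ix_(p, p)],
            expected_partials=self.expected_partials[np.ix_(p, p)],
            expected_density=self.expected_density,
            n_retained_samples=self.n_retained_samples,
            diagnostics=diag,
            labels=labels,
        )


def expected_density(graph_samples: Sequence[np.ndarray]) -> float:
    """Mean network density |E_s| / (d(d-1)/2) over a set of graph samples."""
    samples = list(graph_samples)
    if not samples:
        raise ParameterError("expected_density needs at least one graph sample")
    d = np.asarray(samples[0]).shape[0]
    n_pairs = d * (d - 1) // 2
    dens = []
    for G in samples:
        G = np.asarray(G)
        if G.shape != (d, d):
            raise ParameterError("graph samples must share a common dimension")
        dens.append(np.triu(G, 1).sum() / n_pairs)
    return float(np.mean(dens))


def _extract_values(series) -> tuple[np.ndarray, tuple[str, ...] | None]:
    labels = getattr(series, "labels", None)
    values = getattr(series, "values", series)
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise DataError(f"time series must be 2-D (T x d), got shape {X.shape}")
    return X, tuple(labels) if labels is not None else None


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Center each column and scale to unit variance.  Partial correlations
    are scale-invariant, so this only conditions the numerics."""
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(np.flatnonzero(sd == 0))
        raise DataError(f"constant columns cannot be standardized: indices {bad}")
    return X / sd


def run_mcmc(series, prior: PriorSpec, settings: McmcSettings) -> PosteriorSummary:
    """Posterior over (G, K) for one subject's cleaned ROI time series.

    Columns are standardized internally; the data enter only through the
    scatter matrix S = X'X.  A fixed seed gives bit-identical summaries.
    """
    X, labels = _extract_values(series)
    if not np.all(np.isfinite(X)):
        raise DataError("time series contains non-finite values")
    T, d = X.shape
    if d < 2:
        raise DataError("need at least two ROIs")
    if T <= d:
        warnings.warn(
            f"T={T} rows for d={d} ROIs: fewer samples than dimensions; "
            "the posterior is prior-dominated",
            stacklevel=2,
        )
    Xs = standardize_columns(X)
    S = Xs.T @ Xs
    D = prior.scale_matrix(d)
    edge_sum, part_sum, dens, att, acc, kept, n_fail = _kernels._run_chain(
        S,
        float(T),
        float(prior.delta),
        D,
        float(prior.edge_prior),
        int(settings.n_iterations),
        int(settings.burn_in),
        int(settings.thinning),
        int(settings.seed) & 0x7FFFFFFF,
        _kernels.IPF_MAX_SWEEPS,
        _kernels.IPF_TOL,
    )
    if n_fail > 0:
        raise ConvergenceError(
            f"G-Wishart completion failed to converge in {n_fail} sampler steps",
            n_iterations=int(settings.n_iterations),
        )
    edge_prob = edge_sum / kept
    edge_prob = edge_prob + edge_prob.T
    partials = part_sum / kept
    partials = partials + partials.T
    np.fill_diagonal(partials, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc_rate = np.where(att > 0, acc / np.maximum(att, 1), 0.0)
    acc_rate = acc_rate + acc_rate.T
    return PosteriorSummary(
        edge_probability=edge_prob,
        expected_partials=partials,
        expected_density=float(dens.mean()),
        n_retained_samples=int(kept),
        diagnostics={
            "edge_acceptance_rate": acc_rate,
            "density_trace": dens,
            "edge_attempts": att + att.T,
        },
        labels=labels,
    )
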