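"""ROI-level confound regression, temporal high-pass filtering, and
participant-exclusion accounting.

Works directly on extracted ROI time series: nuisance regressors (motion,
mean white-matter and CSF signal, and their temporal derivatives) are
removed by least squares, then slow drifts below the cutoff frequency are
removed either by an FSL-style Gaussian-weighted running-line detrend or by
projection onto a discrete-cosine drift basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import ConfoundSet, RoiTimeSeries
from .errors import DesignMatrixError, ParameterError, SchemaError

GAUSSIAN_RUNNING_LINE = "gaussian_running_line"
DCT_PROJECTION = "dct"


@dataclass
class CleanSeries:
    """A residualized/filtered T x d matrix plus a provenance trail of the
    steps that produced it."""

    values: np.ndarray
    labels: tuple[str, ...] | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class CohortLedger:
    """Acquisition and exclusion bookkeeping per group."""

    acquired_a: int
    acquired_b: int
    excluded_a: tuple[tuple[str, str], ...] = ()
    excluded_b: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.acquired_a < 0 or self.acquired_b < 0:
            raise ParameterError("acquired counts must be non-negative")
        if len(self.excluded_a) > self.acquired_a or len(self.excluded_b) > self.acquired_b:
            raise ParameterError("cannot exclude more subjects than were acquired")
        for sid, reason in self.excluded_a + self.excluded_b:
            if not reason:
                raise ParameterError(f"exclusion of {sid!r} has an empty reason")


def apply_exclusions(ledger: CohortLedger) -> tuple[int, int]:
    """Retained counts per group: acquired minus the listed exclusions."""
    return (
        ledger.acquired_a - len(ledger.excluded_a),
        ledger.acquired_b - len(ledger.excluded_b),
    )


def _as_matrix(series) -> tuple[np.ndarray, tuple[str, ...] | None, list[dict]]:
    if isinstance(series, CleanSeries):
        return np.asarray(series.values, float), series.labels, list(series.provenance)
    if isinstance(series, RoiTimeSeries):
        return np.asarray(series.values, float), tuple(series.labels), []
    X = np.asarray(series, dtype=float)
    if X.ndim != 2:
        raise ParameterError(f"expected a T x d matrix, got shape {X.shape}")
    return X, None, []


def _dedupe_columns(C: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep: list[int] = []
    for j in range(C.shape[1]):
        if not any(np.array_equal(C[:, j], C[:, k]) for k in keep):
            keep.append(j)
    return C[:, keep], [names[j] for j in keep]


def regress_confounds(series, confounds: ConfoundSet) -> CleanSeries:
    """Residualize each ROI column against the confound design plus an
    intercept, by least-squares projection.

    Residuals are orthogonal to every regressor (including the mean, so the
    output is column-centered).  Exactly duplicated confound columns are
    dropped; any remaining rank deficiency raises ``DesignMatrixError``
    naming the collinear columns.
    """
    X, labels, prov = _as_matrix(series)
    C = np.asarray(confounds.regressors, dtype=float)
    names = list(confounds.names)
    if C.shape[0] != X.shape[0]:
        raise SchemaError(
            f"series has {X.shape[0]} rows but confounds have {C.shape[0]}"
        )
    C, names = _dedupe_columns(C, names)
    design = np.column_stack([np.ones(X.shape[0]), C])
    design_names = ["intercept"] + names
    # rank check via QR: tiny diagonal entries of R mark collinear columns
    Q, R = np.linalg.qr(design)
    diag = np.abs(np.diag(R))
    scale = np.linalg.norm(design, axis=0)
    bad = [design_names[j] for j in range(design.shape[1])
           if diag[j] <= 1e-10 * max(scale[j], 1.0)]
    if bad:
        raise DesignMatrixError(
            f"confound design is rank deficient; collinear columns: {bad}",
            collinear=bad,
        )
    resid = X - Q @ (Q.T @ X)
    prov.append({
        "step": "regress_confounds",
        "regressors": design_names,
    })
    return CleanSeries(values=resid, labels=labels, provenance=prov)


def _running_line_fit(X: np.ndarray, sigma_vol: float) -> np.ndarray:
    """Gaussian-weighted local linear fit evaluated at every time point
    (the trend a running-line high-pass removes).  Window truncated at
    +/- 4 sigma."""
    T = X.shape[0]
    half = int(np.ceil(4.0 * sigma_vol))
    fitted = np.empty_like(X)
    t_all = np.arange(T, dtype=float)
    for t in range(T):
        lo = max(0, t - half)
        hi = min(T, t + half + 1)
        s = t_all[lo:hi] - t
        w = np.exp(-0.5 * (s / sigma_vol) ** 2)
        Sw = w.sum()
        Sx = (w * s).sum()
        Sxx = (w * s * s).sum()
        Sy = w @ X[lo:hi]
        Sxy = (w * s) @ X[lo:hi]
        denom = Sw * Sxx - Sx * Sx
        # weighted-LS intercept at s=0
        fitted[t] = (Sxx * Sy - Sx * Sxy) / denom
    return fitted


def _dct_drift_basis(T: int, tr_seconds: float, cutoff_seconds: float) -> np.ndarray:
    """Discrete-cosine drift regressors with period longer than the cutoff."""
    duration = T * tr_seconds
    n_basis = int(np.floor(2.0 * duration / cutoff_seconds))
    t = np.arange(T)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * T)) for k in range(1, n_basis + 1)]
    if not cols:
        return np.empty((T, 0))
    return np.column_stack(cols)


def highpass_filter(series, cutoff_seconds: float, tr_seconds: float,
                    method: str = DCT_PROJECTION) -> CleanSeries:
    """Remove fluctuations slower than ``cutoff_seconds`` from each column.

    ``gaussian_running_line`` subtracts a Gaussian-weighted local linear
    trend (sigma = cutoff / (2 TR) volumes, the FSL convention);
    ``dct`` projects out a discrete-cosine drift basis whose periods exceed
    the cutoff.  Output columns are mean-centered.
    """
    X, labels, prov = _as_matrix(series)
    if tr_seconds <= 0:
        raise ParameterError("tr_seconds must be positive")
    if cutoff_seconds <= 2.0 * tr_seconds:
        raise ParameterError(
            f"cutoff_seconds ({cutoff_seconds}) must exceed twice the TR "
            f"({tr_seconds}); periods at or below 2 TR are unresolvable"
        )
    if method == GAUSSIAN_RUNNING_LINE:
        sigma_vol = cutoff_seconds / (2.0 * tr_seconds)
        out = X - _running_line_fit(X, sigma_vol)
    elif method == DCT_PROJECTION:
        B = _dct_drift_basis(X.shape[0], tr_seconds, cutoff_seconds)
        design = np.column_stack([np.ones(X.shape[0]), B])
        Q, _ = np.linalg.qr(design)
        out = X - Q @ (Q.T @ X)
    else:
        raise ParameterError(f"unknown high-pass method {method!r}")
    out = out - out.mean(axis=0)
    prov.append({
        "step": "highpass_filter",
        "cutoff_seconds": float(cutoff_seconds),
        "tr_seconds": float(tr_seconds),
        "method": method,
    })
    return CleanSeries(values=out, labels=labels, provenance=prov)


def preprocess_subject(series, confounds: ConfoundSet, cutoff_seconds: float = 100.0,
                       tr_seconds: float = 2.38, order: str = "regress-first",
                       method: str = DCT_PROJECTION) -> CleanSeries:
    """Confound regression and high-pass filtering in the configured order.

    With ``filter-first`` the confound columns are themselves high-pass
    filtered before regression, so the two orders agree up to numerical
    tolerance (both steps are linear projections onto nested spans).
    """
    if order == "regress-first":
        clean = regress_confounds(series, confounds)
        return highpass_filter(clean, cutoff_seconds, tr_seconds, method)
    if order == "filter-first":
        filt = highpass_filter(series, cutoff_seconds, tr_seconds, method)
        fc = highpass_filter(confounds.regressors, cutoff_seconds, tr_seconds, method)
        filtered_confounds = ConfoundSet(regressors=fc.values, names=confounds.names)
        out = regress_confounds(filt, filtered_confounds)
        return out
    raise ParameterError(f"unknown preprocessing order {order!r}")
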