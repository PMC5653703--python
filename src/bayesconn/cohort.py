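"""Synthetic two-group cohorts of ROI time series with known graphical structure.

Emulates the study conditions this pipeline targets: d=14 subcortical ROIs,
T=110 volumes at TR=2.38 s, 72 subjects in group A (patient-like) and 39 in
group B (control-like numbers are configurable), multivariate-Gaussian BOLD
signal whose precision matrix is supported on a sparse graph dominated by
strong homotopic (left/right) edges, contaminated by low-frequency drift and
nuisance-coupled signal.  Group B shares group A's skeleton with every
partial correlation shrunk by a factor (1 - group_effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, MatrixError, ParameterError
from .gwishart import check_graph, partial_from_precision
from .rois import RoiSet, default_roi_set

#: Homotopic partial-correlation targets for the default template, keyed by
#: structure name.  Thalamus and caudate carry the two strongest couplings;
#: remaining pairs default to a moderate 0.30.
DEFAULT_HOMOTOPIC_TARGETS = {
    "Thalamus": 0.55,
    "Caudate": 0.41,
}
DEFAULT_HOMOTOPIC_FALLBACK = 0.30
DEFAULT_EXTRA_EDGE_PROB = 0.2
DEFAULT_EXTRA_MAGNITUDE_RANGE = (0.10, 0.25)

MOTION_NAMES = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the acquisition this pipeline emulates: 110 volumes at
    TR=2.38 s over 14 ROIs, 72 group-A vs 39 group-B subjects, a mild 10%
    group shrinkage of partial correlations, and moderate drift / nuisance
    contamination (in units of the unit-variance clean signal).
    """

    n_group_a: int = 72
    n_group_b: int = 39
    T: int = 110
    tr_seconds: float = 2.38
    group_effect: float = 0.1
    drift_amplitude: float = 0.5
    confound_coupling: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ParameterError("both groups need at least one subject")
        if self.T < 2:
            raise ParameterError("T must be at least 2")
        if self.tr_seconds <= 0:
            raise ParameterError("tr_seconds must be positive")
        if not (0.0 <= self.group_effect <= 1.0):
            raise ParameterError("group_effect must lie in [0, 1]")
        if self.drift_amplitude < 0 or self.confound_coupling < 0:
            raise ParameterError("nuisance amplitudes must be non-negative")


@dataclass
class PrecisionModel:
    """Ground truth for simulation: graph G, precision K, partials rho."""

    graph: np.ndarray
    precision: np.ndarray
    partials: np.ndarray

    def validate(self, tol: float = 1e-8) -> None:
        G = check_graph(self.graph)
        K = np.asarray(self.precision)
        rho = np.asarray(self.partials)
        if K.shape != G.shape or rho.shape != G.shape:
            raise MatrixError("graph, precision and partials must share a shape")
        if np.min(np.linalg.eigvalsh(K)) <= 0:
            raise MatrixError("precision matrix is not positive definite")
        off = ~np.eye(G.shape[0], dtype=bool)
        if np.any((G == 0) & off & (K != 0.0)):
            raise MatrixError("precision has support outside the graph")
        if not np.allclose(rho, partial_from_precision(K), atol=tol):
            raise MatrixError("partials do not match the precision matrix")
        if np.any(np.abs(rho[off]) >= 1):
            raise MatrixError("off-diagonal partial correlations must have |rho| < 1")

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


@dataclass
class ConfoundSet:
    """Nuisance design: T x k regressor matrix with column names."""

    regressors: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        R = np.asarray(self.regressors, dtype=float)
        if R.ndim != 2 or R.shape[1] != len(self.names):
            raise ParameterError("regressor matrix and names disagree")
        if np.any(np.all(R == 0.0, axis=0)):
            raise ParameterError("confound design contains a constant-zero column")
        self.regressors = R


@dataclass
class RoiTimeSeries:
    """One subject's T x d BOLD matrix with ROI labels and a group tag."""

    values: np.ndarray
    labels: tuple[str, ...]
    subject_id: str = ""
    group: str = ""

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[1] != len(self.labels):
            raise ParameterError(
                f"values shape {V.shape} does not match {len(self.labels)} labels"
            )
        self.values = V

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    seed: int
    series: RoiTimeSeries
    confounds: ConfoundSet


@dataclass
class Cohort:
    roi_set: RoiSet
    spec: CohortSpec
    model_a: PrecisionModel
    model_b: PrecisionModel
    subjects: list[SubjectRecord]

    def group_subjects(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]


def build_template_graph(roi_set: RoiSet, extra_edge_prob: float = DEFAULT_EXTRA_EDGE_PROB,
                         seed: int = 0) -> np.ndarray:
    """Binary template skeleton: all homotopic pairs forced on, every other
    pair present independently with ``extra_edge_prob``."""
    if not (0.0 <= extra_edge_prob <= 1.0):
        raise ParameterError(f"extra_edge_prob must lie in [0,1], got {extra_edge_prob}")
    d = roi_set.n_rois
    rng = np.random.default_rng(seed)
    G = np.zeros((d, d), dtype=np.int8)
    homotopic = set()
    for i, j in roi_set.homotopic_pairs:
        G[i, j] = G[j, i] = 1
        homotopic.add((min(i, j), max(i, j)))
    for i in range(d):
        for j in range(i + 1, d):
            if (i, j) in homotopic:
                continue
            if rng.random() < extra_edge_prob:
                G[i, j] = G[j, i] = 1
    return G


def default_homotopic_targets(roi_set: RoiSet | None = None) -> dict[tuple[int, int], float]:
    """Partial-correlation targets for the homotopic pairs of the default
    template (0.55 thalamus, 0.41 caudate, 0.30 elsewhere)."""
    roi_set = roi_set or default_roi_set()
    targets: dict[tuple[int, int], float] = {}
    for i, j in roi_set.homotopic_pairs:
        structure = roi_set.labels[i].split("_", 1)[-1]
        targets[(i, j)] = DEFAULT_HOMOTOPIC_TARGETS.get(structure, DEFAULT_HOMOTOPIC_FALLBACK)
    return targets


def generate_precision(graph: np.ndarray,
                       target_partials: dict[tuple[int, int], float] | None = None,
                       seed: int = 0,
                       default_magnitude_range: tuple[float, float] = DEFAULT_EXTRA_MAGNITUDE_RANGE,
                       max_target_deviation: float = 0.02,
                       spd_margin: float = 1e-3) -> PrecisionModel:
    """Construct an SPD precision matrix supported exactly on ``graph`` whose
    implied partial correlations hit the requested targets.

    Starts from K = I - R with R holding the targets (so the implied partials
    equal the targets exactly when K is already SPD); if not SPD, applies the
    minimal diagonal loading, which shrinks every partial uniformly by
    1/(1+c).  Raises if the shrinkage would move any target by more than
    ``max_target_deviation``, naming the largest-magnitude edges.
    """
    G = check_graph(graph)
    d = G.shape[0]
    target_partials = dict(target_partials or {})
    rng = np.random.default_rng(seed)
    R = np.zeros((d, d))
    for (i, j), v in target_partials.items():
        if G[i, j] == 0:
            raise ParameterError(f"target specified for non-edge ({i},{j})")
        if not abs(v) < 1:
            raise ParameterError(f"|target| must be < 1 for edge ({i},{j}), got {v}")
        R[i, j] = R[j, i] = v
    lo, hi = default_magnitude_range
    for i in range(d):
        for j in range(i + 1, d):
            if G[i, j] and (i, j) not in target_partials and (j, i) not in target_partials:
                mag = rng.uniform(lo, hi)
                sign = 1.0 if rng.random() < 0.8 else -1.0
                R[i, j] = R[j, i] = sign * mag
    P = np.eye(d) - R
    lam_min = float(np.min(np.linalg.eigvalsh(P)))
    c = max(0.0, spd_margin - lam_min)
    if c > 0:
        deviation = np.max(np.abs(R)) * c / (1.0 + c)
        if deviation > max_target_deviation:
            order = np.dstack(np.triu_indices(d, 1))[0]
            offenders = sorted(
                ((i, j) for i, j in order if G[i, j]),
                key=lambda e: -abs(R[e[0], e[1]]),
            )[:3]
            raise ConvergenceError(
                "requested partial correlations are infeasible under the SPD "
                f"constraint (needed diagonal loading {c:.4f}, max target shift "
                f"{deviation:.4f})",
                offending_edges=[(int(i), int(j)) for i, j in offenders],
            )
    K = P + c * np.eye(d)
    rho = partial_from_precision(K)
    model = PrecisionModel(graph=G, precision=K, partials=rho)
    model.validate()
    return model


def shrink_model(model: PrecisionModel, group_effect: float) -> PrecisionModel:
    """Same skeleton, every partial correlation multiplied by (1 - group_effect).

    The shrunk precision I - (1-g) R is a convex combination of the identity
    and the original unit-diagonal precision, hence stays SPD.
    """
    if not (0.0 <= group_effect <= 1.0):
        raise ParameterError("group_effect must lie in [0, 1]")
    g = group_effect
    d = model.graph.shape[0]
    R = model.partials.copy()
    np.fill_diagonal(R, 0.0)
    K = np.eye(d) - (1.0 - g) * R
    graph = model.graph.copy()
    K[(graph == 0) & ~np.eye(d, dtype=bool)] = 0.0
    rho = partial_from_precision(K)
    out = PrecisionModel(graph=graph, precision=K, partials=rho)
    out.validate()
    return out


def template_model(roi_set: RoiSet | None = None,
                   extra_edge_prob: float = DEFAULT_EXTRA_EDGE_PROB,
                   seed: int = 0) -> PrecisionModel:
    """Default generating model: homotopic-dominated template skeleton with
    the standard homotopic targets."""
    roi_set = roi_set or default_roi_set()
    G = build_template_graph(roi_set, extra_edge_prob, seed)
    return generate_precision(G, default_homotopic_targets(roi_set), seed=seed + 1)


def _ar1(rng: np.random.Generator, T: int, phi: float = 0.9) -> np.ndarray:
    x = np.empty(T)
    innov_sd = np.sqrt(1.0 - phi * phi)
    x[0] = rng.standard_normal()
    for t in range(1, T):
        x[t] = phi * x[t - 1] + innov_sd * rng.standard_normal()
    return x


def _backward_difference(X: np.ndarray) -> np.ndarray:
    """Temporal derivative as backward differences, first row zero-padded."""
    D = np.zeros_like(X)
    D[1:] = X[1:] - X[:-1]
    return D


def simulate_confounds(T: int, seed: int) -> ConfoundSet:
    """Motion-like nuisance design: 6 AR(1) motion traces (phi=0.9), mean WM
    and CSF signals, plus backward-difference temporal derivatives of all."""
    if T < 2:
        raise ParameterError("T must be at least 2 to form temporal derivatives")
    rng = np.random.default_rng(seed)
    base = np.column_stack([_ar1(rng, T) for _ in range(8)])
    names = MOTION_NAMES + ("wm_mean", "csf_mean")
    deriv = _backward_difference(base)
    deriv_names = tuple(f"{n}_derivative" for n in names)
    return ConfoundSet(
        regressors=np.column_stack([base, deriv]),
        names=names + deriv_names,
    )


def simulate_subject(model: PrecisionModel, spec: CohortSpec, seed: int,
                     labels: tuple[str, ...] | None = None,
                     subject_id: str = "", group: str = "") -> tuple[RoiTimeSeries, ConfoundSet]:
    """Simulate one subject: i.i.d. Gaussian rows with covariance inv(K),
    plus slow drift (sinusoid + linear trend) and a linear mix of the
    confound regressors."""
    if spec.T < 2:
        raise ParameterError("T must be at least 2")
    model.validate()
    d = model.graph.shape[0]
    if labels is None:
        labels = tuple(f"roi{i}" for i in range(d))
    rng = np.random.default_rng(seed)
    T = spec.T
    L = np.linalg.cholesky(model.covariance)
    clean = rng.standard_normal((T, d)) @ L.T
    confounds = simulate_confounds(T, seed=int(rng.integers(2**31 - 1)))
    X = clean.copy()
    if spec.drift_amplitude > 0:
        t = np.arange(T) * spec.tr_seconds
        period = max(120.0, T * spec.tr_seconds / 2.0)
        phase = rng.uniform(0, 2 * np.pi, size=d)
        slope = rng.uniform(-1.0, 1.0, size=d)
        drift = np.sin(2 * np.pi * t[:, None] / period + phase[None, :])
        drift = drift + slope[None, :] * (t[:, None] / t[-1] - 0.5) * 2.0
        X = X + spec.drift_amplitude * drift
    if spec.confound_coupling > 0:
        k = confounds.regressors.shape[1]
        mix = rng.standard_normal((k, d)) / np.sqrt(k)
        X = X + spec.confound_coupling * confounds.regressors @ mix
    series = RoiTimeSeries(values=X, labels=labels, subject_id=subject_id, group=group)
    return series, confounds


def simulate_cohort(spec: CohortSpec, roi_set: RoiSet | None = None,
                    extra_edge_prob: float = DEFAULT_EXTRA_EDGE_PROB) -> Cohort:
    """Two-group cohort: group A from the template model, group B from the
    same skeleton with partials shrunk by (1 - group_effect).  Subject seeds
    derive deterministically from ``spec.seed``."""
    roi_set = roi_set or default_roi_set()
    root = np.random.SeedSequence(spec.seed)
    model_seed_ss, subjects_ss = root.spawn(2)
    model_seed = int(model_seed_ss.generate_state(1)[0] % (2**31 - 1))
    model_a = template_model(roi_set, extra_edge_prob, seed=model_seed)
    model_b = shrink_model(model_a, spec.group_effect)
    children = subjects_ss.spawn(spec.n_group_a + spec.n_group_b)
    subjects: list[SubjectRecord] = []
    plan = [("a", model_a, spec.n_group_a, 0), ("b", model_b, spec.n_group_b, spec.n_group_a)]
    for group, model, n, offset in plan:
        for k in range(n):
            child = children[offset + k]
            sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            sid = f"sub-{group}{k + 1:03d}"
            series, confounds = simulate_subject(
                model, spec, sub_seed, labels=roi_set.labels,
                subject_id=sid, group=group,
            )
            subjects.append(SubjectRecord(sid, group, sub_seed, series, confounds))
    return Cohort(roi_set=roi_set, spec=spec, model_a=model_a, model_b=model_b,
                  subjects=subjects)
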