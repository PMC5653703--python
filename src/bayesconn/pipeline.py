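"""End-to-end pipeline: simulate -> preprocess -> infer (per subject) -> compare.

Configuration is a single validated object (loadable from JSON or YAML);
every stage writes plain-text artifacts plus a manifest with per-artifact
SHA-256 checksums, so an identical configuration reproduces every artifact
bit-exactly.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, io
from .cohort import CohortSpec, simulate_cohort
from .errors import BayesconnError, ParseError
from .group import GroupResult, compare_groups
from .gwishart import PriorSpec
from .mcmc import McmcSettings, PosteriorSummary, run_mcmc
from .preprocess import preprocess_subject
from .rois import RoiSet, default_roi_set

log = logging.getLogger("bayesconn")


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_group_a: int = 72
    n_group_b: int = 39
    T: int = 110
    tr_seconds: float = 2.38
    group_effect: float = Field(0.1, ge=0.0, le=1.0)
    drift_amplitude: float = 0.5
    confound_coupling: float = 0.5
    seed: int = 0
    extra_edge_prob: float = Field(0.2, ge=0.0, le=1.0)

    def to_spec(self) -> CohortSpec:
        return CohortSpec(
            n_group_a=self.n_group_a, n_group_b=self.n_group_b, T=self.T,
            tr_seconds=self.tr_seconds, group_effect=self.group_effect,
            drift_amplitude=self.drift_amplitude,
            confound_coupling=self.confound_coupling, seed=self.seed,
        )


class PriorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    delta: float = Field(3.0, gt=2.0)
    edge_prior: float = Field(0.5, gt=0.0, lt=1.0)

    def to_spec(self) -> PriorSpec:
        return PriorSpec(delta=self.delta, edge_prior=self.edge_prior)


class McmcConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 5
    seed: int = 0

    def to_settings(self, seed_offset: int = 0) -> McmcSettings:
        return McmcSettings(n_iterations=self.n_iterations, burn_in=self.burn_in,
                            thinning=self.thinning,
                            seed=(self.seed + seed_offset) & 0x7FFFFFFF)


class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cutoff_seconds: float = 100.0
    order: Literal["regress-first", "filter-first"] = "regress-first"
    method: Literal["gaussian_running_line", "dct"] = "dct"


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    out_dir: str = "pipeline_out"
    cohort: CohortConfig = CohortConfig()
    prior: PriorConfig = PriorConfig()
    mcmc: McmcConfig = McmcConfig()
    preprocessing: PreprocessConfig = PreprocessConfig()


def load_config(path: Path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ParseError(f"could not parse config: {exc}", path=str(path)) from exc
    if not isinstance(raw, dict):
        raise ParseError("config must be a mapping", path=str(path))
    return PipelineConfig.model_validate(raw)


def _summary_paths(summaries_dir: Path, sid: str) -> dict[str, Path]:
    return {
        "edge_probability": summaries_dir / f"{sid}_edge_probability.csv",
        "expected_partials": summaries_dir / f"{sid}_expected_partials.csv",
        "edges": summaries_dir / f"{sid}_edges.tsv",
        "report": summaries_dir / f"{sid}_summary.json",
    }


def write_subject_summary(summaries_dir: Path, sid: str,
                          summary: PosteriorSummary) -> list[Path]:
    paths = _summary_paths(summaries_dir, sid)
    labels = summary.labels or tuple(f"roi{i}" for i in range(summary.n_rois))
    io.write_matrix_csv(paths["edge_probability"], summary.edge_probability, labels)
    io.write_matrix_csv(paths["expected_partials"], summary.expected_partials, labels)
    io.write_edge_list_tsv(paths["edges"], labels, summary.edge_probability,
                           summary.expected_partials)
    io.write_json(paths["report"], {
        "subject_id": sid,
        "expected_density": summary.expected_density,
        "n_retained_samples": summary.n_retained_samples,
        "density_trace": [float(x) for x in summary.diagnostics["density_trace"]],
        "mean_edge_acceptance_rate": float(
            np.mean(summary.diagnostics["edge_acceptance_rate"])
        ),
    })
    return list(paths.values())


def read_subject_summary(summaries_dir: Path, sid: str) -> PosteriorSummary:
    paths = _summary_paths(summaries_dir, sid)
    ep = io.read_matrix_csv(paths["edge_probability"])
    pp = io.read_matrix_csv(paths["expected_partials"])
    report = io.read_json(paths["report"])
    trace = np.asarray(report["density_trace"], dtype=float)
    return PosteriorSummary(
        edge_probability=ep.to_numpy(),
        expected_partials=pp.to_numpy(),
        expected_density=float(report["expected_density"]),
        n_retained_samples=int(report["n_retained_samples"]),
        diagnostics={"density_trace": trace},
        labels=tuple(ep.columns),
    )


def run_pipeline(config: PipelineConfig,
                 roi_set: RoiSet | None = None) -> GroupResult:
    """Execute the four stages and write all artifacts under ``out_dir``.

    Stage errors are re-raised annotated with the stage name and subject id.
    Returns the group-level result.
    """
    roi_set = roi_set or default_roi_set()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    try:
        cohort = simulate_cohort(config.cohort.to_spec(), roi_set,
                                 extra_edge_prob=config.cohort.extra_edge_prob)
        cohort_dir = out_dir / "cohort"
        io.write_cohort(cohort, cohort_dir)
        artifacts.extend(sorted(cohort_dir.iterdir()))
    except BayesconnError as exc:
        raise type(exc)(f"[simulate] {exc}") from exc
    timings["simulate"] = time.perf_counter() - t0
    log.info("simulate: %d subjects in %.1fs", len(cohort.subjects), timings["simulate"])

    t0 = time.perf_counter()
    clean_dir = out_dir / "clean"
    clean_dir.mkdir(exist_ok=True)
    clean_series = {}
    pp = config.preprocessing
    for rec in cohort.subjects:
        try:
            clean = preprocess_subject(
                rec.series, rec.confounds,
                cutoff_seconds=pp.cutoff_seconds,
                tr_seconds=config.cohort.tr_seconds,
                order=pp.order, method=pp.method,
            )
        except BayesconnError as exc:
            raise type(exc)(f"[preprocess:{rec.subject_id}] {exc}") from exc
        clean_series[rec.subject_id] = clean
        path = clean_dir / f"{rec.subject_id}_clean.tsv"
        io.write_timeseries_tsv(path, clean.values, clean.labels)
        artifacts.append(path)
    timings["preprocess"] = time.perf_counter() - t0
    log.info("preprocess: done in %.1fs", timings["preprocess"])

    t0 = time.perf_counter()
    summaries_dir = out_dir / "summaries"
    summaries_dir.mkdir(exist_ok=True)
    prior = config.prior.to_spec()
    summaries_a, summaries_b = [], []
    for k, rec in enumerate(cohort.subjects):
        try:
            settings = config.mcmc.to_settings(seed_offset=1000 * (k + 1))
            summary = run_mcmc(clean_series[rec.subject_id], prior, settings)
        except BayesconnError as exc:
            raise type(exc)(f"[infer:{rec.subject_id}] {exc}") from exc
        (summaries_a if rec.group == "a" else summaries_b).append(summary)
        artifacts.extend(write_subject_summary(summaries_dir, rec.subject_id, summary))
    timings["infer"] = time.perf_counter() - t0
    log.info("infer: %d subjects in %.1fs", len(cohort.subjects), timings["infer"])

    t0 = time.perf_counter()
    try:
        result = compare_groups(summaries_a, summaries_b, roi_set)
    except BayesconnError as exc:
        raise type(exc)(f"[compare] {exc}") from exc
    group_dir = out_dir / "group"
    group_dir.mkdir(exist_ok=True)
    io.write_matrix_csv(group_dir / "mean_partials_a.csv",
                        result.mean_partials_a, roi_set.labels)
    io.write_matrix_csv(group_dir / "mean_partials_b.csv",
                        result.mean_partials_b, roi_set.labels)
    io.write_json(group_dir / "group_report.json", group_report_dict(result))
    artifacts.extend(sorted(group_dir.iterdir()))
    timings["compare"] = time.perf_counter() - t0

    manifest = {
        "version": __version__,
        "config": config.model_dump(),
        "timings_seconds": {k: round(v, 3) for k, v in timings.items()},
        "checksums": {
            str(p.relative_to(out_dir)): io.sha256_file(p)
            for p in sorted(set(artifacts))
        },
    }
    io.write_json(out_dir / "manifest.json", manifest)
    return result


def group_report_dict(result: GroupResult) -> dict:
    return {
        "density_a": [float(x) for x in result.density_a],
        "density_b": [float(x) for x in result.density_b],
        "density_mean_a": result.test.mean_a,
        "density_sd_a": result.test.sd_a,
        "density_mean_b": result.test.mean_b,
        "density_sd_b": result.test.sd_b,
        "t_statistic": result.test.t_statistic,
        "p_value": result.test.p_value,
        "equal_var": result.test.equal_var,
        "degenerate_variance": result.test.degenerate_variance,
        "strongest_edges": [
            {"pair": list(pair), "mean_a": a, "mean_b": b}
            for pair, a, b in result.strongest_edges[:10]
        ],
    }
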