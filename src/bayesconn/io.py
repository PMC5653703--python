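"""On-disk artifact formats and their strict round-trip parsers.

All artifacts are plain text: subject time series and confounds as TSV,
summary matrices as labeled CSV, edge lists as TSV, reports and manifests
as JSON.  Readers validate shape and labeling and raise ``ParseError``
rather than silently misreading.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, ConfoundSet, RoiTimeSeries
from .errors import ParseError

FLOAT_FORMAT = "%.12g"


def write_timeseries_tsv(path: Path, values: np.ndarray, labels) -> None:
    df = pd.DataFrame(np.asarray(values, float), columns=list(labels))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_timeseries_tsv(path: Path, expect_columns: int | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"could not parse TSV: {exc}", path=str(path)) from exc
    if df.empty:
        raise ParseError("TSV contains no data rows", path=str(path))
    widths = {len(line.split("\t")) for line in path.read_text().strip().splitlines()}
    if len(widths) != 1:
        raise ParseError("ragged rows: inconsistent column counts", path=str(path))
    if expect_columns is not None and df.shape[1] != expect_columns:
        raise ParseError(
            f"expected {expect_columns} columns, found {df.shape[1]}", path=str(path)
        )
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise ParseError("non-numeric entries in time-series TSV", path=str(path))
    return df


def write_matrix_csv(path: Path, M: np.ndarray, labels) -> None:
    labels = list(labels)
    df = pd.DataFrame(np.asarray(M, float), index=labels, columns=labels)
    df.to_csv(path, float_format=FLOAT_FORMAT)


def read_matrix_csv(path: Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise ParseError(f"could not parse matrix CSV: {exc}", path=str(path)) from exc
    if df.shape[0] != df.shape[1]:
        raise ParseError(
            f"matrix is not square: {df.shape[0]} rows x {df.shape[1]} columns",
            path=str(path),
        )
    if list(df.index) != list(df.columns):
        raise ParseError("row labels do not match column labels", path=str(path))
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise ParseError("non-numeric entries in matrix CSV", path=str(path))
    return df


def write_edge_list_tsv(path: Path, labels, edge_probability: np.ndarray,
                        expected_partials: np.ndarray) -> None:
    labels = list(labels)
    rows = []
    d = len(labels)
    for i in range(d):
        for j in range(i + 1, d):
            rows.append({
                "source": labels[i],
                "target": labels[j],
                "probability": edge_probability[i, j],
                "expected_partial": expected_partials[i, j],
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_edge_list_tsv(path: Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"could not parse edge-list TSV: {exc}", path=str(path)) from exc
    required = {"source", "target", "probability", "expected_partial"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"edge list missing columns {sorted(required - set(df.columns))}",
            path=str(path),
        )
    return df


def write_json(path: Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: Path) -> dict:
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc.msg}", path=str(path), line=exc.lineno) from exc


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_cohort(cohort: Cohort, out_dir: Path) -> dict:
    """One TSV per subject plus a companion confound TSV and a JSON manifest
    (subject id, group, seed, file paths).  Returns the manifest dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort.subjects:
        series_path = out_dir / f"{rec.subject_id}_bold.tsv"
        conf_path = out_dir / f"{rec.subject_id}_confounds.tsv"
        write_timeseries_tsv(series_path, rec.series.values, rec.series.labels)
        write_timeseries_tsv(conf_path, rec.confounds.regressors, rec.confounds.names)
        entries.append({
            "subject_id": rec.subject_id,
            "group": rec.group,
            "seed": rec.seed,
            "series_path": series_path.name,
            "confounds_path": conf_path.name,
        })
    manifest = {
        "roi_labels": list(cohort.roi_set.labels),
        "homotopic_pairs": [list(p) for p in cohort.roi_set.homotopic_pairs],
        "spec": {
            "n_group_a": cohort.spec.n_group_a,
            "n_group_b": cohort.spec.n_group_b,
            "T": cohort.spec.T,
            "tr_seconds": cohort.spec.tr_seconds,
            "group_effect": cohort.spec.group_effect,
            "drift_amplitude": cohort.spec.drift_amplitude,
            "confound_coupling": cohort.spec.confound_coupling,
            "seed": cohort.spec.seed,
        },
        "subjects": entries,
    }
    write_json(out_dir / "cohort_manifest.json", manifest)
    return manifest


def read_cohort_manifest(cohort_dir: Path) -> dict:
    manifest = read_json(Path(cohort_dir) / "cohort_manifest.json")
    for key in ("roi_labels", "subjects"):
        if key not in manifest:
            raise ParseError(f"cohort manifest missing key {key!r}",
                             path=str(Path(cohort_dir) / "cohort_manifest.json"))
    return manifest


def load_subject(cohort_dir: Path, entry: dict,
                 roi_labels: list[str]) -> tuple[RoiTimeSeries, ConfoundSet]:
    cohort_dir = Path(cohort_dir)
    sdf = read_timeseries_tsv(cohort_dir / entry["series_path"],
                              expect_columns=len(roi_labels))
    cdf = read_timeseries_tsv(cohort_dir / entry["confounds_path"])
    series = RoiTimeSeries(values=sdf.to_numpy(), labels=tuple(sdf.columns),
                           subject_id=entry["subject_id"], group=entry["group"])
    confounds = ConfoundSet(regressors=cdf.to_numpy(), names=tuple(cdf.columns))
    return series, confounds
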