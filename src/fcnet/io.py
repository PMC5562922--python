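"""Plain-text serialization: subject TSVs, manifests, metric tables, configs.

One TSV per subject (rows = regions, first column a region label, remaining
columns timepoints), a cohort manifest TSV (subject_id / group / score), the
cohort spec echoed as YAML, and analysis outputs as TSV tables plus a JSON
report.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, SubjectRecord

__all__ = [
    "region_labels",
    "write_subject_tsv",
    "read_subject_tsv",
    "write_cohort",
    "read_cohort",
    "spec_to_yaml",
    "spec_from_yaml",
    "write_json_report",
]


def region_labels(n_regions: int) -> list[str]:
    return [f"R{i:03d}" for i in range(n_regions)]


def write_subject_tsv(record: SubjectRecord, path: Path) -> None:
    df = pd.DataFrame(record.timeseries, index=region_labels(record.n_regions))
    df.index.name = "region"
    df.columns = [f"t{j:03d}" for j in range(record.n_timepoints)]
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_subject_tsv(path: Path, subject_id: str, group: str,
                     behavior_score: float) -> SubjectRecord:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
        ts = df.to_numpy(dtype=float)
    except Exception as exc:
        raise ValueError(f"malformed subject file {path}: {exc}") from exc
    return SubjectRecord(subject_id=subject_id, group=group,
                         timeseries=ts, behavior_score=behavior_score)


def write_cohort(records: list[SubjectRecord], manifest: pd.DataFrame,
                 out_dir: Path, spec: CohortSpec | None = None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_subject_tsv(rec, out_dir / f"{rec.subject_id}.tsv")
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    if spec is not None:
        (out_dir / "cohort_spec.yaml").write_text(spec_to_yaml(spec))


def read_cohort(data_dir: Path, manifest_path: Path | None = None):
    """Load a cohort written by :func:`write_cohort` (or any conforming real
    data set).  Returns ``(records, manifest)``."""
    data_dir = Path(data_dir)
    if manifest_path is None:
        manifest_path = data_dir / "manifest.tsv"
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "group", "score"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    records = [
        read_subject_tsv(data_dir / f"{row.subject_id}.tsv",
                         str(row.subject_id), str(row.group), float(row.score))
        for row in manifest.itertuples()
    ]
    return records, manifest


def spec_to_yaml(spec: CohortSpec) -> str:
    d = dataclasses.asdict(spec)
    d["module_assignment"] = np.asarray(spec.module_assignment).tolist()
    d["behavior_mean_by_group"] = dict(spec.behavior_mean_by_group)
    d["behavior_sd_by_group"] = dict(spec.behavior_sd_by_group)
    return yaml.safe_dump(d, sort_keys=False)


def spec_from_yaml(text: str) -> CohortSpec:
    return CohortSpec(**yaml.safe_load(text))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json_report(report: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")
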