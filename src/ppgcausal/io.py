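"""Plain-text readers/writers for records, segments, feature tables, studies.

Raw records travel as CSV with a single comment header line carrying
the metadata (sampling rate, subject, optional cuff labels); cleaned
segments as a CSV waveform plus a JSON sidecar (onsets, SQI, labels);
feature tables as ordinary CSV with the registry names plus the label/
meta columns; a multi-source study as a small YAML file listing one
feature-table path per dataset.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInput
from .invariance import MultiSourceStudy
from .signals import CleanSegment, RawRecord

__all__ = [
    "write_record_csv",
    "read_record_csv",
    "write_segment",
    "read_segment",
    "write_feature_table",
    "read_feature_table",
    "read_study_yaml",
    "write_study_yaml",
]


def write_record_csv(record: RawRecord, path: str | Path) -> None:
    path = Path(path)
    meta = {"subject_id": record.subject_id, "fs": record.fs}
    if record.labels is not None:
        meta["sbp"], meta["dbp"] = record.labels
    header = "# " + " ".join(f"{k}={v}" for k, v in meta.items())
    cols = {"ppg": record.ppg}
    if record.abp is not None:
        cols["abp"] = record.abp
    with open(path, "w") as fh:
        fh.write(header + "\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_record_csv(path: str | Path) -> RawRecord:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise InvalidInput(f"{path}: missing metadata header line")
        meta = dict(kv.split("=", 1) for kv in first[1:].split())
        df = pd.read_csv(fh)
    labels = None
    if "sbp" in meta and "dbp" in meta:
        labels = (float(meta["sbp"]), float(meta["dbp"]))
    return RawRecord(
        subject_id=meta.get("subject_id", path.stem),
        ppg=df["ppg"].to_numpy(float),
        fs=float(meta["fs"]),
        abp=df["abp"].to_numpy(float) if "abp" in df.columns else None,
        labels=labels,
    )


def write_segment(segment: CleanSegment, prefix: str | Path) -> None:
    prefix = Path(prefix)
    pd.DataFrame({"ppg": segment.ppg}).to_csv(prefix.with_suffix(".csv"), index=False)
    sidecar = {
        "subject_id": segment.subject_id,
        "fs": segment.fs,
        "onsets": [int(o) for o in segment.onsets],
        "sqi_skew": segment.sqi_skew,
        "sqi_kurtosis": segment.sqi_kurtosis,
        "sbp": segment.sbp,
        "dbp": segment.dbp,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))


def read_segment(prefix: str | Path) -> CleanSegment:
    prefix = Path(prefix)
    ppg = pd.read_csv(prefix.with_suffix(".csv"))["ppg"].to_numpy(float)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return CleanSegment(
        ppg=ppg,
        onsets=np.asarray(meta["onsets"], dtype=int),
        sqi_skew=float(meta["sqi_skew"]),
        sqi_kurtosis=float(meta["sqi_kurtosis"]),
        sbp=float(meta["sbp"]),
        dbp=float(meta["dbp"]),
        subject_id=meta["subject_id"],
        fs=float(meta["fs"]),
    )


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_study_yaml(
    paths: dict[str, str | Path], target: str, path: str | Path
) -> None:
    payload = {"target": target, "datasets": {k: str(v) for k, v in paths.items()}}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_study_yaml(path: str | Path) -> MultiSourceStudy:
    cfg = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent
    tables = {}
    for ds, p in cfg["datasets"].items():
        p = Path(p)
        tables[ds] = read_feature_table(p if p.is_absolute() else base / p)
    return MultiSourceStudy(datasets=tables, target=cfg["target"])
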