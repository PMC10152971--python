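"""File formats: feature tables (CSV), models (JSON), traces (delimited text).

Conventions: ages in decimal years; thresholds in dB nHL; an ear with no
replicable response up to the device ceiling carries the explicit sentinel
``"absent"`` in the threshold column (it is a finding, never an empty cell);
decimal points are locale independent and column order is stable so repeated
runs are byte identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .features import AveragedTrace
from .reference import ReferenceIntervalResults

__all__ = [
    "ABSENT",
    "FEATURE_COLUMNS",
    "SubjectRecord",
    "SchemaError",
    "read_feature_csv",
    "write_feature_csv",
    "records_to_frame",
    "frame_to_records",
    "validate_feature_frame",
    "write_model_json",
    "read_model_json",
    "write_trace",
    "read_trace",
    "sha256_file",
]

#: Sentinel used in the threshold column for response-absent ears.
ABSENT = "absent"

FEATURE_COLUMNS = [
    "subject_id", "group", "age_years", "sex", "ear", "mode",
    "pn_uv", "emg_uv", "amplitude_ratio", "p_latency_ms", "n_latency_ms",
    "threshold_dbnhl", "position",
]

_REQUIRED = [c for c in FEATURE_COLUMNS if c != "position"]


class SchemaError(ValueError):
    """Feature-table header or cell did not match the schema."""


@dataclass
class SubjectRecord:
    """One subject x ear x mode row of the feature table."""

    subject_id: str
    group: str
    age_years: float
    sex: str
    ear: str
    mode: str
    pn_uv: float | None = None
    emg_uv: float | None = None
    amplitude_ratio: float | None = None
    p_latency_ms: float | None = None
    n_latency_ms: float | None = None
    threshold_dbnhl: float | None = None
    response_present: bool = True
    position: str | None = None


def _num(value, column: str, line: int) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"line {line}: cannot parse {column}={value!r} as a number") from None


def read_feature_csv(path) -> list[SubjectRecord]:
    """Read and validate a feature table; 'absent' thresholds become the
    absent sentinel (``threshold_dbnhl=None, response_present=False``)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        row = row._asdict()
        thr_raw = row["threshold_dbnhl"]
        absent = str(thr_raw).strip().lower() == ABSENT
        rec = SubjectRecord(
            subject_id=row["subject_id"], group=row["group"],
            age_years=_num(row["age_years"], "age_years", i),
            sex=row["sex"], ear=row["ear"], mode=row["mode"],
            pn_uv=_num(row["pn_uv"], "pn_uv", i),
            emg_uv=_num(row["emg_uv"], "emg_uv", i),
            amplitude_ratio=_num(row["amplitude_ratio"], "amplitude_ratio", i),
            p_latency_ms=_num(row["p_latency_ms"], "p_latency_ms", i),
            n_latency_ms=_num(row["n_latency_ms"], "n_latency_ms", i),
            threshold_dbnhl=None if absent else _num(thr_raw, "threshold_dbnhl", i),
            response_present=not absent,
            position=row.get("position") or None,
        )
        if rec.age_years is None:
            raise SchemaError(f"line {i}: age_years is required")
        records.append(rec)
    validate_feature_frame(records_to_frame(records))
    return records


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    if isinstance(value, float):
        return f"{value:.8g}"
    return str(value)


def write_feature_csv(records, path) -> None:
    """Write records (or a feature DataFrame) with stable formatting."""
    if isinstance(records, pd.DataFrame):
        records = frame_to_records(records)
    path = Path(path)
    lines = [",".join(FEATURE_COLUMNS)]
    for r in records:
        row = {f.name: getattr(r, f.name) for f in fields(r)}
        row["threshold_dbnhl"] = (
            ABSENT if not r.response_present else _fmt(r.threshold_dbnhl))
        lines.append(",".join(
            row[c] if c == "threshold_dbnhl" else _fmt(row[c])
            for c in FEATURE_COLUMNS))
    path.write_text("\n".join(lines) + "\n")


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(r)}
        rows.append(d)
    df = pd.DataFrame(rows)
    for c in ("age_years", "pn_uv", "emg_uv", "amplitude_ratio",
              "p_latency_ms", "n_latency_ms", "threshold_dbnhl"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c])
    return df


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    recs = []
    for row in df.to_dict("records"):
        def g(key, default=None):
            v = row.get(key, default)
            if isinstance(v, float) and np.isnan(v):
                return None
            return v
        recs.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=str(row.get("group", "")),
            age_years=float(row["age_years"]), sex=str(row["sex"]),
            ear=str(row["ear"]), mode=str(row["mode"]),
            pn_uv=g("pn_uv"), emg_uv=g("emg_uv"),
            amplitude_ratio=g("amplitude_ratio"),
            p_latency_ms=g("p_latency_ms"), n_latency_ms=g("n_latency_ms"),
            threshold_dbnhl=g("threshold_dbnhl"),
            response_present=bool(row.get("response_present",
                                          g("threshold_dbnhl") is not None)),
            position=g("position"),
        ))
    return recs


def validate_feature_frame(df: pd.DataFrame, tol: float = 1e-6) -> int:
    """Warn (once per bad row) when amplitude_ratio disagrees with pn/emg."""
    cols = ["pn_uv", "emg_uv", "amplitude_ratio"]
    sub = df.dropna(subset=cols)
    sub = sub[sub["emg_uv"] > 0]
    bad = np.abs(sub["amplitude_ratio"] - sub["pn_uv"] / sub["emg_uv"]) > tol
    n_bad = int(bad.sum())
    for idx in sub.index[bad]:
        warnings.warn(
            f"row {idx}: amplitude_ratio inconsistent with pn_uv/emg_uv",
            UserWarning, stacklevel=2)
    return n_bad


# ---------------------------------------------------------------------------
# Model JSON


def write_model_json(results: ReferenceIntervalResults, path) -> None:
    Path(path).write_text(json.dumps(results.to_dict(), indent=1, sort_keys=True) + "\n")


def read_model_json(path) -> ReferenceIntervalResults:
    return ReferenceIntervalResults.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Trace files: '#'-prefixed header lines, one sample (microvolts) per row


def write_trace(trace: AveragedTrace, path) -> None:
    path = Path(path)
    head = [
        f"# fs_hz {trace.sampling_rate_hz:g}",
        f"# level_dbnhl {trace.level_dbnhl:g}",
        f"# ear {trace.ear}",
        f"# mode {trace.mode}",
        f"# replicate {trace.replicate}",
        f"# n_epochs {trace.n_epochs}",
    ]
    if trace.emg_uv is not None:
        head.append(f"# emg_uv {trace.emg_uv:.6f}")
    body = "\n".join(f"{v:.4f}" for v in trace.samples)
    path.write_text("\n".join(head) + "\n" + body + "\n")


def read_trace(path) -> AveragedTrace:
    meta: dict[str, str] = {}
    samples = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition(" ")
            meta[key] = val.strip()
        elif line.strip():
            samples.append(float(line))
    try:
        return AveragedTrace(
            samples=np.asarray(samples),
            sampling_rate_hz=float(meta["fs_hz"]),
            ear=meta.get("ear", "R"), mode=meta.get("mode", "AC"),
            level_dbnhl=float(meta.get("level_dbnhl", "nan")),
            replicate=int(meta.get("replicate", 0)),
            n_epochs=int(meta.get("n_epochs", 1)),
            emg_uv=float(meta["emg_uv"]) if "emg_uv" in meta else None,
        )
    except KeyError as e:
        raise SchemaError(f"trace file {path} missing header line: {e}") from None


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
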