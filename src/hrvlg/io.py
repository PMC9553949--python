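"""Readers and writers for RR data, summaries, and configuration.

CSV dialect: comma-separated, UTF-8, header required, '.' decimal.  The RR
file is long-format with one row per value:

    subject_id,value[,pvc_ratio,pac_ratio,af_ratio]

``value`` is either an RR interval in milliseconds (``mode="intervals_ms"``)
or a pulse time in seconds (``mode="pulse_times_s"``).  Label columns, when
present, must be constant within a subject.

The plain-text beat export reader accepts the whitespace-delimited files
that Holter annotation tools produce (one beat time in seconds — or one RR
interval in milliseconds — per line, ``#`` comments allowed).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    DISORDERS,
    InvalidIntervalError,
    PulseTrain,
    RRSeries,
    SubjectRecord,
    pulses_to_intervals,
)
from .classify import DecisionZone
from .synthetic import CohortConfig

__all__ = [
    "SchemaError",
    "read_rr_csv",
    "write_rr_csv",
    "read_beat_export",
    "read_wfdb_rr",
    "summaries_to_frame",
    "load_config",
    "save_zones",
    "load_zones",
]

MODES = ("intervals_ms", "pulse_times_s")
_LABEL_COLUMNS = {"pvc_ratio": "PVC", "pac_ratio": "PAC", "af_ratio": "AF"}


class SchemaError(ValueError):
    """Raised when an input file does not match the documented schema."""


def _records_from_values(
    subject_id: str,
    values: np.ndarray,
    mode: str,
    ratios: dict[str, float],
    first_line: int,
) -> SubjectRecord:
    if mode == "pulse_times_s":
        rr = pulses_to_intervals(PulseTrain(times=values, subject_id=subject_id))
    else:
        bad = np.flatnonzero(values <= 0)
        if bad.size:
            raise InvalidIntervalError(
                f"invalid interval at line {first_line + int(bad[0])}: "
                f"{values[bad[0]]!r}"
            )
        rr = RRSeries(intervals=values, subject_id=subject_id)
    return SubjectRecord(rr=rr, disorder_ratios=ratios)


def read_rr_csv(path: str | Path, mode: str = "intervals_ms") -> list[SubjectRecord]:
    """Read a long-format RR CSV into subject records."""
    if mode not in MODES:
        raise ValueError(f"unsupported mode {mode!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"schema error: cannot parse {path}: {exc}") from exc
    for col in ("subject_id", "value"):
        if col not in df.columns:
            raise SchemaError(f"schema error: missing required column {col!r}")
    if not pd.api.types.is_numeric_dtype(df["value"]):
        bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna()][0]
        raise SchemaError(f"schema error: non-numeric value at line {bad + 2}")
    records = []
    # +2: header line plus 1-based numbering
    for subject_id, grp in df.groupby("subject_id", sort=False):
        ratios: dict[str, float] = {}
        for col, disorder in _LABEL_COLUMNS.items():
            if col in df.columns:
                vals = grp[col].dropna().unique()
                if len(vals) > 1:
                    raise SchemaError(
                        f"schema error: {col} not constant for subject {subject_id!r}"
                    )
                if len(vals) == 1:
                    r = float(vals[0])
                    if not 0 <= r <= 1:
                        raise SchemaError(
                            f"schema error: {col}={r} outside [0, 1] "
                            f"for subject {subject_id!r}"
                        )
                    ratios[disorder] = r
        records.append(
            _records_from_values(
                str(subject_id),
                grp["value"].to_numpy(dtype=float),
                mode,
                ratios,
                first_line=int(grp.index[0]) + 2,
            )
        )
    return records


def write_rr_csv(
    records: list[SubjectRecord], path: str | Path, mode: str = "intervals_ms"
) -> None:
    """Write subject records in the long CSV format (lossless at 12 sig. digits)."""
    if mode not in MODES:
        raise ValueError(f"unsupported mode {mode!r}")
    frames = []
    for rec in records:
        if mode == "intervals_ms":
            values = rec.rr.intervals
        else:
            from .core import intervals_to_pulses

            values = intervals_to_pulses(rec.rr).times
        df = pd.DataFrame({"subject_id": rec.subject_id, "value": values})
        for col, disorder in _LABEL_COLUMNS.items():
            if disorder in rec.disorder_ratios:
                df[col] = rec.disorder_ratios[disorder]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_beat_export(
    path: str | Path, mode: str = "pulse_times_s", subject_id: str | None = None
) -> SubjectRecord:
    """Read a plain-text beat-time (or RR) export: one value per line.

    Lines may carry extra leading columns (e.g. a sample index); the last
    whitespace-delimited field is taken.  ``#`` starts a comment.
    """
    if mode not in MODES:
        raise ValueError(f"unsupported mode {mode!r}")
    path = Path(path)
    values = []
    first_data_line = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                values.append(float(line.split()[-1]))
            except ValueError as exc:
                raise SchemaError(
                    f"schema error: non-numeric value at line {lineno}"
                ) from exc
            if first_data_line is None:
                first_data_line = lineno
    if len(values) < 2:
        raise SchemaError("schema error: export holds fewer than 2 values")
    return _records_from_values(
        subject_id or path.stem,
        np.asarray(values, dtype=float),
        mode,
        {},
        first_line=first_data_line or 1,
    )


# adapter name kept for users coming from WFDB-style annotation exports
read_wfdb_rr = read_beat_export


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in summaries],
            "duration_mode": [s.duration_mode for s in summaries],
            "hr": [s.hr for s in summaries],
            "log10_cv": [s.log10_cv for s in summaries],
            "log10_lv": [s.log10_lv for s in summaries],
            "log10_lg": [s.log10_lg for s in summaries],
            "n_windows": [s.n_windows for s in summaries],
        }
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML (or key: value) configuration file."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("schema error: config must be a mapping")
    return cfg


def cohort_config_from_dict(d: dict) -> CohortConfig:
    known = {f for f in CohortConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise SchemaError(f"schema error: unknown cohort config keys {sorted(unknown)}")
    if "mean_interval_range" in d:
        d = {**d, "mean_interval_range": tuple(d["mean_interval_range"])}
    return CohortConfig(**d)


def save_zones(zones: list[DecisionZone], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"zones": [z.to_dict() for z in zones]}, fh)


def load_zones(path: str | Path) -> list[DecisionZone]:
    cfg = load_config(path)
    if "zones" not in cfg:
        raise SchemaError("schema error: missing 'zones' key")
    zones = [DecisionZone.from_dict(z) for z in cfg["zones"]]
    for z in zones:
        if z.disorder not in DISORDERS:
            raise SchemaError(f"schema error: unknown disorder {z.disorder!r}")
    return zones
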