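"""Reading and writing the pipeline's CSV formats.

Three plain-text formats are used, all comma-separated UTF-8 with one header
row:

* signal CSV — leading ``# key=value`` comment lines carrying metadata
  (``fs``, ``participant``, ``cohort``, ``state``, ``phase``, ``axis``,
  ``t0``) followed by a single ``angular_velocity_dps`` column;
* event CSV — same comment-line metadata, then ``start_s,end_s,label``;
* cohort CSV — ``participant_id,cohort,state,age_years,rt_s,av_dps,
  brad_score,updrs3_total,hy_stage`` with missing values as empty fields.
"""

from __future__ import annotations

import csv
import io as _io
import math
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .types import EventLog, GyroRecording, ParticipantSummary

PathLike = Union[str, Path]

COHORT_COLUMNS = [
    "participant_id", "cohort", "state", "age_years",
    "rt_s", "av_dps", "brad_score", "updrs3_total", "hy_stage",
]


def _read_metadata(path: Path) -> Tuple[Dict[str, str], List[str], int]:
    """Split a file into '# key=value' metadata and remaining lines.

    Returns (metadata, data_lines, first_data_lineno) where lineno is 1-based.
    """
    meta: Dict[str, str] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if not body:
            continue
        if "=" not in body:
            raise FormatError(f"{path}:{i + 1}: malformed metadata line {line!r}")
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()
    else:  # file was all comments
        i = len(lines)
    return meta, lines[i:], i + 1


def read_gyro_csv(path: PathLike) -> GyroRecording:
    """Read a signal CSV into a validated :class:`GyroRecording`."""
    path = Path(path)
    meta, data_lines, lineno = _read_metadata(path)
    if "fs" not in meta:
        raise FormatError(f"{path}: missing required '# fs=' metadata line")
    try:
        fs = float(meta["fs"])
    except ValueError:
        raise FormatError(f"{path}: non-numeric fs {meta['fs']!r}") from None
    if fs <= 0:
        raise FormatError(f"{path}: fs must be > 0, got {fs}")
    if not data_lines or data_lines[0].strip() != "angular_velocity_dps":
        raise FormatError(
            f"{path}:{lineno}: expected header 'angular_velocity_dps'"
        )
    samples = np.empty(len(data_lines) - 1, dtype=float)
    for k, line in enumerate(data_lines[1:]):
        try:
            samples[k] = float(line)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno + 1 + k}: non-numeric sample {line!r}"
            ) from None
    try:
        return GyroRecording(
            participant_id=meta.get("participant", "unknown"),
            cohort=meta.get("cohort", "EG"),
            state=meta.get("state", "NA"),
            phase=int(meta.get("phase", 4)),
            fs=fs,
            samples=samples,
            axis=meta.get("axis", "Y"),
            t0=float(meta.get("t0", 0.0)),
        )
    except Exception as exc:
        raise FormatError(f"{path}: invalid recording: {exc}") from exc


def write_gyro_csv(recording: GyroRecording, path: PathLike) -> None:
    """Write a :class:`GyroRecording` in the self-describing signal format."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# fs={recording.fs!r}\n")
        fh.write(f"# participant={recording.participant_id}\n")
        fh.write(f"# cohort={recording.cohort}\n")
        fh.write(f"# state={recording.state}\n")
        fh.write(f"# phase={recording.phase}\n")
        fh.write(f"# axis={recording.axis}\n")
        fh.write(f"# t0={recording.t0!r}\n")
        fh.write("angular_velocity_dps\n")
        for x in recording.samples:
            fh.write(f"{float(x)!r}\n")


def read_event_csv(path: PathLike) -> EventLog:
    """Read an event CSV into a validated, start-sorted :class:`EventLog`."""
    path = Path(path)
    meta, data_lines, lineno = _read_metadata(path)
    if not data_lines:
        raise FormatError(f"{path}: missing header row")
    reader = csv.reader(data_lines)
    header = next(reader)
    header = [h.strip() for h in header]
    if header[:2] != ["start_s", "end_s"]:
        raise FormatError(f"{path}:{lineno}: expected columns 'start_s,end_s'")
    intervals: List[Tuple[float, float]] = []
    for k, row in enumerate(reader):
        if not row:
            continue
        try:
            a, b = float(row[0]), float(row[1])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: row {k + 1}: non-numeric interval {row!r}") from None
        if not b > a:
            raise FormatError(f"{path}: row {k + 1}: end {b} must exceed start {a}")
        intervals.append((a, b))
    ordered = sorted(intervals)
    for k in range(1, len(ordered)):
        if ordered[k][0] < ordered[k - 1][1]:
            raise FormatError(f"{path}: row {k + 1}: overlapping intervals")
    try:
        return EventLog(
            participant_id=meta.get("participant", "unknown"),
            cohort=meta.get("cohort", "EG"),
            state=meta.get("state", "NA"),
            phase=int(meta.get("phase", 4)),
            intervals=tuple(ordered),
        )
    except Exception as exc:
        raise FormatError(f"{path}: invalid event log: {exc}") from exc


def write_event_csv(log: EventLog, path: PathLike) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# participant={log.participant_id}\n")
        fh.write(f"# cohort={log.cohort}\n")
        fh.write(f"# state={log.state}\n")
        fh.write(f"# phase={log.phase}\n")
        fh.write("start_s,end_s,label\n")
        for k, (a, b) in enumerate(log.intervals):
            fh.write(f"{a!r},{b!r},event{k + 1}\n")


def _opt(value, cast):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return cast(value)


def read_cohort_csv(path: PathLike) -> pd.DataFrame:
    """Read a cohort CSV into a DataFrame of validated summary rows."""
    # "NA" is a meaningful state label, so only empty fields mean missing
    df = pd.read_csv(path, dtype={"participant_id": str},
                     keep_default_na=False, na_values=[""],
                     float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    rows = [
        ParticipantSummary(
            participant_id=str(r.participant_id),
            cohort=str(r.cohort),
            state=str(r.state),
            age_years=_opt(r.age_years, int),
            rt_s=_opt(r.rt_s, float),
            av_dps=_opt(r.av_dps, float),
            brad_score=_opt(r.brad_score, int),
            updrs3_total=_opt(r.updrs3_total, int),
            hy_stage=_opt(r.hy_stage, int),
        )
        for r in df.itertuples(index=False)
    ]
    return summaries_to_frame(rows)


def summaries_to_frame(rows) -> pd.DataFrame:
    """Tabulate :class:`ParticipantSummary` rows (missing -> NaN/NA)."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "cohort": r.cohort,
                "state": r.state,
                "age_years": r.age_years,
                "rt_s": r.rt_s,
                "av_dps": r.av_dps,
                "brad_score": r.brad_score,
                "updrs3_total": r.updrs3_total,
                "hy_stage": r.hy_stage,
            }
            for r in rows
        ],
        columns=COHORT_COLUMNS,
    )


def write_cohort_csv(frame: pd.DataFrame, path: PathLike) -> None:
    # %.17g round-trips float64 exactly, so table-only reruns are bit-faithful
    frame.to_csv(path, index=False, columns=COHORT_COLUMNS,
                 float_format="%.17g")
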