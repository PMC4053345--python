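"""Reading and writing tap logs and run configurations.

Tap logs are stored in long-format CSV — one row per tap, columns
``subject_id,video_id,rr_ref,tap_time_s`` — or in an equivalent JSON layout
(one object per log with a ``tap_times`` array).  Times are serialized at
millisecond precision; round-trips are exact on logs already at that
precision.  Every output file carries a config snapshot: a leading ``#``
comment line in CSV, a ``config`` key in JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .core import TapLog

__all__ = ["read_tap_logs", "write_tap_logs"]

logger = logging.getLogger(__name__)

_CSV_COLUMNS = ["subject_id", "video_id", "rr_ref", "tap_time_s"]


def write_tap_logs(
    logs: Sequence[TapLog], path: str | Path, config: Optional[dict] = None
) -> None:
    """Write tap logs to CSV (default) or JSON, chosen by file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "config": config or {},
            "logs": [
                {
                    "subject_id": log.subject_id,
                    "video_id": log.video_id,
                    "rr_ref": log.rr_ref,
                    "tap_times": [round(t, 3) for t in log.tap_times],
                }
                for log in logs
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    with path.open("w") as fh:
        fh.write(f"# config: {json.dumps(config or {})}\n")
        fh.write(",".join(_CSV_COLUMNS) + "\n")
        for log in logs:
            for t in log.tap_times:
                fh.write(f"{log.subject_id},{log.video_id},{log.rr_ref:g},{t:.3f}\n")


def _build_log(subject_id: str, video_id: str, rr_ref: float, times: list[float]) -> TapLog:
    ordered = sorted(times)
    if ordered != times:
        logger.warning(
            "tap times out of order in log %s/%s; reordered by timestamp",
            subject_id,
            video_id,
        )
    for a, b in zip(ordered, ordered[1:]):
        if b == a:
            raise ValueError(
                f"duplicate tap timestamp {a} in log {subject_id}/{video_id}"
            )
    return TapLog(subject_id, video_id, tuple(ordered), rr_ref)


def read_tap_logs(path: str | Path) -> list[TapLog]:
    """Read tap logs from CSV or JSON; see the module docstring for formats.

    Rows within a log are sorted by time (with a warning if reordering was
    needed); duplicate timestamps raise a validation error naming the log.
    An empty file yields an empty collection with a warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        records = payload["logs"] if isinstance(payload, dict) else payload
        return [
            _build_log(
                str(rec["subject_id"]),
                str(rec["video_id"]),
                float(rec["rr_ref"]),
                [float(t) for t in rec["tap_times"]],
            )
            for rec in records
        ]
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("empty tap-log file %s", path)
        return []
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        logger.warning("tap-log file %s has no rows", path)
        return []
    logs = []
    for (sid, vid), group in df.groupby(["subject_id", "video_id"], sort=False):
        rr_ref = float(group["rr_ref"].iloc[0])
        logs.append(_build_log(str(sid), str(vid), rr_ref, group["tap_time_s"].astype(float).tolist()))
    return logs
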