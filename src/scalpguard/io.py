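"""Event-log serialization: JSONL (canonical) and CSV (convenience).

A log file starts with a header carrying the seed, a config hash and the
event count; timestamps are written ISO-8601 with an explicit UTC offset
and read back losslessly at millisecond resolution.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .simulate import EVENT_COLUMNS

_REQUIRED = ["event_id", "account_id", "timestamp", "action"]


def config_hash(config) -> str:
    return hashlib.sha1(repr(config).encode()).hexdigest()[:12]


def _serialize_frame(events: pd.DataFrame) -> pd.DataFrame:
    out = events[EVENT_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    return out


def write_event_log(events: pd.DataFrame, path, seed=None, config=None) -> None:
    path = Path(path)
    meta = {"format": "scalpguard-event-log", "n_events": int(len(events)),
            "seed": seed, "config_hash": config_hash(config) if config is not None else None}
    ser = _serialize_frame(events)
    if path.suffix == ".csv":
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            ser.to_csv(fh, index=False)
    else:  # JSONL canonical
        with open(path, "w") as fh:
            fh.write(json.dumps({"_meta": meta}) + "\n")
            for rec in ser.to_dict(orient="records"):
                rec["ref_event_id"] = (None if pd.isna(rec["ref_event_id"])
                                       else int(rec["ref_event_id"]))
                fh.write(json.dumps(rec) + "\n")


def _postprocess(df: pd.DataFrame) -> pd.DataFrame:
    for lineno, row in enumerate(df[_REQUIRED].itertuples(index=False), start=1):
        for col, val in zip(_REQUIRED, row):
            if pd.isna(val) or val == "":
                raise SchemaError(f"row {lineno}: missing {col}")
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    df["event_id"] = df["event_id"].astype("int64")
    df["ref_event_id"] = pd.array(
        [None if (v is None or v == "" or pd.isna(v)) else int(float(v))
         for v in df["ref_event_id"]], dtype="Int64")
    df["op_duration_s"] = df["op_duration_s"].astype(float)
    return df[EVENT_COLUMNS]


def read_event_log(path) -> tuple[pd.DataFrame, dict]:
    """Read a log; returns (events, header metadata)."""
    path = Path(path)
    if path.suffix == ".csv":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for line in lines:
            if not line.startswith("#"):
                break
            body_start += 1
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
        if body_start >= len(lines):
            return pd.DataFrame(columns=EVENT_COLUMNS), meta
        from io import StringIO
        df = pd.read_csv(StringIO("".join(lines[body_start:])), dtype={"ref_event_id": "object"})
        if len(df) == 0:
            return pd.DataFrame(columns=EVENT_COLUMNS), meta
        return _postprocess(df), meta
    meta = {}
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise SchemaError(f"line {lineno}: invalid JSON ({e})") from e
            if "_meta" in obj:
                meta = obj["_meta"]
                continue
            for col in _REQUIRED:
                if obj.get(col) in (None, ""):
                    raise SchemaError(f"line {lineno}: missing {col}")
            records.append(obj)
    if not records:
        return pd.DataFrame(columns=EVENT_COLUMNS), meta
    df = pd.DataFrame.from_records(records)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    return _postprocess(df), meta
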