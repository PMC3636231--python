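"""Headered-CSV I/O with ISO-8601 dates.

Internally all dates are integer day offsets from the study epoch
(``EPOCH``); calendar rendering happens only here.
"""

from __future__ import annotations

import json
from datetime import date, timedelta
from pathlib import Path

import pandas as pd

from .errors import ValidationError

EPOCH = date(2008, 2, 1)

MEMBER_COLUMNS = ["member_id", "age", "sex", "height_in", "weight_lb",
                  "reg_date", "reg_source", "region"]
WEIGHT_COLUMNS = ["entry_id", "member_id", "date", "weight_lb"]
LOGIN_COLUMNS = ["member_id", "date"]
USAGE_COLUMNS = ["member_id", "food_entry_days", "exercise_entry_days",
                 "exercise_minutes", "sparkpoints", "forum_posts", "friends"]


def day_to_iso(day):
    return (EPOCH + timedelta(days=int(day))).isoformat()


def iso_to_day(iso):
    return (date.fromisoformat(str(iso)) - EPOCH).days


def _require_columns(frame: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def write_members(members: pd.DataFrame, path) -> None:
    out = members.copy()
    out["reg_date"] = out["reg_date"].map(day_to_iso)
    out[MEMBER_COLUMNS].to_csv(path, index=False)


def read_members(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, MEMBER_COLUMNS, path)
    frame["reg_date"] = frame["reg_date"].map(iso_to_day)
    return frame


def write_weights(weights: pd.DataFrame, path) -> None:
    out = weights.copy()
    out["date"] = out["day"].map(day_to_iso)
    out[WEIGHT_COLUMNS].to_csv(path, index=False)


def read_weights(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, ["member_id", "date", "weight_lb"], path)
    frame["day"] = frame["date"].map(iso_to_day)
    if "entry_id" not in frame.columns:
        frame["entry_id"] = [f"E{i:07d}" for i in range(1, len(frame) + 1)]
    if (frame["weight_lb"] <= 0).any():
        raise ValidationError(f"{path}: weights must be positive")
    if frame.duplicated(["member_id", "entry_id"]).any():
        raise ValidationError(f"{path}: duplicate (member_id, entry_id)")
    return frame.drop(columns=["date"])


def write_logins(logins: pd.DataFrame, path) -> None:
    out = logins.copy()
    out["date"] = out["day"].map(day_to_iso)
    out[LOGIN_COLUMNS].to_csv(path, index=False)


def read_logins(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, LOGIN_COLUMNS, path)
    frame["day"] = frame["date"].map(iso_to_day)
    return frame.drop(columns=["date"])


def write_usage(usage: pd.DataFrame, path) -> None:
    usage[USAGE_COLUMNS].to_csv(path, index=False)


def read_usage(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, USAGE_COLUMNS, path)
    return frame


def write_ground_truth(entry_truth: pd.DataFrame, path) -> None:
    out = entry_truth.copy()
    if len(out):
        out["date"] = out["day"].map(day_to_iso)
        out = out.drop(columns=["day"])
    out.to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "date" in frame.columns:
        frame["day"] = frame["date"].map(iso_to_day)
        frame = frame.drop(columns=["date"])
    return frame


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_json_default)
                          + "\n")


def _json_default(obj):
    try:
        import numpy as np
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
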