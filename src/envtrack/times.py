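"""Timestamp handling: everything internal is UTC epoch seconds (float)."""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The timestamp format used in annotation requests and track files.
TIME_FORMAT = "%Y-%m-%d %H:%M:%S"


def parse_timestamp(value) -> float:
    """Coerce a timestamp (string, datetime, pandas/numpy time, or number)
    to UTC epoch seconds.

    Strings must follow ``yyyy-MM-dd HH:mm:ss`` (an ISO-8601 ``T`` separator
    is tolerated); naive times are taken as UTC.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, np.datetime64):
        return float(pd.Timestamp(value).value) / 1e9
    if isinstance(value, datetime):
        if value.tzinfo is None:
            value = value.replace(tzinfo=timezone.utc)
        return value.timestamp()
    if isinstance(value, pd.Timestamp):
        if value.tz is None:
            value = value.tz_localize("UTC")
        return value.timestamp()
    if isinstance(value, str):
        text = value.strip().replace("T", " ")
        try:
            dt = datetime.strptime(text, TIME_FORMAT)
        except ValueError as exc:
            raise ValidationError(f"unparseable timestamp {value!r}: {exc}") from exc
        return dt.replace(tzinfo=timezone.utc).timestamp()
    raise ValidationError(f"unsupported timestamp type {type(value).__name__}")


def format_timestamp(epoch_s: float) -> str:
    """Render epoch seconds as ``yyyy-MM-dd HH:mm:ss`` UTC."""
    return datetime.fromtimestamp(float(epoch_s), tz=timezone.utc).strftime(TIME_FORMAT)
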