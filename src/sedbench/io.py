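"""CSV interchange: validated readers and writers for the flat tables.

Monitoring programs distribute flat tables; the package reads sample-event
CSVs (one row per visit), pebble-count CSVs (one row per transect x size
class), taxa-occurrence CSVs and score-table CSVs, and writes benchmark
sets as JSON with full provenance. Event validation reports every bad row
with its row number rather than failing on the first.
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd

from .config import ORDERS, SITE_CLASSES

logger = logging.getLogger(__name__)

REQUIRED_EVENT_COLUMNS = ("event_id", "site_class", "order", "bankfull_width_m")
OPTIONAL_EVENT_COLUMNS = ("sf", "fsbi", "smi2", "oe", "weight", "disturbance", "comid")

_CLASS_ALIASES = {
    "mountains": "mountains",
    "mountain": "mountains",
    "foothills": "foothills",
    "foothill": "foothills",
    "ppbv": "ppbv",
    "plains, plateaus, and broad valleys": "ppbv",
}


class EventValidationError(ValueError):
    """Carries the full list of per-row validation messages."""

    def __init__(self, messages: list[str]):
        self.messages = messages
        super().__init__(
            f"{len(messages)} invalid event row(s):\n" + "\n".join(messages)
        )


def read_events(path) -> pd.DataFrame:
    """Read and validate a sample-event CSV.

    Required columns: ``event_id, site_class, order, bankfull_width_m``;
    optional: ``sf, fsbi, smi2, oe, weight, disturbance, comid``. Site
    classes are normalized to {mountains, foothills, ppbv}; order must be
    an integer 1-4 and bankfull width positive. All offending rows are
    reported together (row numbers are 1-based data rows).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventValidationError([f"missing required columns: {missing}"])

    messages: list[str] = []
    classes = []
    for i, raw in enumerate(df["site_class"], start=1):
        key = " ".join(str(raw).split()).casefold()
        if key in _CLASS_ALIASES:
            classes.append(_CLASS_ALIASES[key])
        else:
            classes.append(None)
            messages.append(
                f"row {i}: unknown site class {raw!r} "
                f"(expected one of {list(SITE_CLASSES)})"
            )
    orders = pd.to_numeric(df["order"], errors="coerce")
    for i, (raw, val) in enumerate(zip(df["order"], orders), start=1):
        if pd.isna(val) or float(val) != int(val) or int(val) not in ORDERS:
            messages.append(
                f"row {i}: order {raw!r} outside supported range 1-4"
            )
    bw = pd.to_numeric(df["bankfull_width_m"], errors="coerce")
    for i, (raw, val) in enumerate(zip(df["bankfull_width_m"], bw), start=1):
        if pd.isna(val) or val <= 0:
            messages.append(f"row {i}: bankfull_width_m {raw!r} must be positive")
    if "weight" in df.columns:
        w = pd.to_numeric(df["weight"], errors="coerce")
        for i, (raw, val) in enumerate(zip(df["weight"], w), start=1):
            if pd.isna(val) or val <= 0:
                messages.append(f"row {i}: weight {raw!r} must be positive")
    if messages:
        raise EventValidationError(messages)

    out = df.copy()
    out["site_class"] = classes
    out["order"] = orders.astype(int)
    out["bankfull_width_m"] = bw.astype(float)
    for col in ("sf", "fsbi", "smi2", "oe", "weight"):
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def write_events(events: pd.DataFrame, path) -> None:
    cols = [c for c in (*REQUIRED_EVENT_COLUMNS, *OPTIONAL_EVENT_COLUMNS)
            if c in events.columns]
    events[cols].to_csv(path, index=False)


def read_pebbles(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"event_id", "transect_id", "size_class", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pebble CSV missing columns: {sorted(missing)}")
    df["count"] = pd.to_numeric(df["count"], errors="raise").astype(int)
    return df


def read_taxa(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"event_id", "taxon"} - set(df.columns)
    if missing:
        raise ValueError(f"taxa CSV missing columns: {sorted(missing)}")
    return df


def dataset_hash(df: pd.DataFrame) -> str:
    """Stable sha256 of a table's canonical CSV form (for provenance)."""
    blob = df.to_csv(index=False).encode()
    return hashlib.sha256(blob).hexdigest()
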