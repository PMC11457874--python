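"""Percent surface fines (SF) from Wolman pebble-count records.

A sample event carries three bankfull transects of particle counts binned
into 11 ordered size classes. All particles across the three transects are
pooled before the fines fraction is taken: SF = 100 x (particles strictly
below 2.5 mm) / (total particles). The 2.5 mm class boundary itself is not
fines (classes are half-open [lower, upper)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_SIZE_CLASS_EDGES, FINES_CUTOFF_MM, size_class_labels

PEBBLE_COLUMNS = ("event_id", "transect_id", "size_class", "count")


@dataclass(frozen=True)
class SubstrateSummary:
    """Pooled substrate summary for one sample event."""

    event_id: str
    sf_percent: float
    total_particles: int


def bin_particle(
    diameter_mm: float,
    edges: tuple[float, ...] = DEFAULT_SIZE_CLASS_EDGES,
) -> str:
    """Assign a measured intermediate-axis diameter to its size class.

    Classes are half-open ``[lower, upper)``, so a particle measured exactly
    at 2.5 mm falls in the 2.5–6 mm class and does not count as fines.
    """
    if not diameter_mm > 0:
        raise ValueError(f"particle diameter must be positive, got {diameter_mm}")
    labels = size_class_labels(edges)
    # np.searchsorted with side='right' gives the half-open [lower, upper) bin
    idx = int(np.searchsorted(np.asarray(edges[1:-1]), diameter_mm, side="right"))
    return labels[idx]


def fines_labels(edges: tuple[float, ...] = DEFAULT_SIZE_CLASS_EDGES) -> tuple[str, ...]:
    """Labels of the size classes lying entirely below the fines cutoff."""
    labels = size_class_labels(edges)
    return tuple(
        lab for lab, hi in zip(labels, edges[1:]) if hi <= FINES_CUTOFF_MM
    )


def compute_sf(
    pebbles: pd.DataFrame,
    edges: tuple[float, ...] = DEFAULT_SIZE_CLASS_EDGES,
) -> pd.DataFrame:
    """Compute percent surface fines per event from pebble-count records.

    Parameters
    ----------
    pebbles
        Long table with columns ``event_id, transect_id, size_class, count``;
        one row per (transect, size class). Transects are pooled within each
        event before the fines fraction is taken.
    edges
        Size-class boundaries in mm (12 ascending edges defining 11 classes).

    Returns
    -------
    DataFrame with columns ``event_id, sf_percent, total_particles``, one row
    per event, sorted by event_id.
    """
    missing = [c for c in PEBBLE_COLUMNS if c not in pebbles.columns]
    if missing:
        raise ValueError(f"pebble table missing columns: {missing}")
    labels = set(size_class_labels(edges))
    unknown = set(pebbles["size_class"].unique()) - labels
    if unknown:
        raise ValueError(f"unknown size-class labels: {sorted(unknown)}")
    counts = pebbles["count"].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative particle counts")

    fines = set(fines_labels(edges))
    df = pebbles.assign(
        is_fines=pebbles["size_class"].isin(fines),
    )
    grouped = df.groupby("event_id", sort=True).apply(
        lambda g: pd.Series(
            {
                "total_particles": int(g["count"].sum()),
                "fines_count": int(g.loc[g["is_fines"], "count"].sum()),
            }
        ),
        include_groups=False,
    )
    zero = grouped.index[grouped["total_particles"] == 0].tolist()
    if zero:
        raise ValueError(f"events with zero pooled particles: {zero}")
    grouped["sf_percent"] = 100.0 * grouped["fines_count"] / grouped["total_particles"]
    out = grouped.reset_index()[["event_id", "sf_percent", "total_particles"]]
    out["total_particles"] = out["total_particles"].astype(int)
    return out


def summarize_event(pebbles: pd.DataFrame, event_id: str, edges=DEFAULT_SIZE_CLASS_EDGES) -> SubstrateSummary:
    """Pooled :class:`SubstrateSummary` for a single event."""
    sub = pebbles[pebbles["event_id"] == event_id]
    if sub.empty:
        raise ValueError(f"no pebble records for event {event_id!r}")
    row = compute_sf(sub, edges).iloc[0]
    return SubstrateSummary(
        event_id=event_id,
        sf_percent=float(row["sf_percent"]),
        total_particles=int(row["total_particles"]),
    )
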