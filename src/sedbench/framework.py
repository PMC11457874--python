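"""Evidence rating for a sediment-induced community composition change.

Each sample event with paired surface-fines and FSBI data is rated by the
joint status of its two reference benchmarks: "unlikely" when both are
achieved, "mixed_evidence" when exactly one is achieved, and "likely" when
neither is. Equality with a benchmark counts as achieved; the rating
depends only on benchmark status, never on the magnitude of exceedance.
Events missing either line of evidence receive no rating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import BenchmarkSet

logger = logging.getLogger(__name__)

RATINGS = ("unlikely", "mixed_evidence", "likely")


def classify_event(sf_achieved: bool, fsbi_achieved: bool) -> str:
    """Three-level rating from the two benchmark-achievement flags."""
    if sf_achieved and fsbi_achieved:
        return "unlikely"
    if sf_achieved or fsbi_achieved:
        return "mixed_evidence"
    return "likely"


@dataclass
class FrameworkAssessment:
    """Per-event ratings plus summary counts and the exclusion report."""

    ratings: pd.DataFrame
    summary: dict
    exclusions: dict = field(default_factory=dict)  # reason -> count


def assess_dataset(
    events: pd.DataFrame,
    benchmark_set: BenchmarkSet,
) -> FrameworkAssessment:
    """Rate every assessable event against its reference benchmarks.

    An event is assessable when it carries SF, FSBI, site class, order and
    bankfull width, and both its order's SF quantile model and its class
    FSBI_ref are available. Unassessable events are excluded and tallied by
    reason; the summary reports counts and shares per rating.
    """
    required = {"event_id", "site_class", "order", "bankfull_width_m", "sf", "fsbi"}
    missing = required - set(events.columns)
    if missing:
        raise KeyError(f"events missing columns: {sorted(missing)}")

    rows = []
    exclusions: dict[str, int] = {}

    def exclude(reason: str) -> None:
        exclusions[reason] = exclusions.get(reason, 0) + 1

    for _, ev in events.iterrows():
        if not np.isfinite(ev["sf"]) or not np.isfinite(ev["fsbi"]):
            exclude("missing indicator value")
            continue
        if not np.isfinite(ev["bankfull_width_m"]) or ev["bankfull_width_m"] <= 0:
            exclude("missing bankfull width")
            continue
        try:
            sf_ref = benchmark_set.sf_ref_for(ev["order"], ev["bankfull_width_m"])
        except KeyError:
            exclude(f"no SF quantile model for order {int(ev['order'])}")
            continue
        fsbi_ref = benchmark_set.fsbi_ref.get(ev["site_class"])
        if fsbi_ref is None:
            exclude(f"no FSBI_ref for class {ev['site_class']!r}")
            continue
        sf_achieved = bool(ev["sf"] <= sf_ref)
        fsbi_achieved = bool(ev["fsbi"] >= fsbi_ref)
        rows.append({
            "event_id": ev["event_id"],
            "rating": classify_event(sf_achieved, fsbi_achieved),
            "sf_achieved": sf_achieved,
            "fsbi_achieved": fsbi_achieved,
            "sf_ref_used": float(sf_ref),
            "fsbi_ref_used": float(fsbi_ref),
        })

    ratings = pd.DataFrame(
        rows,
        columns=["event_id", "rating", "sf_achieved", "fsbi_achieved",
                 "sf_ref_used", "fsbi_ref_used"],
    )
    if ratings.empty and not events.empty:
        raise ValueError("no events with paired data could be assessed")
    n = len(ratings)
    counts = {r: int((ratings["rating"] == r).sum()) for r in RATINGS}
    summary = {
        "n_assessed": n,
        "n_excluded": int(sum(exclusions.values())),
        "counts": counts,
        "shares": {r: (counts[r] / n if n else float("nan")) for r in RATINGS},
    }
    if exclusions:
        logger.info("excluded events: %s", exclusions)
    return FrameworkAssessment(ratings=ratings, summary=summary, exclusions=exclusions)
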