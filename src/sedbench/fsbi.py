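"""Fine Sediment Biotic Index (FSBI) scoring.

FSBI is an occurrence-only biotic index: each taxon carries a sediment
sensitivity score and a sample's FSBI is the sum of scores over taxa
present. High FSBI means many sediment-sensitive taxa are present; scores
generally range 0-350. Tolerance values can also be derived from paired
data as the SF associated with a taxon's 75th-percentile occurrence.

The authoritative published score table (206 Pacific-Northwest taxa) is
external literature; the packaged table (``data/demo_fsbi_scores.csv``) is
a small synthetic demonstration table for tests and examples. Production
use should supply the published table as a CSV with columns taxon, score.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Upper end of the plausibility band for FSBI scores; values above it are
#: flagged with a warning but not rejected.
FSBI_PLAUSIBLE_MAX = 350.0


def normalize_taxon(name: str) -> str:
    """Canonical taxon key: whitespace-collapsed, case-folded."""
    return " ".join(str(name).split()).casefold()


def load_score_table(source) -> dict[str, float]:
    """Load a taxon -> sensitivity-score table.

    *source* is a CSV path or a DataFrame with columns ``taxon, score``.
    Names are matched case-insensitively after whitespace normalization;
    duplicate normalized names or negative scores are errors.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if not {"taxon", "score"}.issubset(df.columns):
        raise ValueError("score table needs columns 'taxon' and 'score'")
    table: dict[str, float] = {}
    for taxon, score in zip(df["taxon"], df["score"]):
        key = normalize_taxon(taxon)
        score = float(score)
        if score < 0:
            raise ValueError(f"negative sensitivity score for {taxon!r}")
        if key in table:
            raise ValueError(f"duplicate taxon after normalization: {taxon!r}")
        table[key] = score
    if not table:
        raise ValueError("score table is empty")
    return table


def demo_score_table() -> dict[str, float]:
    """The packaged synthetic demonstration score table (26 taxa)."""
    ref = importlib.resources.files("sedbench").joinpath("data/demo_fsbi_scores.csv")
    with importlib.resources.as_file(ref) as path:
        return load_score_table(path)


def score_sample(
    taxa_present,
    table: dict[str, float],
    on_missing: str = "ignore",
) -> float:
    """FSBI for one sample: sum of scores over distinct taxa present.

    Duplicates collapse (occurrence only, abundance ignored). Taxa absent
    from the table are handled per *on_missing*: ``ignore`` (skip), ``warn``
    (skip with a warning), or ``error``.
    """
    if not table:
        raise ValueError("score table is empty")
    if on_missing not in ("ignore", "warn", "error"):
        raise ValueError(f"invalid on_missing: {on_missing!r}")
    total = 0.0
    for taxon in {normalize_taxon(t) for t in taxa_present}:
        if taxon in table:
            total += table[taxon]
        elif on_missing == "error":
            raise KeyError(f"taxon not in score table: {taxon!r}")
        elif on_missing == "warn":
            warnings.warn(f"taxon not in score table, skipped: {taxon!r}")
    return total


def score_events(
    taxa: pd.DataFrame,
    table: dict[str, float],
    on_missing: str = "ignore",
) -> pd.DataFrame:
    """FSBI per event from a long occurrence table (``event_id, taxon``).

    Returns a DataFrame with columns ``event_id, fsbi``. Scores above the
    0-350 plausibility band are logged as warnings, not rejected.
    """
    if not {"event_id", "taxon"}.issubset(taxa.columns):
        raise ValueError("taxa table needs columns 'event_id' and 'taxon'")
    rows = [
        (event_id, score_sample(group["taxon"], table, on_missing))
        for event_id, group in taxa.groupby("event_id", sort=True)
    ]
    out = pd.DataFrame(rows, columns=["event_id", "fsbi"])
    high = out[out["fsbi"] > FSBI_PLAUSIBLE_MAX]
    if not high.empty:
        logger.warning(
            "%d events with FSBI above the 0-%g plausibility band",
            len(high), FSBI_PLAUSIBLE_MAX,
        )
    return out


def derive_taxon_tolerance(
    events: pd.DataFrame,
    taxa: pd.DataFrame,
    min_events: int = 5,
) -> pd.DataFrame:
    """Per-taxon tolerance: SF at the taxon's 75th-percentile occurrence.

    For each taxon, take the SF values of the events where it occurs and
    report the type-7 (linear interpolation) 75th percentile. Taxa occurring
    at fewer than *min_events* events are omitted with a warning. Mapping
    the percentile to a sensitivity score is left to a user-supplied binning
    table.

    Parameters
    ----------
    events : DataFrame with ``event_id`` and ``sf`` columns.
    taxa : long occurrence table ``event_id, taxon``.

    Returns
    -------
    DataFrame ``taxon, n_events, sf_p75`` sorted by taxon.
    """
    if "sf" not in events.columns:
        raise ValueError("events table needs an 'sf' column")
    sf_by_event = events.set_index("event_id")["sf"]
    rows = []
    for taxon, group in taxa.assign(
        taxon=taxa["taxon"].map(normalize_taxon)
    ).groupby("taxon", sort=True):
        event_ids = group["event_id"].unique()
        sf_vals = sf_by_event.reindex(event_ids).dropna().to_numpy(float)
        if len(sf_vals) < min_events:
            warnings.warn(
                f"taxon {taxon!r} occurs at {len(sf_vals)} events "
                f"(< {min_events}); omitted from tolerance derivation"
            )
            continue
        rows.append((taxon, len(sf_vals), float(np.percentile(sf_vals, 75))))
    return pd.DataFrame(rows, columns=["taxon", "n_events", "sf_p75"])
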