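"""Design-weighted relative risk and reference false-positive rates.

Each sample event is rated good/poor on the stressor side (SF against a
benchmark; poor iff SF strictly exceeds it) and on the biology side (an
indicator against its benchmark; poor iff strictly below it). Relative
risk is the ratio of the survey-weighted probability of poor biology given
poor SF to that probability given good SF; its confidence interval comes
from a Taylor linearization of log(RR) treating the design as single stage
with known weights. Equality with the benchmark counts as achieved
("good") on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .reference import BenchmarkSet

logger = logging.getLogger(__name__)

BIO_INDICATORS = ("FSBI", "SMI2", "OE")


@dataclass(frozen=True)
class RREstimate:
    """Design-weighted relative risk with Wald log-scale CI and cell tallies."""

    rr: float
    ci: tuple[float, float]
    level: float
    cells: dict  # weighted 2x2 totals keyed (sf_status, bio_status)
    n_events: int
    method: str = "taylor-linearized log(RR), single-stage weighted design"


@dataclass(frozen=True)
class FalsePositiveRates:
    """Shares of reference events failing each benchmark, in percent."""

    fp_sf: float
    fp_fsbi: float
    fp_framework: float
    n: int


def _bio_benchmark_series(
    events: pd.DataFrame,
    benchmark_set: BenchmarkSet,
    bio_indicator: str,
    config: RunConfig,
    bio_benchmark=None,
) -> tuple[pd.Series, pd.Series]:
    """(indicator values, per-event benchmark) for the chosen bio indicator."""
    if bio_indicator == "FSBI":
        ref = {} if bio_benchmark is None else None
        if bio_benchmark is not None:
            bench = events["site_class"].map(lambda c: float(bio_benchmark))
        else:
            missing = set(events["site_class"]) - set(benchmark_set.fsbi_ref)
            if missing:
                raise KeyError(f"no FSBI_ref for classes: {sorted(missing)}")
            bench = events["site_class"].map(benchmark_set.fsbi_ref)
        return events["fsbi"], bench
    if bio_indicator == "SMI2":
        if "smi2" not in events.columns:
            raise KeyError("events lack an 'smi2' column")
        if bio_benchmark is not None:
            bench = pd.Series(float(bio_benchmark), index=events.index)
        else:
            bench = events["site_class"].map(config.smi2_benchmark_for)
        return events["smi2"], bench
    if bio_indicator == "OE":
        if "oe" not in events.columns:
            raise KeyError("events lack an 'oe' column")
        cutoff = config.oe_benchmark if bio_benchmark is None else float(bio_benchmark)
        return events["oe"], pd.Series(float(cutoff), index=events.index)
    raise ValueError(f"unknown bio indicator: {bio_indicator!r} (use {BIO_INDICATORS})")


def condition_flags(
    events: pd.DataFrame,
    benchmark_set: BenchmarkSet,
    bio_indicator: str = "FSBI",
    bio_benchmark=None,
    sf_benchmark: str = "sf_ref",
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Rate each event good/poor on the SF and biology sides.

    ``sf_benchmark`` selects the stressor benchmark: ``"sf_ref"`` (reach-
    specific quantile prediction) or ``"sr50"``/``"sr75"`` (per-cell
    stressor-response values). Events whose benchmark cell is unavailable
    are dropped with a log message.

    Returns a DataFrame ``event_id, sf_status, bio_status, weight`` with
    statuses in {"good", "poor"}.
    """
    cfg = config or RunConfig()
    required = {"event_id", "site_class", "order", "sf"}
    missing = required - set(events.columns)
    if missing:
        raise KeyError(f"events missing columns: {sorted(missing)}")

    rows = []
    bio_vals, bio_bench = _bio_benchmark_series(
        events, benchmark_set, bio_indicator, cfg, bio_benchmark
    )
    for idx, ev in events.iterrows():
        try:
            if sf_benchmark == "sf_ref":
                if not np.isfinite(ev.get("bankfull_width_m", np.nan)):
                    raise KeyError("missing bankfull width")
                sf_bench = benchmark_set.sf_ref_for(ev["order"], ev["bankfull_width_m"])
            elif sf_benchmark in ("sr50", "sr75"):
                p = 0.50 if sf_benchmark == "sr50" else 0.75
                sf_bench = benchmark_set.sr_for(ev["site_class"], ev["order"], p)
            else:
                raise ValueError(f"unknown sf benchmark: {sf_benchmark!r}")
        except KeyError as exc:
            logger.info("event %s dropped: %s", ev["event_id"], exc)
            continue
        bv, bb = bio_vals.loc[idx], bio_bench.loc[idx]
        if not (np.isfinite(ev["sf"]) and np.isfinite(bv)):
            logger.info("event %s dropped: missing indicator value", ev["event_id"])
            continue
        rows.append({
            "event_id": ev["event_id"],
            "sf_status": "poor" if ev["sf"] > sf_bench else "good",
            "bio_status": "poor" if bv < bb else "good",
            "weight": float(ev.get("weight", 1.0)),
        })
    flags = pd.DataFrame(rows, columns=["event_id", "sf_status", "bio_status", "weight"])
    if not flags.empty and (flags["weight"] <= 0).any():
        raise ValueError("weights must be positive")
    return flags


def relative_risk(flags: pd.DataFrame, level: float = 0.95) -> RREstimate:
    """Design-weighted relative risk of poor biology given poor SF.

    RR = P_w(bio poor | SF poor) / P_w(bio poor | SF good) with weighted
    probabilities. The CI is ``RR * exp(+/- z * se(log RR))`` where
    ``var(log RR)`` sums the linearized variances of the two weighted
    stratum proportions; it is invariant under rescaling all weights.
    """
    if flags.empty:
        raise ValueError("no condition flags")
    z = {0.95: 1.959963984540054}.get(level)
    if z is None:
        from scipy import stats

        z = float(stats.norm.ppf(0.5 + level / 2.0))

    strata = {}
    for status in ("poor", "good"):
        sub = flags[flags["sf_status"] == status]
        wsum = sub["weight"].sum()
        if sub.empty or wsum <= 0:
            raise ValueError(f"empty SF stratum: {status!r}")
        y = (sub["bio_status"] == "poor").to_numpy(float)
        w = sub["weight"].to_numpy(float)
        p = float((w * y).sum() / wsum)
        var = float((w**2 * (y - p) ** 2).sum() / wsum**2)
        strata[status] = (p, var)

    p1, v1 = strata["poor"]
    p2, v2 = strata["good"]
    if p2 == 0:
        raise ValueError("RR undefined: zero weighted probability in the "
                         "good-SF stratum")
    rr = p1 / p2
    cells = {
        (s, b): float(flags.loc[
            (flags["sf_status"] == s) & (flags["bio_status"] == b), "weight"
        ].sum())
        for s in ("poor", "good")
        for b in ("poor", "good")
    }
    if p1 == 0:
        logger.warning("no poor-biology events in the poor-SF stratum; RR=0 "
                       "with degenerate CI")
        ci = (0.0, 0.0)
    else:
        se_log = float(np.sqrt(v1 / p1**2 + v2 / p2**2))
        ci = (rr * float(np.exp(-z * se_log)), rr * float(np.exp(z * se_log)))
    return RREstimate(rr=float(rr), ci=ci, level=level,
                      cells=cells, n_events=int(len(flags)))


def rr_table(
    events: pd.DataFrame,
    benchmark_set: BenchmarkSet,
    bio_indicators=("FSBI",),
    sf_benchmarks=("sf_ref", "sr50", "sr75"),
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Relative risk for each (SF benchmark, bio indicator) combination."""
    rows = []
    for sfb in sf_benchmarks:
        for bio in bio_indicators:
            try:
                flags = condition_flags(
                    events, benchmark_set, bio_indicator=bio,
                    sf_benchmark=sfb, config=config,
                )
                est = relative_risk(flags)
                rows.append({
                    "sf_benchmark": sfb, "bio_indicator": bio,
                    "rr": est.rr, "ci_low": est.ci[0], "ci_high": est.ci[1],
                    "n_events": est.n_events, "status": "ok",
                })
            except (ValueError, KeyError) as exc:
                logger.warning("RR %s/%s unavailable: %s", sfb, bio, exc)
                rows.append({
                    "sf_benchmark": sfb, "bio_indicator": bio, "status": str(exc),
                })
    return pd.DataFrame(rows)


def false_positive_rates(
    reference_events: pd.DataFrame,
    benchmark_set: BenchmarkSet,
) -> FalsePositiveRates:
    """Benchmark false-positive rates among reference events, in percent.

    ``fp_sf`` is the share of reference events with SF strictly above their
    reach-specific SF_ref, ``fp_fsbi`` the share with FSBI strictly below
    the class FSBI_ref, and ``fp_framework`` the share failing both (rated
    "likely"); by construction the joint rate never exceeds either
    marginal.
    """
    from .framework import assess_dataset

    if reference_events.empty:
        raise ValueError("empty reference set")
    assessment = assess_dataset(reference_events, benchmark_set)
    ratings = assessment.ratings
    if ratings.empty:
        raise ValueError("no assessable reference events")
    n = len(ratings)
    fp_sf = 100.0 * (~ratings["sf_achieved"]).sum() / n
    fp_fsbi = 100.0 * (~ratings["fsbi_achieved"]).sum() / n
    fp_fw = 100.0 * (ratings["rating"] == "likely").sum() / n
    return FalsePositiveRates(
        fp_sf=float(fp_sf), fp_fsbi=float(fp_fsbi),
        fp_framework=float(fp_fw), n=int(n),
    )
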