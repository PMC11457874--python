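"""Reference benchmarks: SF quantile regression and FSBI percentiles.

The SF reference benchmark (SF_ref) is reach-specific: within each Strahler
order, a 75th-percentile quantile regression of percent surface fines on
bankfull width is fitted to reference-labelled events, and the fitted line
evaluated at a reach's bankfull width (clipped to [0, 100]) is its upper
bound SF expected under reference condition. The FSBI reference benchmark
(FSBI_ref) is the 25th-percentile FSBI among reference events within each
site class.

The quantile fit minimizes the pinball (check) loss
``sum_i rho_tau(SF_i - a - b*BW_i)``. For small samples the exact optimum
is found by enumerating all lines through point pairs (the LP vertices of
the two-parameter problem); flat optima are resolved by a deterministic
tie-break (smallest |slope|, then smallest intercept). Larger fits use
iteratively reweighted least squares.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ORDERS, RunConfig, SITE_CLASSES
from . import stressor as _stressor
from .stressor import (
    LogisticDiagnostics,
    LogisticModel,
    SRCell,
    StressorResponseBenchmark,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantileModel:
    """Per-order linear quantile model SF_q(BW) = intercept + slope * BW."""

    order: int
    tau: float
    intercept: float
    slope: float
    n: int


def pinball_loss(residuals, tau: float) -> float:
    """Check-function loss: tau*r for r >= 0, (tau-1)*r for r < 0."""
    r = np.asarray(residuals, float)
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1.0) * r)))


def _pair_search(bw: np.ndarray, sf: np.ndarray, tau: float) -> tuple[float, float]:
    """Exact pinball-loss optimum by enumerating point-pair lines.

    With two free parameters the LP optimum is attained at a line
    interpolating two observations with distinct BW; ties within 1e-9 of
    the best loss break to the smallest |slope|, then smallest intercept.
    """
    n = len(bw)
    ii, jj = np.triu_indices(n, k=1)
    keep = bw[ii] != bw[jj]
    ii, jj = ii[keep], jj[keep]
    if len(ii) == 0:
        raise ValueError("degenerate bankfull widths: all values equal")
    slopes = (sf[jj] - sf[ii]) / (bw[jj] - bw[ii])
    intercepts = sf[ii] - slopes * bw[ii]
    # losses for all candidate lines at once: (n_candidates, n)
    resid = sf[None, :] - intercepts[:, None] - slopes[:, None] * bw[None, :]
    losses = np.where(resid >= 0, tau * resid, (tau - 1.0) * resid).sum(axis=1)
    best = losses.min()
    tied = np.flatnonzero(losses <= best + 1e-9)
    order = np.lexsort((intercepts[tied], np.abs(slopes[tied])))
    pick = tied[order[0]]
    return float(intercepts[pick]), float(slopes[pick])


def fit_sf_quantile_model(
    bw,
    sf,
    tau: float = 0.75,
    order: int = 0,
    min_n: int = 10,
    pair_search_max_n: int = 200,
) -> QuantileModel:
    """Fit the per-order SF ~ BW quantile regression on reference events."""
    bw = np.asarray(bw, float)
    sf = np.asarray(sf, float)
    if bw.shape != sf.shape:
        raise ValueError("bw and sf must have the same length")
    n = len(bw)
    if n < min_n:
        raise ValueError(f"n={n} below minimum {min_n}")
    if not (bw > 0).all():
        raise ValueError("bankfull widths must be positive")
    if np.ptp(bw) == 0:
        raise ValueError("degenerate bankfull widths: all values equal")
    if n <= pair_search_max_n:
        intercept, slope = _pair_search(bw, sf, tau)
    else:
        from statsmodels.regression.quantile_regression import QuantReg

        X = np.column_stack([np.ones(n), bw])
        res = QuantReg(sf, X).fit(q=tau)
        intercept, slope = float(res.params[0]), float(res.params[1])
    return QuantileModel(order=int(order), tau=float(tau),
                         intercept=intercept, slope=slope, n=n)


def predict_sf_ref(model: QuantileModel, bw) -> np.ndarray | float:
    """Reach-specific SF_ref: the fitted line at BW, clipped to [0, 100]."""
    bw_arr = np.asarray(bw, float)
    if not (bw_arr > 0).all():
        raise ValueError("bankfull width must be positive")
    raw = model.intercept + model.slope * bw_arr
    clipped = np.clip(raw, 0.0, 100.0)
    return float(clipped) if np.ndim(bw) == 0 else clipped


def compute_fsbi_ref(fsbi_values, percentile: float = 25.0, min_n: int = 10) -> float:
    """Class FSBI reference benchmark: type-7 sample percentile of FSBI."""
    vals = np.asarray(fsbi_values, float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < min_n:
        raise ValueError(f"n={len(vals)} below minimum {min_n}")
    return float(np.percentile(vals, percentile))  # linear = Hyndman-Fan type 7


def subsample_one_per_segment(
    events: pd.DataFrame,
    rng: np.random.Generator,
    labels: tuple[str, ...] = ("reference", "stress"),
) -> pd.DataFrame:
    """Keep one randomly selected event per stream segment (comid).

    Applied to reference- and stress-labelled events only, mirroring the
    screening used to build the benchmark datasets; other events pass
    through unchanged. No-op when there is no ``comid`` column.
    """
    if "comid" not in events.columns:
        return events
    mask = events["disturbance"].isin(labels) if "disturbance" in events.columns else pd.Series(True, index=events.index)
    subject = events[mask]
    keep_idx = list(events.index[~mask])
    for _, group in subject.groupby("comid", sort=True):
        keep_idx.append(group.index[rng.integers(len(group))])
    return events.loc[sorted(keep_idx)]


@dataclass
class BenchmarkSet:
    """All derived benchmarks plus provenance metadata.

    ``unavailable`` lists every cell that could not be populated, keyed
    ``"sf_quantile:<order>"``, ``"fsbi_ref:<class>"`` or
    ``"sr:<class>:<order>"``, with a reason.
    """

    quantile_models: dict = field(default_factory=dict)  # order -> QuantileModel
    fsbi_ref: dict = field(default_factory=dict)  # site_class -> float
    sr_cells: dict = field(default_factory=dict)  # (class, order) -> SRCell
    unavailable: dict = field(default_factory=dict)  # str key -> reason
    metadata: dict = field(default_factory=dict)

    # -- lookups -------------------------------------------------------

    def sf_ref_for(self, order: int, bw: float) -> float:
        model = self.quantile_models.get(int(order))
        if model is None:
            raise KeyError(f"no SF quantile model for order {order}")
        return float(predict_sf_ref(model, float(bw)))

    def sr_for(self, site_class: str, order: int, probability: float) -> float:
        cell = self.sr_cells.get((site_class, int(order)))
        if cell is None:
            raise KeyError(f"no stressor-response cell for {site_class} order {order}")
        bench = cell.benchmarks.get(probability)
        if bench is None:
            raise KeyError(f"no benchmark at p={probability}")
        return float(bench.sf_value)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def cell_dict(cell: SRCell) -> dict:
            m, d = cell.model, cell.diagnostics
            return {
                "model": {
                    "site_class": m.site_class, "order": m.order,
                    "beta0": m.beta0, "beta1": m.beta1,
                    "se0": m.se0, "se1": m.se1,
                    "null_deviance": m.null_deviance,
                    "residual_deviance": m.residual_deviance,
                    "n": m.n, "converged": m.converged,
                },
                "diagnostics": {
                    "model_chi_square": d.model_chi_square,
                    "chi_square_p": d.chi_square_p,
                    "odds_ratio": d.odds_ratio,
                    "or_ci": list(d.or_ci),
                    "hl_statistic": d.hl_statistic,
                    "hl_p": d.hl_p,
                    "hl_groups": d.hl_groups,
                },
                "benchmarks": {
                    str(p): {
                        "probability": b.probability,
                        "sf_value": b.sf_value,
                        "rounded_sf": b.rounded_sf,
                    }
                    for p, b in cell.benchmarks.items()
                },
            }

        return {
            "quantile_models": {
                str(o): {
                    "order": m.order, "tau": m.tau,
                    "intercept": m.intercept, "slope": m.slope, "n": m.n,
                }
                for o, m in sorted(self.quantile_models.items())
            },
            "fsbi_ref": {c: v for c, v in sorted(self.fsbi_ref.items())},
            "sr_cells": {
                f"{c}:{o}": cell_dict(cell)
                for (c, o), cell in sorted(self.sr_cells.items())
            },
            "unavailable": dict(sorted(self.unavailable.items())),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkSet":
        qms = {
            int(o): QuantileModel(**m) for o, m in d.get("quantile_models", {}).items()
        }
        cells = {}
        for key, cd in d.get("sr_cells", {}).items():
            site_class, order = key.rsplit(":", 1)
            model = LogisticModel(**cd["model"])
            dd = dict(cd["diagnostics"])
            dd["or_ci"] = tuple(dd["or_ci"])
            diag = LogisticDiagnostics(**dd)
            benchmarks = {
                float(p): StressorResponseBenchmark(
                    site_class=site_class, order=int(order), **b
                )
                for p, b in cd["benchmarks"].items()
            }
            cells[(site_class, int(order))] = SRCell(model, diag, benchmarks)
        return cls(
            quantile_models=qms,
            fsbi_ref={c: float(v) for c, v in d.get("fsbi_ref", {}).items()},
            sr_cells=cells,
            unavailable=dict(d.get("unavailable", {})),
            metadata=dict(d.get("metadata", {})),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "BenchmarkSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def quantile_table(self) -> pd.DataFrame:
        """Coefficient table of the per-order SF_ref quantile regressions."""
        rows = [
            {
                "order": m.order, "tau": m.tau, "n": m.n,
                "intercept": m.intercept, "slope": m.slope,
                "equation": f"SF_ref = {m.slope:.5f} * BW + {m.intercept:.5f}",
            }
            for _, m in sorted(self.quantile_models.items())
        ]
        return pd.DataFrame(rows)

    def sr_table(self) -> pd.DataFrame:
        un = {
            (k.split(":")[1], int(k.split(":")[2])): v
            for k, v in self.unavailable.items()
            if k.startswith("sr:")
        }
        return _stressor.sr_table(self.sr_cells, un)


def derive_benchmark_set(
    events: pd.DataFrame,
    config: RunConfig | None = None,
    metadata: dict | None = None,
) -> BenchmarkSet:
    """Derive the full benchmark set from a labelled event table.

    Order of operations: (1) one event per stream segment is kept among
    reference/stress events when segment ids (comid) are present, seeded by
    ``config.subsample_seed``; (2) per-order 75th-percentile SF quantile
    regressions on reference events; (3) per-class 25th-percentile FSBI_ref
    on reference events; (4) per-cell logistic stressor-response benchmarks
    on all events. Cells below minimum n are marked unavailable, never
    fatal.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(cfg.subsample_seed)
    data = subsample_one_per_segment(events, rng)
    reference = (
        data[data["disturbance"] == "reference"]
        if "disturbance" in data.columns
        else data.iloc[0:0]
    )

    out = BenchmarkSet(metadata={
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "subsample_seed": cfg.subsample_seed,
        "n_events": int(len(data)),
        "n_reference": int(len(reference)),
        "percentile_method": "type-7 linear interpolation",
        **(metadata or {}),
    })

    for order in ORDERS:
        sub = reference[reference["order"] == order].dropna(subset=["sf", "bankfull_width_m"])
        try:
            out.quantile_models[order] = fit_sf_quantile_model(
                sub["bankfull_width_m"], sub["sf"],
                tau=cfg.tau, order=order,
                min_n=cfg.min_n_quantile,
                pair_search_max_n=cfg.pair_search_max_n,
            )
        except ValueError as exc:
            logger.warning("SF quantile model order %d unavailable: %s", order, exc)
            out.unavailable[f"sf_quantile:{order}"] = str(exc)

    for site_class in SITE_CLASSES:
        vals = reference.loc[reference["site_class"] == site_class, "fsbi"]
        try:
            out.fsbi_ref[site_class] = compute_fsbi_ref(
                vals, percentile=cfg.fsbi_ref_percentile, min_n=cfg.min_n_fsbi_ref
            )
        except ValueError as exc:
            logger.warning("FSBI_ref %s unavailable: %s", site_class, exc)
            out.unavailable[f"fsbi_ref:{site_class}"] = str(exc)

    cells, un = _stressor.derive_sr_benchmarks(data, out.fsbi_ref, cfg)
    out.sr_cells = cells
    for (site_class, order), reason in un.items():
        out.unavailable[f"sr:{site_class}:{order}"] = reason
    return out
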