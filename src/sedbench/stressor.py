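"""Logistic stressor-response models and SR50/SR75 benchmark inversion.

Within each site class x stream order cell, a logistic regression predicts
the probability that a sample's FSBI is worse (strictly less) than the
class FSBI reference benchmark as a function of percent surface fines:

    P(FSBI < FSBI_ref | SF) = 1 / (1 + exp(-(b0 + b1 * SF)))

Inverting the fitted curve at p = 0.50 and 0.75 gives the SR50 and SR75
stressor-response benchmarks. Model adequacy is documented with the model
chi-square (null minus residual deviance), the slope odds ratio with
confidence interval, and the Hosmer-Lemeshow calibration test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats, special

logger = logging.getLogger(__name__)


class SeparationError(ValueError):
    """Raised when the binary response is completely separated along SF."""


@dataclass(frozen=True)
class LogisticModel:
    """Fitted per-cell logistic stressor-response model (log-odds scale)."""

    site_class: str
    order: int
    beta0: float
    beta1: float
    se0: float
    se1: float
    null_deviance: float
    residual_deviance: float
    n: int
    converged: bool = True

    def __post_init__(self):
        if self.residual_deviance > self.null_deviance + 1e-8:
            raise ValueError("residual deviance exceeds null deviance")


@dataclass(frozen=True)
class LogisticDiagnostics:
    model_chi_square: float
    chi_square_p: float
    odds_ratio: float
    or_ci: tuple[float, float]
    hl_statistic: float
    hl_p: float
    hl_groups: int


@dataclass(frozen=True)
class StressorResponseBenchmark:
    """SF value with a given probability that FSBI is worse than reference."""

    site_class: str
    order: int
    probability: float
    sf_value: float
    rounded_sf: int


@dataclass(frozen=True)
class SRCell:
    """One fitted site-class x order cell with diagnostics and benchmarks."""

    model: LogisticModel
    diagnostics: LogisticDiagnostics
    benchmarks: dict  # probability -> StressorResponseBenchmark


def make_response(events: pd.DataFrame, fsbi_ref: dict[str, float]) -> pd.Series:
    """Binary response: 1 iff FSBI is strictly less than the class FSBI_ref."""
    missing = set(events["site_class"].unique()) - set(fsbi_ref)
    if missing:
        raise KeyError(f"no FSBI_ref for site classes: {sorted(missing)}")
    ref = events["site_class"].map(fsbi_ref)
    return (events["fsbi"] < ref).astype(int)


def _check_separation(sf: np.ndarray, y: np.ndarray) -> None:
    s0, s1 = sf[y == 0], sf[y == 1]
    if s0.max() < s1.min() or s1.max() < s0.min():
        raise SeparationError(
            "complete separation: a single SF threshold perfectly splits the "
            "response; logistic coefficients are unbounded"
        )


def log_likelihood(beta0: float, beta1: float, sf, y) -> float:
    """Bernoulli log-likelihood of the logistic model (numerically stable)."""
    sf = np.asarray(sf, float)
    y = np.asarray(y, float)
    eta = beta0 + beta1 * sf
    # log p = -log1p(exp(-eta)); log(1-p) = -log1p(exp(eta))
    return float(-(y * np.logaddexp(0.0, -eta) + (1 - y) * np.logaddexp(0.0, eta)).sum())


def fit_logistic(
    sf,
    labels,
    site_class: str = "",
    order: int = 0,
    min_n: int = 10,
) -> LogisticModel:
    """Maximum-likelihood logistic fit of the binary response on SF.

    Fitting is by iteratively reweighted least squares; standard errors come
    from the observed information at the optimum. Single-label data and
    completely separated data are rejected with explicit errors.
    """
    sf = np.asarray(sf, float)
    y = np.asarray(labels, int)
    if sf.shape != y.shape:
        raise ValueError("sf and labels must have the same length")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("single-label data: both response values required")
    _check_separation(sf, y)
    if len(y) < min_n:
        raise ValueError(f"n={len(y)} below minimum {min_n}")

    X = sm.add_constant(sf)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return LogisticModel(
        site_class=site_class,
        order=int(order),
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        se0=float(res.bse[0]),
        se1=float(res.bse[1]),
        null_deviance=float(res.null_deviance),
        residual_deviance=float(res.deviance),
        n=int(len(y)),
        converged=bool(getattr(res, "converged", True)),
    )


def predict_probability(model: LogisticModel, sf) -> np.ndarray | float:
    """P(FSBI worse than reference | SF) under the fitted model."""
    p = special.expit(model.beta0 + model.beta1 * np.asarray(sf, float))
    return float(p) if np.isscalar(sf) or np.ndim(sf) == 0 else p


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def invert_logistic(model: LogisticModel, p: float) -> StressorResponseBenchmark:
    """SF at which the model predicts response probability *p*.

    Solves ``b0 + b1*SF = logit(p)``. Only defined for an increasing risk
    curve (b1 > 0). Reported benchmarks are rounded to the nearest integer
    (half away from zero); full precision is retained in ``sf_value``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must be in (0,1), got {p}")
    if model.beta1 <= 0:
        raise ValueError(
            "benchmark undefined: slope is non-positive (risk does not "
            "increase with SF)"
        )
    sf_value = (special.logit(p) - model.beta0) / model.beta1
    return StressorResponseBenchmark(
        site_class=model.site_class,
        order=model.order,
        probability=float(p),
        sf_value=float(sf_value),
        rounded_sf=_round_half_away(float(sf_value)),
    )


def hosmer_lemeshow(
    model: LogisticModel,
    sf,
    labels,
    groups: int = 10,
) -> tuple[float, float, int]:
    """Hosmer-Lemeshow calibration test over predicted-probability bins.

    Events are ranked by predicted probability and split into *groups*
    near-equal bins; tied predictions stay in the same bin (bin boundaries
    snap forward past ties so the split is order-independent). Bins with a
    degenerate expected count are merged into their neighbor. The statistic
    is ``sum_g (O_g - E_g)^2 / (n_g * pbar_g * (1 - pbar_g))`` on
    chi-square with ``groups_used - 2`` degrees of freedom.

    Returns ``(statistic, p_value, groups_used)``.
    """
    sf = np.asarray(sf, float)
    y = np.asarray(labels, float)
    n = len(y)
    if groups < 3:
        raise ValueError("need at least 3 groups (df = groups - 2 >= 1)")
    if n < 2 * groups:
        raise ValueError(f"n={n} below 2*groups={2 * groups}")
    p = special.expit(model.beta0 + model.beta1 * sf)
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]

    # near-equal-count boundaries, snapped forward so ties share a bin
    edges = []
    for g in range(1, groups):
        e = int(round(n * g / groups))
        while 0 < e < n and ps[e - 1] == ps[e]:
            e += 1
        edges.append(e)
    edges = sorted(set(e for e in edges if 0 < e < n))
    bounds = [0] + edges + [n]

    bins = []  # (n_g, O_g, E_g)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        bins.append([hi - lo, ys[lo:hi].sum(), ps[lo:hi].sum()])
    # merge bins whose variance term would be zero into the previous bin
    merged: list[list[float]] = []
    for b in bins:
        n_g, O, E = b
        if merged and (E <= 0 or E >= n_g):
            merged[-1] = [merged[-1][0] + n_g, merged[-1][1] + O, merged[-1][2] + E]
        else:
            merged.append(b)
    if len(merged) > 1 and (merged[0][2] <= 0 or merged[0][2] >= merged[0][0]):
        first = merged.pop(0)
        merged[0] = [merged[0][0] + first[0], merged[0][1] + first[1], merged[0][2] + first[2]]

    groups_used = len(merged)
    df = groups_used - 2
    if df < 1:
        raise ValueError(
            f"insufficient degrees of freedom after merging ({groups_used} bins)"
        )
    stat = 0.0
    for n_g, O, E in merged:
        pbar = E / n_g
        stat += (O - E) ** 2 / (n_g * pbar * (1.0 - pbar))
    return float(stat), float(stats.chi2.sf(stat, df)), groups_used


def odds_ratio_ci(
    model: LogisticModel,
    level: float = 0.95,
    method: str = "wald",
    sf=None,
    labels=None,
) -> tuple[float, float]:
    """Confidence interval for exp(beta1), the per-1%-SF odds ratio.

    ``wald`` (default): exp(beta1 +/- z * se1). ``profile``: profile
    likelihood, refitting the intercept with beta1 fixed (requires the
    original ``sf`` and ``labels``).
    """
    if method == "wald":
        z = stats.norm.ppf(0.5 + level / 2.0)
        return (
            float(np.exp(model.beta1 - z * model.se1)),
            float(np.exp(model.beta1 + z * model.se1)),
        )
    if method != "profile":
        raise ValueError(f"unknown CI method: {method!r}")
    if sf is None or labels is None:
        raise ValueError("profile CI requires the original sf and labels")
    sf = np.asarray(sf, float)
    y = np.asarray(labels, int)
    crit = stats.chi2.ppf(level, 1)
    ll_hat = log_likelihood(model.beta0, model.beta1, sf, y)

    def profile_excess(b1: float) -> float:
        # intercept-only refit with the slope term as an offset
        res = sm.GLM(
            y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=b1 * sf
        ).fit()
        ll = log_likelihood(float(res.params[0]), b1, sf, y)
        return 2.0 * (ll_hat - ll) - crit

    span = max(5.0 * model.se1, 1e-3)
    lo = optimize.brentq(profile_excess, model.beta1 - 50 * span, model.beta1)
    hi = optimize.brentq(profile_excess, model.beta1, model.beta1 + 50 * span)
    return float(np.exp(lo)), float(np.exp(hi))


def diagnostics(
    model: LogisticModel,
    sf,
    labels,
    groups: int = 10,
    level: float = 0.95,
    or_method: str = "wald",
) -> LogisticDiagnostics:
    """Assemble the standard adequacy statistics for a fitted cell."""
    chi2_stat = model.null_deviance - model.residual_deviance
    chi2_p = float(stats.chi2.sf(chi2_stat, 1))
    try:
        hl_stat, hl_p, hl_groups = hosmer_lemeshow(model, sf, labels, groups)
    except ValueError as exc:
        logger.warning("Hosmer-Lemeshow unavailable: %s", exc)
        hl_stat, hl_p, hl_groups = float("nan"), float("nan"), 0
    return LogisticDiagnostics(
        model_chi_square=float(chi2_stat),
        chi_square_p=chi2_p,
        odds_ratio=float(np.exp(model.beta1)),
        or_ci=odds_ratio_ci(model, level, or_method, sf, labels),
        hl_statistic=hl_stat,
        hl_p=hl_p,
        hl_groups=hl_groups,
    )


def derive_sr_benchmarks(
    events: pd.DataFrame,
    fsbi_ref: dict[str, float],
    config=None,
) -> tuple[dict, dict]:
    """Fit all site-class x order cells and invert SR benchmarks.

    Every cell present in the data is attempted; cells that cannot be fitted
    (too few events, one-sided response, separation, non-positive slope) are
    reported in the second return value with a reason, never raised.

    Returns ``(cells, unavailable)`` where ``cells`` maps
    ``(site_class, order)`` to :class:`SRCell` and ``unavailable`` maps the
    same keys to a reason string.
    """
    from .config import ORDERS, RunConfig, SITE_CLASSES

    cfg = config or RunConfig()
    cells: dict[tuple[str, int], SRCell] = {}
    unavailable: dict[tuple[str, int], str] = {}
    for site_class in SITE_CLASSES:
        for order in ORDERS:
            key = (site_class, int(order))
            sub = events[
                (events["site_class"] == site_class) & (events["order"] == order)
            ].dropna(subset=["sf", "fsbi"])
            if site_class not in fsbi_ref:
                unavailable[key] = "no FSBI_ref for site class"
                continue
            if len(sub) < cfg.min_n_logistic:
                unavailable[key] = f"n={len(sub)} below minimum {cfg.min_n_logistic}"
                continue
            y = make_response(sub, fsbi_ref)
            try:
                model = fit_logistic(
                    sub["sf"], y, site_class, order, min_n=cfg.min_n_logistic
                )
                diag = diagnostics(
                    model, sub["sf"], y,
                    groups=cfg.hl_groups, level=cfg.ci_level,
                    or_method=cfg.or_ci_method,
                )
                benchmarks = {
                    p: invert_logistic(model, p) for p in cfg.sr_probabilities
                }
            except (ValueError, KeyError) as exc:
                logger.warning("cell %s order %d unavailable: %s", site_class, order, exc)
                unavailable[key] = str(exc)
                continue
            if not math.isnan(diag.hl_p) and diag.hl_p < 0.05:
                logger.warning(
                    "cell %s order %d: significant Hosmer-Lemeshow p=%.3f; model "
                    "retained (chi-square and odds ratio indicate fit)",
                    site_class, order, diag.hl_p,
                )
            cells[key] = SRCell(model=model, diagnostics=diag, benchmarks=benchmarks)
    return cells, unavailable


def sr_table(cells: dict, unavailable: dict) -> pd.DataFrame:
    """Flat per-cell report: n, SR50/SR75, coefficients (SE), diagnostics."""
    rows = []
    keys = sorted(set(cells) | set(unavailable))
    for site_class, order in keys:
        if (site_class, order) in cells:
            cell = cells[(site_class, order)]
            m, d = cell.model, cell.diagnostics
            row = {
                "site_class": site_class,
                "order": order,
                "n": m.n,
                "intercept": m.beta0,
                "intercept_se": m.se0,
                "slope": m.beta1,
                "slope_se": m.se1,
                "model_chi_square": d.model_chi_square,
                "chi_square_p": d.chi_square_p,
                "odds_ratio": d.odds_ratio,
                "or_ci_low": d.or_ci[0],
                "or_ci_high": d.or_ci[1],
                "hl_p": d.hl_p,
                "status": "ok",
            }
            for p, bench in cell.benchmarks.items():
                row[f"sr{int(round(p * 100))}"] = bench.rounded_sf
        else:
            row = {
                "site_class": site_class,
                "order": order,
                "status": unavailable[(site_class, order)],
            }
        rows.append(row)
    return pd.DataFrame(rows)
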