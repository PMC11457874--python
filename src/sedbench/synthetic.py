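"""Synthetic monitoring datasets with known generating truth.

Emulates the structure of a wadable-stream bioassessment dataset: three
ecoregion site classes, Strahler orders 1-4, lognormal bankfull widths per
order, percent surface fines decreasing with order and bankfull width, an
occurrence-only biotic index responding to fines with a wedge-shaped
pattern, reference/stress/ambient disturbance labels, and probability-
survey weights. Every event table is generated from a single seed expanded
into per-operation substreams, so tables are bit-identical across calls.

SF is generated on the logit scale around the configured per-order 75th-
percentile line: ``logit(SF/100) = logit(q75(BW)/100) + s*(z - z75)`` with
``z ~ N(0,1)`` and ``z75`` the 0.75 normal quantile, so the conditional
75th percentile of SF among reference events equals the configured line
exactly, and SF is bounded in (0, 100) by construction. Stress and ambient
events shift the same distribution upward on the logit scale. Taxon
presence is independent Bernoulli with logistic occupancy in SF (sensitive
taxa have negative occupancy slopes), which yields the wedge: variance of
the index is high at low fines and its upper bound declines as fines
increase.

The generating truth (quantile lines, per-class reference-FSBI 25th
percentiles, per-cell SF at 50%/75% exceedance probability) is recorded
exactly as the generator uses it: closed-form where available, otherwise
by Monte Carlo from the generating distributions themselves, never by
re-estimating from the emitted sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .config import ORDERS, SITE_CLASSES

Z75 = float(special.ndtri(0.75))  # 0.75 standard-normal quantile

#: Logistic occupancy parameters (intercept at SF=0, slope per % SF) for
#: the taxa in the packaged demonstration score table. Sensitive taxa
#: (high scores) have steep negative slopes; tolerant taxa are flat.
_OCCUPANCY: dict[str, tuple[float, float]] = {
    "Drunella": (1.6, -0.080), "Epeorus": (1.5, -0.085),
    "Rhithrogena": (1.4, -0.080), "Cinygmula": (1.5, -0.075),
    "Yoraperla": (1.3, -0.090), "Megarcys": (1.2, -0.080),
    "Zapada": (1.7, -0.070), "Doroneuria": (1.1, -0.075),
    "Glossosoma": (1.4, -0.070), "Neophylax": (1.2, -0.065),
    "Rhyacophila": (1.0, -0.030), "Micrasema": (0.8, -0.030),
    "Brachycentrus": (0.7, -0.028), "Sweltsa": (0.9, -0.032),
    "Heterlimnius": (0.8, -0.025), "Cleptelmis": (0.6, -0.025),
    "Narpus": (0.6, -0.022), "Optioservus": (0.7, -0.020),
    "Baetis": (1.8, -0.004), "Hydropsyche": (1.2, -0.003),
    "Simulium": (0.8, 0.000), "Sphaerium": (0.2, 0.000),
    "Chironomidae": (2.2, 0.000), "Oligochaeta": (0.9, 0.000),
    "Physa": (0.1, 0.000), "Ostracoda": (0.0, 0.000),
}


@dataclass(frozen=True)
class TaxonSpec:
    """One taxon in the generating pool."""

    name: str
    score: float
    occ_intercept: float
    occ_slope: float


def default_taxon_pool() -> tuple[TaxonSpec, ...]:
    """Pool built from the packaged demonstration score table."""
    from .fsbi import demo_score_table, normalize_taxon

    table = demo_score_table()
    pool = []
    for name, (a, b) in _OCCUPANCY.items():
        key = normalize_taxon(name)
        if key not in table:
            raise RuntimeError(f"occupancy taxon {name!r} missing from demo table")
        pool.append(TaxonSpec(name=name, score=table[key], occ_intercept=a, occ_slope=b))
    return tuple(pool)


#: Default generating 75th-percentile SF lines per order (intercept %,
#: slope % per meter bankfull width); fines decrease with width and order.
DEFAULT_SF_QUANTILE_TRUTH: dict[int, tuple[float, float]] = {
    1: (47.73073, -3.22255),
    2: (41.62932, -2.49803),
    3: (34.97105, -1.24737),
    4: (29.54360, -0.62823),
}


@dataclass
class SimulationConfig:
    """Parameters of the generating process.

    Proportions must each sum to 1; ``sf_quantile_truth`` gives the
    per-order (intercept, slope) of the generating reference 75th-
    percentile SF line; ``sf_noise_scale`` is the within-reach spread on
    the logit scale; ``class_occupancy_shift`` moves every taxon's
    occupancy intercept per site class so the classes differ in index
    richness; ``stress/ambient_logit_shift`` move the SF distribution of
    non-reference events upward.
    """

    n_sites: int = 1000
    class_proportions: tuple[float, float, float] = (0.20, 0.54, 0.26)
    order_proportions: tuple[float, float, float, float] = (0.17, 0.43, 0.30, 0.10)
    bw_log_mean_by_order: tuple[float, float, float, float] = (1.1, 1.6, 2.1, 2.5)
    bw_log_sd: float = 0.35
    sf_quantile_truth: dict = field(
        default_factory=lambda: dict(DEFAULT_SF_QUANTILE_TRUTH)
    )
    sf_noise_scale: float = 0.5
    taxon_pool: tuple = field(default_factory=default_taxon_pool)
    weight_scheme: str = "equal"
    order_extent_shares: tuple[float, float, float, float] = (0.45, 0.30, 0.15, 0.10)
    disturbance_mix: tuple[float, float, float] = (0.10, 0.10, 0.80)  # ref, stress, ambient
    stress_logit_shift: float = 1.6
    ambient_logit_shift: float = 0.8
    class_occupancy_shift: dict = field(
        default_factory=lambda: {"mountains": 0.7, "foothills": 0.0, "ppbv": -1.2}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        for name, props, k in (
            ("class_proportions", self.class_proportions, 3),
            ("order_proportions", self.order_proportions, 4),
            ("disturbance_mix", self.disturbance_mix, 3),
        ):
            props = tuple(float(p) for p in props)
            if len(props) != k or any(p < 0 for p in props):
                raise ValueError(f"{name} must be {k} non-negative fractions")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(props)})")
            setattr(self, name, props)
        if self.sf_noise_scale < 0:
            raise ValueError("sf_noise_scale must be non-negative")
        if not self.taxon_pool:
            raise ValueError("taxon pool is empty")
        for t in self.taxon_pool:
            if t.score < 0:
                raise ValueError(f"negative score for taxon {t.name!r}")
            if t.score > 0 and t.occ_slope > 0:
                raise ValueError(
                    f"sensitive taxon {t.name!r} must have non-positive "
                    f"occupancy SF-slope"
                )
        if self.weight_scheme not in ("equal", "order_stratified"):
            raise ValueError("weight_scheme must be 'equal' or 'order_stratified'")
        missing_orders = set(ORDERS) - set(self.sf_quantile_truth)
        if missing_orders:
            raise ValueError(f"sf_quantile_truth missing orders: {sorted(missing_orders)}")


@dataclass
class SimulationTruth:
    """Generating truth recorded exactly as the generator used it."""

    sf_quantile_lines: dict  # order -> (intercept, slope)
    fsbi_ref_by_class: dict  # site_class -> 25th-percentile reference FSBI
    sr_by_class_order: dict  # (class, order) -> {probability: SF}

    def to_dict(self) -> dict:
        return {
            "sf_quantile_lines": {
                str(o): list(v) for o, v in sorted(self.sf_quantile_lines.items())
            },
            "fsbi_ref_by_class": dict(sorted(self.fsbi_ref_by_class.items())),
            "sr_by_class_order": {
                f"{c}:{o}": {str(p): v for p, v in sorted(d.items())}
                for (c, o), d in sorted(self.sr_by_class_order.items())
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# generating primitives


def _simulate_sf(
    config: SimulationConfig,
    orders: np.ndarray,
    bw: np.ndarray,
    disturbance: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """SF draws; reference events have conditional q75 on the truth line."""
    q75 = np.empty(len(orders))
    for o in ORDERS:
        a, b = config.sf_quantile_truth[o]
        mask = orders == o
        q75[mask] = a + b * bw[mask]
    q75 = np.clip(q75, 1.0, 99.0)
    shift = np.select(
        [disturbance == "stress", disturbance == "ambient"],
        [config.stress_logit_shift, config.ambient_logit_shift],
        default=0.0,
    )
    z = rng.standard_normal(len(orders))
    logit_sf = special.logit(q75 / 100.0) + config.sf_noise_scale * (z - Z75) + shift
    return 100.0 * special.expit(logit_sf)


def _occupancy_probs(
    config: SimulationConfig, site_class: str, sf: np.ndarray
) -> np.ndarray:
    """(n_events, n_taxa) presence probabilities for one site class."""
    shift = config.class_occupancy_shift.get(site_class, 0.0)
    a = np.array([t.occ_intercept for t in config.taxon_pool])
    b = np.array([t.occ_slope for t in config.taxon_pool])
    return special.expit(a[None, :] + shift + b[None, :] * sf[:, None])


def _simulate_fsbi(
    config: SimulationConfig,
    classes: np.ndarray,
    sf: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(fsbi values, presence matrix) via independent Bernoulli occupancy."""
    scores = np.array([t.score for t in config.taxon_pool])
    presence = np.zeros((len(sf), len(scores)), dtype=bool)
    for site_class in SITE_CLASSES:
        mask = classes == site_class
        if not mask.any():
            continue
        probs = _occupancy_probs(config, site_class, sf[mask])
        presence[mask] = rng.random(probs.shape) < probs
    return presence @ scores, presence


def simulate_weights(
    events: pd.DataFrame,
    scheme: str = "equal",
    order_extent_shares: tuple[float, ...] = (0.45, 0.30, 0.15, 0.10),
    total_extent: float = 1000.0,
) -> pd.Series:
    """Survey weights: equal, or order-stratified (extent / sample size).

    Under ``order_stratified`` the weight of an event in stream order *o*
    is the stratum extent divided by the number of sampled events in that
    stratum, so weighted stratum totals reproduce the extent shares.
    """
    if scheme == "equal":
        return pd.Series(1.0, index=events.index, name="weight")
    if scheme != "order_stratified":
        raise ValueError(f"unknown weight scheme: {scheme!r}")
    weights = pd.Series(np.nan, index=events.index, name="weight")
    for o, share in zip(ORDERS, order_extent_shares):
        mask = events["order"] == o
        n = int(mask.sum())
        if n == 0:
            if share > 0:
                raise ValueError(f"empty stratum: no sampled events in order {o}")
            continue
        weights[mask] = share * total_extent / n
    return weights


# ---------------------------------------------------------------------------
# truth computation (from the generating distributions, not the sample)


def _reference_truth(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_ref: int = 8000,
    n_curve: int = 3000,
    sf_grid_step: float = 2.0,
) -> tuple[dict, dict]:
    """Per-class true 25th-percentile reference FSBI and SR50/75 SF values."""
    scores = np.array([t.score for t in config.taxon_pool])
    # reference SF distribution (shared by classes; order mix x BW x noise)
    orders = rng.choice(ORDERS, size=n_ref, p=config.order_proportions)
    mu = np.array(config.bw_log_mean_by_order)[orders - 1]
    bw = np.exp(rng.normal(mu, config.bw_log_sd))
    sf_ref_draws = _simulate_sf(
        config, orders, bw, np.full(n_ref, "reference"), rng
    )

    fsbi_ref: dict[str, float] = {}
    sr: dict[tuple[str, int], dict] = {}
    grid = np.arange(0.0, 100.0 + sf_grid_step, sf_grid_step)
    for site_class in SITE_CLASSES:
        probs = _occupancy_probs(config, site_class, sf_ref_draws)
        fsbi_draws = (rng.random(probs.shape) < probs) @ scores
        f_ref = float(np.percentile(fsbi_draws, 25))
        fsbi_ref[site_class] = f_ref
        # exceedance curve P(FSBI < f_ref | SF) on a grid, then invert
        p_curve = np.empty(len(grid))
        for i, sf_val in enumerate(grid):
            gp = _occupancy_probs(config, site_class, np.full(n_curve, sf_val))
            gf = (rng.random(gp.shape) < gp) @ scores
            p_curve[i] = np.mean(gf < f_ref)
        p_mono = np.maximum.accumulate(p_curve)
        cell = {
            p: float(np.interp(p, p_mono, grid)) for p in (0.50, 0.75)
        }
        for o in ORDERS:
            sr[(site_class, o)] = dict(cell)
    return fsbi_ref, sr


# ---------------------------------------------------------------------------
# public API


def simulate_events(
    config: SimulationConfig,
    compute_truth: bool = True,
) -> tuple[pd.DataFrame, SimulationTruth | None]:
    """Generate one event table (one event per site) plus generating truth.

    Deterministic for a fixed config: the seed is expanded into independent
    substreams for site attributes, fines, taxa, auxiliary indices, and
    truth, so the same config always yields bit-identical tables.

    Returns ``(events, truth)``; ``truth`` is None when
    ``compute_truth=False`` (cheaper, for bulk property simulations).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_site, rng_sf, rng_taxa, rng_aux, rng_truth = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    n = config.n_sites
    classes = rng_site.choice(SITE_CLASSES, size=n, p=config.class_proportions)
    orders = rng_site.choice(ORDERS, size=n, p=config.order_proportions)
    mu = np.array(config.bw_log_mean_by_order)[orders - 1]
    bw = np.exp(rng_site.normal(mu, config.bw_log_sd))
    disturbance = rng_site.choice(
        ["reference", "stress", "ambient"], size=n, p=config.disturbance_mix
    )
    sf = _simulate_sf(config, orders, bw, disturbance, rng_sf)
    fsbi, presence = _simulate_fsbi(config, classes, sf, rng_taxa)

    # auxiliary generalized condition indices, correlated with the index
    smi2 = np.clip(15.0 + 0.22 * fsbi + rng_aux.normal(0, 8.0, n), 0.0, 100.0)
    oe = np.clip(0.35 + 0.0022 * fsbi + rng_aux.normal(0, 0.12, n), 0.0, 1.4)

    events = pd.DataFrame({
        "event_id": [f"S{i:05d}" for i in range(n)],
        "comid": np.arange(1, n + 1),
        "site_class": classes,
        "order": orders.astype(int),
        "bankfull_width_m": bw,
        "disturbance": disturbance,
        "sf": sf,
        "fsbi": fsbi.astype(float),
        "smi2": smi2,
        "oe": oe,
    })
    events["weight"] = simulate_weights(
        events, config.weight_scheme, config.order_extent_shares
    )
    events.attrs["presence"] = presence
    events.attrs["taxon_names"] = [t.name for t in config.taxon_pool]

    truth = None
    if compute_truth:
        fsbi_ref, sr = _reference_truth(config, rng_truth)
        truth = SimulationTruth(
            sf_quantile_lines={o: tuple(config.sf_quantile_truth[o]) for o in ORDERS},
            fsbi_ref_by_class=fsbi_ref,
            sr_by_class_order=sr,
        )
    return events, truth


def taxa_table(events: pd.DataFrame) -> pd.DataFrame:
    """Long occurrence table (``event_id, taxon``) from a simulated table."""
    presence = events.attrs.get("presence")
    names = events.attrs.get("taxon_names")
    if presence is None or names is None:
        raise ValueError("events table lacks simulated presence data")
    rows = []
    for i, event_id in enumerate(events["event_id"]):
        for j, name in enumerate(names):
            if presence[i, j]:
                rows.append((event_id, name))
    return pd.DataFrame(rows, columns=["event_id", "taxon"])


#: Fixed distribution of non-fines particles over the 10 coarser classes.
_COARSE_PROFILE = np.array(
    [0.18, 0.20, 0.18, 0.14, 0.10, 0.08, 0.05, 0.04, 0.02, 0.01]
)


def simulate_pebble_counts(
    events: pd.DataFrame,
    particles_per_transect: int = 50,
    seed: int = 0,
    n_transects: int = 3,
) -> pd.DataFrame:
    """Multinomial pebble counts whose expected fines fraction is SF/100.

    Each event gets *n_transects* transects of *particles_per_transect*
    particles over the 11 default size classes; the finest-class cell
    probability is the event's SF/100 and the remainder follows a fixed
    coarse profile.
    """
    from .config import DEFAULT_SIZE_CLASS_EDGES, size_class_labels

    if particles_per_transect < 1:
        raise ValueError("particles_per_transect must be >= 1")
    labels = size_class_labels(DEFAULT_SIZE_CLASS_EDGES)
    rng = np.random.default_rng(seed)
    rows = []
    for _, ev in events.iterrows():
        p0 = float(ev["sf"]) / 100.0
        probs = np.concatenate([[p0], (1.0 - p0) * _COARSE_PROFILE])
        probs = probs / probs.sum()
        for t in range(1, n_transects + 1):
            counts = rng.multinomial(particles_per_transect, probs)
            for label, count in zip(labels, counts):
                rows.append((ev["event_id"], f"T{t}", label, int(count)))
    return pd.DataFrame(rows, columns=["event_id", "transect_id", "size_class", "count"])
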