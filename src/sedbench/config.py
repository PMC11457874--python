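"""Run-level configuration shared by the benchmark pipeline.

All tunable thresholds (quantile tau, percentile ids, minimum cell sizes,
confidence-interval methods, substrate size-class edges, bio-indicator
cutoffs) live in a single frozen :class:`RunConfig` so that every output
artifact can embed the exact configuration it was produced under.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

#: Canonical ecoregion site-class names (lower case).
SITE_CLASSES: tuple[str, ...] = ("mountains", "foothills", "ppbv")

#: Strahler orders in scope (wadable streams).
ORDERS: tuple[int, ...] = (1, 2, 3, 4)

#: Default Wolman pebble-count size-class edges in mm (11 half-open classes
#: [lower, upper); the finest class, below 2.5 mm, is the sand-and-fines
#: fraction). A standard modified-Wentworth series; overridable per run.
DEFAULT_SIZE_CLASS_EDGES: tuple[float, ...] = (
    0.0, 2.5, 6.0, 15.0, 30.0, 60.0, 120.0, 180.0, 300.0, 600.0, 1000.0,
    float("inf"),
)

#: Particles strictly below this diameter count as sand and fines (SF).
FINES_CUTOFF_MM: float = 2.5


def size_class_labels(edges: tuple[float, ...] = DEFAULT_SIZE_CLASS_EDGES) -> tuple[str, ...]:
    """Human-readable labels for the half-open size classes defined by *edges*."""
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi == float("inf"):
            labels.append(f">={lo:g}")
        elif lo == 0.0:
            labels.append(f"<{hi:g}")
        else:
            labels.append(f"{lo:g}-{hi:g}")
    return tuple(labels)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a benchmark-derivation / assessment run.

    Attributes
    ----------
    tau
        Quantile level for the SF reference regression (0.75 = upper bound
        expected among reference streams).
    fsbi_ref_percentile
        Percentile of reference FSBI defining FSBI_ref per site class (25).
    percentile_method
        Sample-percentile rule; ``"linear"`` is the Hyndman–Fan type-7
        interpolation used throughout.
    min_n_quantile, min_n_fsbi_ref, min_n_logistic
        Minimum cell sizes below which a benchmark cell is marked
        unavailable instead of fitted.
    pair_search_max_n
        Largest n for which the quantile regression is solved by exhaustive
        point-pair search (exact LP vertex enumeration with a deterministic
        tie-break); larger fits use iteratively reweighted least squares.
    sr_probabilities
        Response probabilities at which stressor-response benchmarks are
        reported (0.50 -> SR50, 0.75 -> SR75).
    hl_groups
        Number of predicted-probability bins for the Hosmer–Lemeshow test.
    ci_level
        Two-sided confidence level for odds-ratio and relative-risk CIs.
    or_ci_method
        ``"wald"`` (default) or ``"profile"`` likelihood for the slope
        odds-ratio interval.
    subsample_seed
        Seed for the one-site-per-stream-segment (comid) subsampling step;
        required so the "randomly selected" step is reproducible.
    smi2_benchmark
        Multimetric-index cutoff(s); value below the cutoff is poor
        condition. Scalar or per-site-class mapping.
    oe_benchmark
        Observed/expected taxa-ratio cutoff; below it is poor condition.
    size_class_edges
        Pebble-count size-class boundaries in mm (12 ascending edges for
        11 classes).
    min_taxon_occurrences
        Minimum events at which a taxon must occur before a tolerance value
        is derived for it.
    """

    tau: float = 0.75
    fsbi_ref_percentile: float = 25.0
    percentile_method: str = "linear"
    min_n_quantile: int = 10
    min_n_fsbi_ref: int = 10
    min_n_logistic: int = 10
    pair_search_max_n: int = 200
    sr_probabilities: tuple[float, ...] = (0.50, 0.75)
    hl_groups: int = 10
    ci_level: float = 0.95
    or_ci_method: str = "wald"
    rr_ci_method: str = "taylor"
    subsample_seed: int = 0
    smi2_benchmark: Any = field(
        default_factory=lambda: {"mountains": 54.0, "foothills": 53.0, "ppbv": 52.0}
    )
    oe_benchmark: float = 0.63
    size_class_edges: tuple[float, ...] = DEFAULT_SIZE_CLASS_EDGES
    min_taxon_occurrences: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must be in (0,1), got {self.tau}")
        if not 0.0 < self.fsbi_ref_percentile < 100.0:
            raise ValueError("fsbi_ref_percentile must be in (0,100)")
        edges = tuple(float(e) for e in self.size_class_edges)
        if len(edges) != 12:
            raise ValueError("size_class_edges must define 11 classes (12 edges)")
        if any(b <= a for a, b in zip(edges[:-1], edges[1:])):
            raise ValueError("size_class_edges must be strictly ascending")
        object.__setattr__(self, "size_class_edges", edges)
        object.__setattr__(self, "sr_probabilities", tuple(self.sr_probabilities))
        for p in self.sr_probabilities:
            if not 0.0 < p < 1.0:
                raise ValueError("sr_probabilities must lie in (0,1)")
        if self.or_ci_method not in ("wald", "profile"):
            raise ValueError("or_ci_method must be 'wald' or 'profile'")

    # -- serialization -------------------------------------------------

    def smi2_benchmark_for(self, site_class: str) -> float:
        """Resolve the SMI2 cutoff for a site class (scalar or mapping)."""
        if isinstance(self.smi2_benchmark, Mapping):
            return float(self.smi2_benchmark[site_class])
        return float(self.smi2_benchmark)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["size_class_edges"] = [
            "inf" if e == float("inf") else e for e in d["size_class_edges"]
        ]
        d["sr_probabilities"] = list(d["sr_probabilities"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "size_class_edges" in d:
            d["size_class_edges"] = tuple(
                float("inf") if e == "inf" else float(e) for e in d["size_class_edges"]
            )
        if "sr_probabilities" in d:
            d["sr_probabilities"] = tuple(d["sr_probabilities"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable sha256 of the canonical JSON form, embedded in artifacts."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
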