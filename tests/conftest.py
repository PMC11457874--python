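import numpy as np
import pandas as pd
import pytest

import sedbench as sb


@pytest.fixture(scope="session")
def sim():
    """Moderate synthetic dataset with generating truth."""
    config = sb.SimulationConfig(n_sites=2000, seed=42)
    events, truth = sb.simulate_events(config)
    return config, events, truth


@pytest.fixture(scope="session")
def benchset(sim):
    """Benchmark set derived from the session dataset."""
    _, events, _ = sim
    return sb.derive_benchmark_set(events)


@pytest.fixture()
def toy_benchmarks():
    """Hand-built benchmark set: flat SF_ref = 30 for every order, constant
    FSBI_ref = 100 per class; convenient for exact enumeration tests."""
    bs = sb.BenchmarkSet()
    for order in sb.ORDERS:
        bs.quantile_models[order] = sb.QuantileModel(
            order=order, tau=0.75, intercept=30.0, slope=0.0, n=50
        )
    for site_class in sb.SITE_CLASSES:
        bs.fsbi_ref[site_class] = 100.0
    return bs


def make_events(sf, fsbi, site_class="mountains", order=1, bw=5.0, **extra):
    """Minimal valid event table from parallel value lists."""
    n = len(sf)
    df = pd.DataFrame({
        "event_id": [f"E{i:03d}" for i in range(n)],
        "site_class": site_class if isinstance(site_class, (list, np.ndarray, pd.Series)) else [site_class] * n,
        "order": order if isinstance(order, (list, np.ndarray, pd.Series)) else [order] * n,
        "bankfull_width_m": bw if isinstance(bw, (list, np.ndarray, pd.Series)) else [bw] * n,
        "sf": sf,
        "fsbi": fsbi,
    })
    for key, val in extra.items():
        df[key] = val
    return df
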