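"""Quantile-regression reference benchmarks and benchmark-set derivation."""

import math

import numpy as np
import pandas as pd
import pytest

import sedbench as sb
from sedbench.reference import pinball_loss, subsample_one_per_segment

from conftest import make_events


def brute_force_min_loss(bw, sf, tau):
    """Independent oracle: minimum pinball loss over all point-pair lines."""
    best = math.inf
    n = len(bw)
    for i in range(n):
        for j in range(i + 1, n):
            if bw[i] == bw[j]:
                continue
            slope = (sf[j] - sf[i]) / (bw[j] - bw[i])
            intercept = sf[i] - slope * bw[i]
            loss = sum(
                tau * r if r >= 0 else (tau - 1) * r
                for r in (sf - intercept - slope * bw)
            )
            best = min(best, loss)
    return best


class TestFitQuantileModel:
    @pytest.mark.parametrize("tau", [0.25, 0.5, 0.75])
    def test_zero_loss_line_recovered(self, tau):
        bw = np.array([1.0, 2.0, 4.0, 5.0, 8.0, 10.0])
        sf = 40.0 - 2.0 * bw
        m = sb.fit_sf_quantile_model(bw, sf, tau=tau, min_n=2)
        assert m.intercept == pytest.approx(40.0)
        assert m.slope == pytest.approx(-2.0)

    def test_median_fit_on_symmetric_data(self):
        """tau=0.5 on data symmetric about a line recovers that line."""
        bw = np.array([1.0, 1.0, 3.0, 3.0, 5.0, 5.0, 7.0, 7.0, 2.0, 6.0])
        sf = 20.0 + 1.5 * bw + np.array([-2, 2, -2, 2, -2, 2, -2, 2, 0, 0.0])
        m = sb.fit_sf_quantile_model(bw, sf, tau=0.5, min_n=2)
        assert m.intercept == pytest.approx(20.0)
        assert m.slope == pytest.approx(1.5)

    def test_matches_pair_enumeration_oracle_small_instance(self):
        rng = np.random.default_rng(3)
        bw = rng.uniform(1, 15, size=8)
        sf = rng.uniform(0, 80, size=8)
        m = sb.fit_sf_quantile_model(bw, sf, tau=0.75, min_n=2)
        fitted_loss = pinball_loss(sf - m.intercept - m.slope * bw, 0.75)
        assert fitted_loss == pytest.approx(
            brute_force_min_loss(bw, sf, 0.75), abs=1e-9
        )

    def test_large_n_irls_path_agrees_with_lp(self):
        """Above the pair-search cutoff the IRLS fit attains near-LP loss."""
        from scipy.optimize import linprog

        rng = np.random.default_rng(5)
        n, tau = 300, 0.75
        bw = rng.uniform(1, 20, n)
        sf = np.clip(45 - 2.5 * bw + rng.normal(0, 8, n), 0, 100)
        m = sb.fit_sf_quantile_model(bw, sf, tau=tau, pair_search_max_n=200)
        # LP: min tau*sum(u) + (1-tau)*sum(v) s.t. a + b*bw + u - v = sf
        A_eq = np.hstack([
            np.ones((n, 1)), bw[:, None], np.eye(n), -np.eye(n)
        ])
        c = np.concatenate([[0, 0], tau * np.ones(n), (1 - tau) * np.ones(n)])
        res = linprog(
            c, A_eq=A_eq, b_eq=sf,
            bounds=[(None, None)] * 2 + [(0, None)] * (2 * n),
            method="highs",
        )
        fitted_loss = pinball_loss(sf - m.intercept - m.slope * bw, tau)
        assert fitted_loss == pytest.approx(res.fun, rel=1e-4)

    def test_degenerate_bw_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sb.fit_sf_quantile_model([2.0] * 12, np.arange(12.0), min_n=2)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="below minimum"):
            sb.fit_sf_quantile_model([1, 2, 3], [1, 2, 3], min_n=10)

    def test_coverage_band(self):
        """For tau=0.75 the share of points on/below the fitted line lies in
        the LP optimality band [ceil(n*tau)-2, floor(n*tau)+2]."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = 60
            bw = rng.uniform(1, 15, n)
            sf = np.clip(45 - 2 * bw + rng.normal(0, 10, n), 0, 100)
            m = sb.fit_sf_quantile_model(bw, sf, tau=0.75)
            resid = sf - m.intercept - m.slope * bw
            n_below = int(np.sum(resid <= 0))
            assert math.ceil(n * 0.75) - 2 <= n_below <= math.floor(n * 0.75) + 2


class TestPredictSfRef:
    model = sb.QuantileModel(order=1, tau=0.75, intercept=47.73073,
                             slope=-3.22255, n=294)

    def test_printed_equation_at_bw5(self):
        assert sb.predict_sf_ref(self.model, 5.0) == pytest.approx(31.618, abs=1e-3)

    def test_clipped_to_zero_at_large_bw(self):
        # raw value -16.72 at BW=20 is clipped to 0
        assert sb.predict_sf_ref(self.model, 20.0) == 0.0

    def test_flat_model(self):
        flat = sb.QuantileModel(order=2, tau=0.75, intercept=25.0, slope=0.0, n=20)
        assert sb.predict_sf_ref(flat, 3.0) == 25.0
        assert sb.predict_sf_ref(flat, 17.0) == 25.0

    def test_monotone_non_increasing_for_negative_slope(self):
        widths = np.linspace(0.5, 30, 50)
        preds = sb.predict_sf_ref(self.model, widths)
        assert (np.diff(preds) <= 1e-12).all()

    def test_nonpositive_bw_rejected(self):
        with pytest.raises(ValueError):
            sb.predict_sf_ref(self.model, 0.0)


class TestComputeFsbiRef:
    def test_constant_values(self):
        assert sb.compute_fsbi_ref([100, 100, 100], min_n=1) == 100.0

    def test_type7_interpolation(self):
        assert sb.compute_fsbi_ref([0, 40, 80, 120], min_n=1) == pytest.approx(30.0)

    def test_single_value(self):
        assert sb.compute_fsbi_ref([77.0], min_n=1) == 77.0

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="below minimum"):
            sb.compute_fsbi_ref([1, 2, 3], min_n=10)


class TestDeriveBenchmarkSet:
    def test_segment_subsampling_keeps_one_event(self):
        events = make_events(
            sf=[10.0, 20.0], fsbi=[100.0, 120.0],
            disturbance=["reference", "reference"], comid=[7, 7],
        )
        rng = np.random.default_rng(0)
        out = subsample_one_per_segment(events, rng)
        assert len(out) == 1

    def test_subsampling_seeded_and_reproducible(self):
        events = make_events(
            sf=np.arange(10.0), fsbi=np.arange(10.0) + 50,
            disturbance=["reference"] * 10, comid=[1, 1, 1, 2, 2, 3, 3, 3, 3, 4],
        )
        picks = [
            set(subsample_one_per_segment(events, np.random.default_rng(5))["event_id"])
            for _ in range(2)
        ]
        assert picks[0] == picks[1]
        assert len(picks[0]) == 4

    def test_empty_reference_set_marks_all_unavailable(self):
        events = make_events(
            sf=[10.0] * 12, fsbi=[50.0] * 12, disturbance=["ambient"] * 12
        )
        bs = sb.derive_benchmark_set(events)
        assert not bs.quantile_models
        assert not bs.fsbi_ref
        assert any(k.startswith("sf_quantile:") for k in bs.unavailable)
        assert any(k.startswith("fsbi_ref:") for k in bs.unavailable)

    def test_slope_sign_recovered_on_stratified_reference_data(self):
        """With >=200 reference events per order, fitted slopes are negative
        whenever the generating quantile relationship decreases with width."""
        config = sb.SimulationConfig(
            n_sites=1600, seed=21,
            order_proportions=(0.25, 0.25, 0.25, 0.25),
            disturbance_mix=(0.6, 0.1, 0.3),
        )
        events, truth = sb.simulate_events(config, compute_truth=False)
        bs = sb.derive_benchmark_set(events)
        for order, model in bs.quantile_models.items():
            assert model.n >= 200
            assert sb.SimulationConfig().sf_quantile_truth[order][1] < 0
            assert model.slope < 0

    def test_roundtrip_json(self, benchset, tmp_path):
        path = tmp_path / "bench.json"
        benchset.to_json(path)
        back = sb.BenchmarkSet.from_json(path)
        assert back.fsbi_ref == benchset.fsbi_ref
        for order in benchset.quantile_models:
            assert back.quantile_models[order] == benchset.quantile_models[order]
        assert set(back.sr_cells) == set(benchset.sr_cells)
        key = next(iter(benchset.sr_cells))
        assert back.sr_cells[key].model == benchset.sr_cells[key].model
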