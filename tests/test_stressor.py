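"""Logistic stressor-response fitting, diagnostics and benchmark inversion."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

import sedbench as sb
from sedbench.stressor import diagnostics, log_likelihood

from conftest import make_events


def simulate_logistic(beta0, beta1, n, rng, sf_low=0.0, sf_high=100.0):
    sf = rng.uniform(sf_low, sf_high, n)
    y = (rng.random(n) < special.expit(beta0 + beta1 * sf)).astype(int)
    return sf, y


class TestMakeResponse:
    @pytest.mark.parametrize(
        "fsbi, expected", [(139.0, 1), (140.0, 0), (300.0, 0)]
    )
    def test_strictly_less_than_reference(self, fsbi, expected):
        events = make_events(sf=[10.0], fsbi=[fsbi])
        y = sb.make_response(events, {"mountains": 140.0})
        assert y.iloc[0] == expected

    def test_missing_class_reference_is_error(self):
        events = make_events(sf=[10.0], fsbi=[50.0], site_class="ppbv")
        with pytest.raises(KeyError):
            sb.make_response(events, {"mountains": 140.0})


class TestFitLogistic:
    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(17)
        sf, y = simulate_logistic(-2.1, 0.06, 2000, rng)
        m = sb.fit_logistic(sf, y)
        assert abs(m.beta0 - (-2.1)) < 3 * m.se0
        assert abs(m.beta1 - 0.06) < 3 * m.se1

    def test_null_data_gives_flat_slope_and_insignificant_chi_square(self):
        """With labels independent of SF the slope is ~0 and the model
        chi-square is insignificant in >=90% of replicates."""
        rng = np.random.default_rng(23)
        ok = 0
        reps = 40
        for _ in range(reps):
            sf = rng.uniform(0, 100, 2000)
            y = (rng.random(2000) < 0.5).astype(int)
            m = sb.fit_logistic(sf, y)
            chi2_p = stats.chi2.sf(m.null_deviance - m.residual_deviance, 1)
            if abs(m.beta1) < 0.01 and chi2_p > 0.05:
                ok += 1
        assert ok / reps >= 0.90

    def test_complete_separation_is_explicit_error(self):
        with pytest.raises(sb.SeparationError, match="separation"):
            sb.fit_logistic([10.0, 90.0], [0, 1])

    def test_single_label_data_rejected(self):
        with pytest.raises(ValueError, match="single-label"):
            sb.fit_logistic(np.arange(20.0), np.zeros(20, int))

    def test_deviance_ordering_invariant(self):
        rng = np.random.default_rng(2)
        sf, y = simulate_logistic(-1.0, 0.04, 300, rng)
        m = sb.fit_logistic(sf, y)
        assert m.residual_deviance <= m.null_deviance + 1e-8

    def test_loglikelihood_matches_numeric_optimizer(self):
        """IRLS fit reaches the same maximum as a direct numeric optimizer."""
        rng = np.random.default_rng(31)
        for _ in range(10):
            sf, y = simulate_logistic(
                rng.uniform(-3, 0), rng.uniform(0.02, 0.1), 60, rng
            )
            if len(np.unique(y)) < 2:
                continue
            try:
                m = sb.fit_logistic(sf, y, min_n=10)
            except sb.SeparationError:
                continue
            res = optimize.minimize(
                lambda b: -log_likelihood(b[0], b[1], sf, y),
                x0=[0.0, 0.0], method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            assert log_likelihood(m.beta0, m.beta1, sf, y) == pytest.approx(
                -res.fun, abs=1e-3
            )


class TestPredictAndInvert:
    model = sb.LogisticModel("foothills", 1, -2.1, 0.06, 0.43, 0.01,
                             100.0, 50.0, 503)

    def test_probability_half_at_inflection(self):
        assert sb.predict_probability(self.model, 2.1 / 0.06) == pytest.approx(0.5)

    def test_closed_form_probability_at_zero_sf(self):
        assert sb.predict_probability(self.model, 0.0) == pytest.approx(0.1091, abs=1e-4)

    def test_flat_model_constant_probability(self):
        flat = sb.LogisticModel("m", 1, -2.1, 0.0, 0.1, 0.1, 10.0, 10.0, 50)
        p = special.expit(-2.1)
        assert sb.predict_probability(flat, 0.0) == pytest.approx(p)
        assert sb.predict_probability(flat, 99.0) == pytest.approx(p)

    def test_sr50_from_printed_foothills_first_order_coefficients(self):
        bench = sb.invert_logistic(self.model, 0.5)
        assert bench.sf_value == pytest.approx(35.0)
        assert bench.rounded_sf == 35

    def test_sr75_from_printed_mountains_second_order_coefficients(self):
        # intercept magnitude 2.18 interpreted with a negative sign
        model = sb.LogisticModel("mountains", 2, -2.18, 0.06, 0.13, 0.005,
                                 100.0, 50.0, 392)
        bench = sb.invert_logistic(model, 0.75)
        assert bench.sf_value == pytest.approx(54.64, abs=0.01)
        assert bench.rounded_sf == 55

    def test_zero_intercept_inverts_to_zero(self):
        model = sb.LogisticModel("m", 1, 0.0, 0.08, 0.1, 0.01, 10.0, 10.0, 50)
        assert sb.invert_logistic(model, 0.5).sf_value == pytest.approx(0.0)

    def test_nonpositive_slope_is_error(self):
        model = sb.LogisticModel("m", 1, -2.0, -0.01, 0.1, 0.01, 10.0, 10.0, 50)
        with pytest.raises(ValueError, match="non-positive"):
            sb.invert_logistic(model, 0.5)

    def test_round_trip_identity(self):
        for p in np.arange(0.1, 0.95, 0.1):
            bench = sb.invert_logistic(self.model, p)
            assert sb.predict_probability(self.model, bench.sf_value) == pytest.approx(
                p, abs=1e-10
            )

    def test_sr75_exceeds_sr50_for_positive_slope(self):
        assert (
            sb.invert_logistic(self.model, 0.75).sf_value
            > sb.invert_logistic(self.model, 0.5).sf_value
        )


class TestHosmerLemeshow:
    def test_matches_hand_computation_four_groups(self):
        """Manual evaluation of the HL formula on a fixed 20-point set."""
        model = sb.LogisticModel("m", 1, -2.0, 0.2, 0.1, 0.01, 30.0, 20.0, 20)
        sf = np.arange(20.0)
        y = np.array([0, 0, 0, 1, 0, 0, 1, 0, 1, 0,
                      1, 0, 1, 1, 0, 1, 1, 1, 1, 1])
        p = special.expit(-2.0 + 0.2 * sf)
        stat_manual = 0.0
        for lo in (0, 5, 10, 15):  # sf already sorted by predicted p
            O = y[lo:lo + 5].sum()
            E = p[lo:lo + 5].sum()
            pbar = E / 5
            stat_manual += (O - E) ** 2 / (5 * pbar * (1 - pbar))
        stat, pval, groups = sb.hosmer_lemeshow(model, sf, y, groups=4)
        assert groups == 4
        assert stat == pytest.approx(stat_manual, abs=1e-12)
        assert pval == pytest.approx(float(stats.chi2.sf(stat_manual, 2)), abs=1e-12)

    def test_two_groups_insufficient_df(self):
        model = sb.LogisticModel("m", 1, -2.0, 0.2, 0.1, 0.01, 30.0, 20.0, 20)
        with pytest.raises(ValueError, match="group"):
            sb.hosmer_lemeshow(model, np.arange(20.0), np.tile([0, 1], 10), groups=2)

    def test_tied_predictions_share_a_bin(self):
        """Constant SF gives identical predictions; the bins collapse and the
        test reports insufficient df rather than splitting ties arbitrarily."""
        model = sb.LogisticModel("m", 1, -1.0, 0.02, 0.1, 0.01, 30.0, 20.0, 40)
        sf = np.full(40, 25.0)
        y = np.tile([0, 1], 20)
        with pytest.raises(ValueError, match="insufficient"):
            sb.hosmer_lemeshow(model, sf, y, groups=10)

    def test_calibration_under_the_true_model(self):
        """When data really come from the fitted logistic family the HL
        rejection rate at alpha=0.05 stays near nominal (2-10%)."""
        rng = np.random.default_rng(41)
        reps, rejections = 120, 0
        for _ in range(reps):
            sf, y = simulate_logistic(-2.0, 0.05, 2500, rng)
            m = sb.fit_logistic(sf, y)
            _, pval, _ = sb.hosmer_lemeshow(m, sf, y, groups=10)
            rejections += pval < 0.05
        assert 0.02 <= rejections / reps <= 0.10


class TestOddsRatioCI:
    def test_wald_closed_form(self):
        m = sb.LogisticModel("m", 1, -2.0, 0.06, 0.3, 0.01, 30.0, 20.0, 100)
        low, high = sb.odds_ratio_ci(m)
        assert low == pytest.approx(1.0412, abs=1e-4)
        assert high == pytest.approx(1.0829, abs=1e-4)

    def test_degenerate_se(self):
        m = sb.LogisticModel("m", 1, -2.0, 0.06, 0.3, 0.0, 30.0, 20.0, 100)
        assert sb.odds_ratio_ci(m) == pytest.approx((np.exp(0.06),) * 2)

    def test_zero_slope_interval_straddles_one(self):
        m = sb.LogisticModel("m", 1, -2.0, 0.0, 0.3, 0.01, 30.0, 30.0, 100)
        low, high = sb.odds_ratio_ci(m)
        assert low < 1.0 < high

    def test_profile_close_to_wald_on_well_behaved_data(self):
        rng = np.random.default_rng(3)
        sf, y = simulate_logistic(-2.0, 0.05, 1500, rng)
        m = sb.fit_logistic(sf, y)
        wald = sb.odds_ratio_ci(m, method="wald")
        prof = sb.odds_ratio_ci(m, method="profile", sf=sf, labels=y)
        assert prof[0] == pytest.approx(wald[0], rel=0.01)
        assert prof[1] == pytest.approx(wald[1], rel=0.01)


class TestDeriveSrBenchmarks:
    def test_one_sided_cell_marked_unavailable(self):
        rng = np.random.default_rng(4)
        events = make_events(
            sf=rng.uniform(0, 100, 30), fsbi=np.full(30, 300.0),
        )
        cells, unavailable = sb.derive_sr_benchmarks(events, {"mountains": 140.0})
        assert ("mountains", 1) not in cells
        assert "single-label" in unavailable[("mountains", 1)]

    def test_chi_square_is_deviance_difference(self, benchset):
        for cell in benchset.sr_cells.values():
            m, d = cell.model, cell.diagnostics
            assert d.model_chi_square == pytest.approx(
                m.null_deviance - m.residual_deviance
            )
            assert d.odds_ratio == pytest.approx(np.exp(m.beta1))

    def test_batch_never_raises_on_sparse_classes(self):
        events = make_events(
            sf=[10.0, 20.0, 30.0], fsbi=[50.0, 60.0, 70.0], site_class="ppbv"
        )
        cells, unavailable = sb.derive_sr_benchmarks(events, {"ppbv": 65.0})
        assert not cells
        assert len(unavailable) == 12
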