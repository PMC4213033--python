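"""Growth-curve fitting, AICc ranking, classification, and K/r extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invasionfit import (
    AbundanceTimeSeries,
    classify_trajectory,
    compare_models,
    compute_aicc,
    extract_carrying_capacity,
    extract_growth_rate,
    filter_sites,
    fit_growth_model,
)
from invasionfit.growth import GrowthModelFit, fit_all_families


def _ts(counts, years=None, site_id="x"):
    counts = np.asarray(counts, dtype=float)
    if years is None:
        years = np.arange(counts.size)
    return AbundanceTimeSeries(site_id=site_id, years=years, counts=counts)


def _fake_fit(family, aicc, params=None, t_window=(0.0, 10.0)):
    return GrowthModelFit(
        family=family, params=params or {}, sigma=1.0, loglik=0.0, n_obs=12,
        k_params={"exponential": 3, "quadratic": 4, "logistic": 4}[family],
        aicc=aicc, converged=True, t_window=t_window,
    )


class TestFitting:
    def test_noiseless_quadratic_recovered_exactly(self):
        t = np.arange(11, dtype=float)
        y = -((t - 5.0) ** 2) + 25.0
        fit = fit_growth_model(_ts(y), "quadratic")
        assert fit.converged
        np.testing.assert_allclose(
            [fit.params["a"], fit.params["b"], fit.params["c"]],
            [-1.0, 10.0, 0.0], atol=1e-8,
        )

    def test_noiseless_exponential_rate_recovered(self):
        t = np.arange(10, dtype=float)
        fit = fit_growth_model(_ts(2.0 * np.exp(0.3 * t)), "exponential")
        assert fit.converged
        assert fit.params["r_exp"] == pytest.approx(0.3, abs=1e-6)
        assert fit.params["N0"] == pytest.approx(2.0, abs=1e-5)

    def test_noiseless_logistic_asymptote_recovered(self):
        t = np.arange(20, dtype=float)
        y = 100.0 / (1.0 + np.exp(-0.5 * (t - 10.0)))
        fit = fit_growth_model(_ts(y), "logistic")
        assert fit.converged
        assert fit.params["K_asym"] == pytest.approx(100.0, abs=1e-3)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            fit_growth_model(_ts(np.arange(1, 9)), "gompertz")

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_growth_model(_ts([1, 2, 3, 4]), "quadratic")

    def test_constant_counts_logistic_nonconvergent_without_raising(self):
        fit = fit_growth_model(_ts(np.full(10, 7.0)), "logistic")
        assert not fit.converged
        assert not math.isfinite(fit.aicc)

    def test_exponential_like_data_drives_logistic_to_bound(self):
        # pure exponential growth has no interior asymptote: the logistic
        # fit should end at a bound and be declared non-convergent
        t = np.arange(12, dtype=float)
        fit = fit_growth_model(_ts(2.0 * np.exp(0.5 * t)), "logistic")
        assert not fit.converged


class TestAicc:
    def test_hand_value(self):
        assert compute_aicc(-10.0, 3, 10) == pytest.approx(30.0, abs=1e-12)

    def test_large_n_limit_is_aic(self):
        assert compute_aicc(-10.0, 3, 10**6) == pytest.approx(26.0, abs=1e-4)

    def test_undefined_below_minimum_n(self):
        assert math.isinf(compute_aicc(-10.0, 3, 4))

    @given(st.integers(min_value=6, max_value=500))
    @settings(derandomize=True, max_examples=40)
    def test_monotone_decreasing_in_n(self, n):
        assert compute_aicc(-10.0, 3, n + 1) < compute_aicc(-10.0, 3, n)


class TestComparison:
    def test_delta_arithmetic(self):
        comp = compare_models([
            _fake_fit("exponential", 100.0, {"r_exp": 0.2}),
            _fake_fit("quadratic", 103.0, {"a": -1, "b": 5, "c": 0}),
            _fake_fit("logistic", 101.0, {"r_log": 0.3}),
        ])
        assert comp.best_family == "exponential"
        assert comp.delta_aicc == pytest.approx(
            {"exponential": 0.0, "quadratic": 3.0, "logistic": 1.0})

    def test_single_converged_fit_is_best(self):
        bad = _fake_fit("logistic", math.inf)
        bad.converged = False
        comp = compare_models([_fake_fit("quadratic", 50.0, {"a": -1, "b": 5, "c": 0}), bad])
        assert comp.best_family == "quadratic"
        assert comp.delta_aicc["quadratic"] == 0.0

    def test_exact_tie_goes_to_fewer_parameters(self):
        comp = compare_models([
            _fake_fit("quadratic", 100.0, {"a": 1, "b": 1, "c": 0}),
            _fake_fit("exponential", 100.0, {"r_exp": 0.1}),
        ])
        assert comp.best_family == "exponential"

    def test_no_converged_fits_unresolved(self):
        bad = _fake_fit("logistic", math.inf)
        bad.converged = False
        comp = compare_models([bad])
        assert comp.label == "unresolved"
        assert comp.best_family is None


class TestClassification:
    def test_negative_exponential_is_decreasing(self):
        comp = compare_models([_fake_fit("exponential", 10.0, {"r_exp": -0.2})])
        assert classify_trajectory(comp) == "decreasing"

    def test_positive_logistic_keeps_label(self):
        comp = compare_models(
            [_fake_fit("logistic", 10.0, {"K_asym": 50, "r_log": 0.4, "t_mid": 5})])
        assert classify_trajectory(comp) == "logistic"

    def test_quadratic_decreasing_throughout_window(self):
        # vertex before the first observation, negative leading coefficient:
        # derivative 2at + b < 0 across the window
        comp = compare_models(
            [_fake_fit("quadratic", 10.0, {"a": -1.0, "b": -2.0, "c": 100.0},
                       t_window=(0.0, 10.0))])
        assert classify_trajectory(comp) == "decreasing"

    def test_quadratic_with_interior_peak_is_quadratic(self):
        comp = compare_models(
            [_fake_fit("quadratic", 10.0, {"a": -1.0, "b": 10.0, "c": 0.0},
                       t_window=(0.0, 10.0))])
        assert classify_trajectory(comp) == "quadratic"


class TestCarryingCapacity:
    def test_quadratic_vertex_value(self):
        comp = compare_models(
            [_fake_fit("quadratic", 10.0, {"a": -1.0, "b": 10.0, "c": 0.0})])
        K, source, flags = extract_carrying_capacity(comp)
        assert K == pytest.approx(25.0, abs=1e-12)
        assert source == "quadratic_vertex"
        assert flags == []

    def test_logistic_asymptote_passthrough(self):
        comp = compare_models(
            [_fake_fit("logistic", 10.0, {"K_asym": 100.0, "r_log": 0.5, "t_mid": 5})])
        K, source, _ = extract_carrying_capacity(comp)
        assert K == 100.0
        assert source == "logistic_asymptote"

    def test_exponential_best_takes_better_supported_alternative(self):
        comp = compare_models([
            _fake_fit("exponential", 100.0, {"r_exp": 0.2}),
            _fake_fit("logistic", 101.5, {"K_asym": 80.0, "r_log": 0.5, "t_mid": 5}),
            _fake_fit("quadratic", 101.8, {"a": -1.0, "b": 10.0, "c": 0.0}),
        ])
        K, source, _ = extract_carrying_capacity(comp)
        assert source == "logistic_asymptote"
        assert K == 80.0

    def test_exponential_best_without_support_yields_no_k(self):
        comp = compare_models([
            _fake_fit("exponential", 100.0, {"r_exp": 0.2}),
            _fake_fit("logistic", 103.0, {"K_asym": 80.0, "r_log": 0.5, "t_mid": 5}),
        ])
        K, source, _ = extract_carrying_capacity(comp)
        assert K is None and source is None

    def test_convex_quadratic_has_no_vertex_maximum(self):
        comp = compare_models(
            [_fake_fit("quadratic", 10.0, {"a": 1.0, "b": -2.0, "c": 5.0})])
        K, _, flags = extract_carrying_capacity(comp)
        assert K is None
        assert "no_interior_maximum" in flags

    def test_vertex_outside_window_flagged(self):
        comp = compare_models(
            [_fake_fit("quadratic", 10.0, {"a": -1.0, "b": 30.0, "c": 0.0},
                       t_window=(0.0, 10.0))])
        K, _, flags = extract_carrying_capacity(comp)
        assert K is not None
        assert "vertex_outside_window" in flags

    def test_vertex_matches_brute_force_grid_maximum(self, rng):
        for _ in range(50):
            a = -rng.uniform(0.1, 3.0)
            b = rng.uniform(-5, 25)
            c = rng.uniform(0, 50)
            comp = compare_models(
                [_fake_fit("quadratic", 10.0, {"a": a, "b": b, "c": c},
                           t_window=(-50.0, 50.0))])
            K, _, _ = extract_carrying_capacity(comp)
            grid = np.linspace(-50, 50, 2_000_001)
            assert K == pytest.approx(
                np.max(a * grid**2 + b * grid + c), abs=1e-6)


class TestGrowthRate:
    def test_exact_exponential_slope(self):
        t = np.arange(10, dtype=float)
        ts = _ts(2.0 * np.exp(0.3 * t))
        comp = compare_models(fit_all_families(ts))
        r, flags = extract_growth_rate(ts, comp)
        assert r == pytest.approx(0.3, abs=1e-10)
        assert flags == []

    def test_threshold_is_strict(self):
        ts = _ts(2.0 * np.exp(0.3 * np.arange(10.0)))
        comp = compare_models([
            _fake_fit("exponential", 102.0, {"r_exp": 0.3}),
            _fake_fit("quadratic", 100.0, {"a": -1, "b": 5, "c": 0}),
        ])
        r, _ = extract_growth_rate(ts, comp)  # exponential delta = 2.0, not < 2
        assert r is None

    def test_constant_counts_give_zero_rate(self):
        ts = _ts(np.full(10, 10.0))
        comp = compare_models(fit_all_families(ts))
        assert comp.best_family == "exponential"  # tie broken to fewer params
        r, _ = extract_growth_rate(ts, comp)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_leading_zeros_dropped(self):
        counts = np.concatenate([[0.0, 0.0], 2.0 * np.exp(0.3 * np.arange(8.0))])
        ts = _ts(counts)
        comp = compare_models([_fake_fit("exponential", 10.0, {"r_exp": 0.3})])
        r, _ = extract_growth_rate(ts, comp)
        assert r == pytest.approx(0.3, abs=0.05)


class TestFiltering:
    def test_seven_years_excluded_eight_retained(self):
        short = _ts(np.arange(1.0, 8.0), site_id="short")
        exact = _ts(np.arange(1.0, 9.0), site_id="exact")
        res = filter_sites([short, exact], comparisons={}, min_years=8)
        assert res.exclusions["short"] == "too_few_years"
        assert "exact" in res.eligible

    def test_decreasing_sites_listed_exactly(self):
        series, comps = [], {}
        for i in range(20):
            sid = f"s{i:02d}"
            if i < 5:
                ts = _ts(100.0 * np.exp(-0.2 * np.arange(10.0)), site_id=sid)
            else:
                ts = _ts(2.0 * np.exp(0.3 * np.arange(10.0)), site_id=sid)
            series.append(ts)
            comps[sid] = compare_models(fit_all_families(ts))
        res = filter_sites(series, comps, min_years=8)
        dec = {s for s, v in res.exclusions.items() if v == "discarded_decreasing"}
        assert dec == {f"s{i:02d}" for i in range(5)}
        assert len(res.eligible) == 15

    def test_labels_partition_all_sites(self):
        series = [
            _ts(np.arange(1.0, 8.0), site_id="a"),
            _ts(2.0 * np.exp(0.3 * np.arange(10.0)), site_id="b"),
            _ts(100.0 * np.exp(-0.2 * np.arange(10.0)), site_id="c"),
        ]
        comps = {ts.site_id: compare_models(fit_all_families(ts))
                 for ts in series if len(ts) >= 8}
        res = filter_sites(series, comps, min_years=8)
        assert len(res.eligible) + len(res.exclusions) == len(series)
        assert res.counts["eligible"] == 1

    def test_empty_dataset_is_empty_result(self):
        res = filter_sites([], {}, min_years=8)
        assert res.eligible == [] and res.exclusions == {}
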