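"""Mixture decomposition: mode detection, fitting, model selection, metrics."""

import itertools
import math

import numpy as np
import pytest

from starchgran import (
    DiameterGrid,
    MixtureParams,
    PopulationSpec,
    derive_metrics,
    detect_modes,
    expected_volume_density,
    fit_one_component,
    fit_two_component,
    make_preset,
    number_to_volume,
    percent_change,
    sample_binned_counts,
    select_model,
)
from starchgran.decompose import FitResult, mixture_bin_percent

WT_TRUTH = MixtureParams(
    w_B=0.40, mu_A=19.0, sigma_A=3.5,
    mlog_B=math.log(6.0) - 0.35**2 / 2, slog_B=0.35,
)


def analytic_density(params, grid=None, **spec_kw):
    spec = PopulationSpec(params=params, grid=grid or DiameterGrid.log_spaced(2, 60, 300),
                          **spec_kw)
    return expected_volume_density(spec)


class TestDetectModes:
    def test_wt_preset_is_bimodal_with_a_peak_near_19(self, wt_expected):
        modes, valley = detect_modes(wt_expected)
        assert len(modes) == 2
        mids = wt_expected.grid.midpoints
        a_mode = modes[-1].diameter
        bin_width_at_19 = np.diff(mids)[np.searchsorted(mids, 19.0)]
        assert abs(a_mode - 19.0) <= bin_width_at_19
        assert modes[0].diameter < valley < modes[1].diameter

    def test_single_normal_has_one_mode_and_no_valley(self):
        d = analytic_density(MixtureParams(w_B=0.0, mu_A=14.0, sigma_A=3.5))
        modes, valley = detect_modes(d)
        assert len(modes) == 1
        assert valley is None

    def test_low_prominence_peak_suppressed(self):
        d = analytic_density(MixtureParams(
            w_B=0.005, mu_A=19.0, sigma_A=3.5,
            mlog_B=math.log(6.0), slog_B=0.35))
        modes, _ = detect_modes(d, prominence_frac=0.05)
        assert len(modes) == 1

    def test_too_few_bins_rejected(self):
        d = analytic_density(MixtureParams(w_B=0.0, mu_A=14.0, sigma_A=3.5),
                             grid=DiameterGrid.log_spaced(2, 60, 8))
        with pytest.raises(ValueError, match="bins"):
            detect_modes(d)


class TestTwoComponentFit:
    def test_noiseless_recovery_within_point1_percent(self, wt_expected):
        fit = fit_two_component(wt_expected)
        assert fit.converged
        assert fit.rss < 1e-8
        for name in ("w_B", "mu_A", "sigma_A", "mlog_B", "slog_B"):
            est, true = getattr(fit.params, name), getattr(WT_TRUTH, name)
            assert abs(est - true) / abs(true) < 1e-3, name

    def test_noisy_recovery_within_tolerance(self, wt_spec):
        counts = sample_binned_counts(wt_spec, seed=101)
        fit = fit_two_component(number_to_volume(counts))
        assert abs(fit.params.mu_A - 19.0) / 19.0 < 0.02
        assert abs(fit.params.w_B - 0.40) < 0.03

    def test_ordering_constraint_always_holds(self, wt_expected):
        fit = fit_two_component(wt_expected)
        assert fit.params.b_mean < fit.params.mu_A
        fit.params.validate()

    def test_invalid_init_rejected_before_optimization(self, wt_expected):
        bad = MixtureParams(w_B=0.4, mu_A=5.0, sigma_A=3.5,
                            mlog_B=math.log(10.0), slog_B=0.35)  # B above A
        with pytest.raises(ValueError, match="ordering"):
            fit_two_component(wt_expected, init=bad)

    def test_optimizer_beats_coarse_grid_search(self):
        # brute-force oracle: 5 points per parameter over the constrained box
        grid = DiameterGrid.log_spaced(2, 60, 50)
        d = analytic_density(WT_TRUTH, grid=grid)
        obs = d.values
        best_grid_rss = np.inf
        for w, mu, sig, bm, sl in itertools.product(
            np.linspace(0.2, 0.6, 5),
            np.linspace(15.0, 23.0, 5),
            np.linspace(2.0, 5.0, 5),
            np.linspace(math.log(4.0), math.log(9.0), 5),
            np.linspace(0.2, 0.6, 5),
        ):
            params = MixtureParams(w_B=w, mu_A=mu, sigma_A=sig,
                                   mlog_B=bm - sl**2 / 2, slog_B=sl)
            if not params.b_mean < params.mu_A:
                continue
            model = mixture_bin_percent(grid, params)
            model = 100.0 * model / model.sum()
            best_grid_rss = min(best_grid_rss, float(np.sum((obs - model) ** 2)))
        fit = fit_two_component(d)
        assert fit.rss <= best_grid_rss


class TestOneComponentFit:
    def test_noiseless_normal_at_14(self):
        d = analytic_density(MixtureParams(w_B=0.0, mu_A=14.0, sigma_A=3.5))
        fit = fit_one_component(d)
        assert fit.n_components == 1
        assert fit.params.w_B == 0.0
        assert abs(fit.params.mu_A - 14.0) <= 0.01

    def test_symmetric_input_mu_matches_mode_bin(self):
        d = analytic_density(MixtureParams(w_B=0.0, mu_A=14.0, sigma_A=3.0))
        fit = fit_one_component(d)
        mids = d.grid.midpoints
        density = d.values / np.diff(d.grid.edges)
        k = int(np.argmax(density))
        assert abs(fit.params.mu_A - mids[k]) <= float(np.diff(d.grid.edges)[k])

    def test_nested_model_rss_ordering(self, wt_expected):
        one = fit_one_component(wt_expected)
        two = fit_two_component(wt_expected)
        assert one.converged and two.converged
        assert two.rss <= one.rss
        assert one.rss > two.rss  # bimodal input: strict improvement


class TestSelectModel:
    def test_12daf_presets_are_unimodal_with_na_b_fields(self):
        for name in ("WT_12DAF", "parc6_12DAF"):
            d = expected_volume_density(make_preset(name))
            fit = select_model(d)
            assert fit.n_components == 1
            assert fit.params.w_B == 0.0
            assert math.isnan(fit.params.mlog_B)
            metrics = derive_metrics(fit)
            assert metrics.b_mean_diameter is None
            assert metrics.b_content_pct is None

    def test_mature_wt_is_bimodal(self, wt_expected):
        assert select_model(wt_expected).n_components == 2

    def test_vanishing_b_component_collapses_to_one(self):
        d = analytic_density(MixtureParams(
            w_B=0.005, mu_A=19.0, sigma_A=3.5,
            mlog_B=math.log(6.0), slog_B=0.35))
        assert select_model(d).n_components == 1


class TestMetrics:
    def test_b_content_and_b_mean_identities(self):
        fit = FitResult(n_components=2, params=WT_TRUTH, rss=0.0,
                        converged=True, n_bins_used=300)
        m = derive_metrics(fit)
        assert m.b_content_pct == pytest.approx(40.0)
        assert m.b_mean_diameter == pytest.approx(6.0)
        assert m.a_mean_diameter == pytest.approx(19.0)

    def test_non_converged_fit_rejected(self):
        fit = FitResult(n_components=2, params=WT_TRUTH, rss=1.0,
                        converged=False, n_bins_used=300)
        with pytest.raises(ValueError, match="converged"):
            derive_metrics(fit)


class TestPercentChange:
    def test_hand_values(self):
        assert percent_change(19.0, 19.0) == 0.0
        assert percent_change(23.0, 19.0) == pytest.approx(21.052631578947366)
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)

    def test_mutant_contrast_is_positive_end_to_end(self):
        wt = derive_metrics(select_model(
            expected_volume_density(make_preset("WT_mature"))))
        mut = derive_metrics(select_model(
            expected_volume_density(make_preset("parc6_mature"))))
        assert percent_change(mut.a_mean_diameter, wt.a_mean_diameter) > 0
        assert percent_change(mut.b_mean_diameter, wt.b_mean_diameter) > 0
        assert percent_change(mut.b_content_pct, wt.b_content_pct) > 0
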