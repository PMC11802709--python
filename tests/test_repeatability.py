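import numpy as np
import pandas as pd
import pytest

from flocknet import (AssociationParams, classify_repeatability,
                      cross_definition_regression, estimate_repeatability,
                      simulate_weekly_panel, sweep_time_window,
                      weekly_metric_panel)
from flocknet.repeatability import METRICS, WeeklyMetricPanel, _anova_components


def panel_from_rows(rows):
    return WeeklyMetricPanel(pd.DataFrame(
        rows, columns=["individual", "week", "definition", "metric",
                       "value", "z"]))


def gaussian_panel(rng, n_ind=40, n_weeks=8, s2a=1.0, s2e=1.0,
                   definition="sim", metric="strength"):
    rows = []
    for i in range(n_ind):
        a = rng.normal(0, np.sqrt(s2a))
        for wk in range(n_weeks):
            v = a + rng.normal(0, np.sqrt(s2e))
            rows.append((f"I{i:03d}", wk, definition, metric, v, v))
    return panel_from_rows(rows)


class TestWeeklyMetricPanel:
    def test_z_standardized_within_week_cells(self, small_world):
        streams = simulate_weekly_panel(small_world)
        panel = weekly_metric_panel(streams, "arrival",
                                    AssociationParams(150.0, delta_i=300.0))
        for (wk, metric), sub in panel.df.groupby(["week", "metric"]):
            if len(sub) >= 2:
                assert sub["z"].mean() == pytest.approx(0.0, abs=1e-9)
                assert sub["z"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_row_count_is_three_metrics_per_connected_individual(self, small_world):
        from flocknet import build_sri_network, detect, prune_isolates
        streams = simulate_weekly_panel(small_world)
        params = AssociationParams(150.0, delta_i=300.0)
        panel = weekly_metric_panel(streams, "arrival", params)
        expected = 0
        for s in streams:
            net = prune_isolates(build_sri_network(detect(s, "arrival", params)))
            if net.n_nodes >= 2:
                expected += net.n_nodes * len(METRICS)
        assert len(panel) == expected

    def test_identical_weeks_identical_metrics(self, small_world):
        from flocknet import simulate_detections
        s = simulate_detections(small_world, 0)
        panel = weekly_metric_panel([s, s], "window", AssociationParams(1.0))
        w0 = panel.df[panel.df.week == 0].drop(columns="week").reset_index(drop=True)
        w1 = panel.df[panel.df.week == 1].drop(columns="week").reset_index(drop=True)
        pd.testing.assert_frame_equal(w0, w1)

    def test_sparse_week_skipped_with_warning(self):
        from conftest import make_stream
        lone = make_stream([0.0], ["A"])
        with pytest.warns(UserWarning, match="skipped"):
            panel = weekly_metric_panel([lone], "window", AssociationParams(1.0))
        assert len(panel) == 0


class TestEstimateRepeatability:
    def test_pure_individual_signal_gives_one(self):
        rows = [(f"I{i}", wk, "d", "degree", float(i), float(i))
                for i in range(5) for wk in range(4)]
        res = estimate_repeatability(panel_from_rows(rows), "degree", "d",
                                     n_boot=50, seed=0)
        assert res.R == pytest.approx(1.0)
        assert res.band == "high"

    def test_iid_noise_gives_zero_with_covering_ci(self, rng):
        panel = gaussian_panel(rng, s2a=0.0)
        res = estimate_repeatability(panel, "strength", "sim", n_boot=300, seed=1)
        assert res.R < 0.1
        assert res.ci_low <= 0.0 + 1e-12

    def test_recovers_half(self, rng):
        panel = gaussian_panel(rng, n_ind=100, n_weeks=10, s2a=1.0, s2e=1.0)
        res = estimate_repeatability(panel, "strength", "sim", n_boot=300, seed=2)
        assert res.R == pytest.approx(0.5, abs=0.1)
        assert res.ci_low <= 0.5 <= res.ci_high

    def test_anova_equals_reml_on_balanced_data(self, rng):
        panel = gaussian_panel(rng, n_ind=30, n_weeks=6)
        r_anova = estimate_repeatability(panel, "strength", "sim",
                                         n_boot=0, seed=0, method="anova")
        r_reml = estimate_repeatability(panel, "strength", "sim",
                                        n_boot=0, seed=0, method="reml")
        assert r_anova.R == pytest.approx(r_reml.R, abs=1e-6)

    def test_anova_matches_oneway_icc_formula(self, rng):
        # balanced design: R = (MSA - MSW) / (MSA + (n-1) MSW)
        panel = gaussian_panel(rng, n_ind=20, n_weeks=5)
        sub = panel.subset("strength", "sim")
        y = sub["z"].to_numpy()
        g = sub["individual"].to_numpy()
        wide = sub.pivot(index="individual", columns="week", values="z").to_numpy()
        k, n = wide.shape
        msa = n * wide.mean(axis=1).var(ddof=1)
        msw = (wide.var(axis=1, ddof=1)).mean()
        icc = (msa - msw) / (msa + (n - 1) * msw)
        s2a, s2e = _anova_components(y, g)
        assert s2a / (s2a + s2e) == pytest.approx(icc, abs=1e-6)

    def test_constant_response_errors(self):
        rows = [(f"I{i}", wk, "d", "degree", 1.0, 1.0)
                for i in range(4) for wk in range(3)]
        with pytest.raises(ValueError, match="zero total variance"):
            estimate_repeatability(panel_from_rows(rows), "degree", "d",
                                   n_boot=10, seed=0)

    def test_requires_repeated_measures(self):
        rows = [(f"I{i}", 0, "d", "degree", float(i), float(i))
                for i in range(5)]
        with pytest.raises(ValueError):
            estimate_repeatability(panel_from_rows(rows), "degree", "d")

    def test_ci_ordered_and_bounded(self, rng):
        panel = gaussian_panel(rng, n_ind=25, n_weeks=5, s2a=0.5)
        res = estimate_repeatability(panel, "strength", "sim", n_boot=200, seed=3)
        assert 0.0 <= res.ci_low <= res.R <= res.ci_high <= 1.0


class TestClassify:
    @pytest.mark.parametrize("r,band", [
        (0.0, "low"), (0.28, "low"), (0.3, "medium"), (0.45, "medium"),
        (0.5, "medium"), (0.51, "high"), (0.81, "high"), (1.0, "high"),
    ])
    def test_bands(self, r, band):
        assert classify_repeatability(r) == band


class TestCrossDefinitionRegression:
    def test_self_pairing_slope_one(self, rng):
        panel = gaussian_panel(rng, definition="a")
        mirror = panel.df.assign(definition="b")
        both = WeeklyMetricPanel(pd.concat([panel.df, mirror], ignore_index=True))
        slope, intercept, p = cross_definition_regression(both, "strength", "a", "b")
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_negated_slope_minus_one(self, rng):
        panel = gaussian_panel(rng, definition="a")
        neg = panel.df.assign(definition="b", z=-panel.df["z"])
        both = WeeklyMetricPanel(pd.concat([panel.df, neg], ignore_index=True))
        slope, _, _ = cross_definition_regression(both, "strength", "a", "b")
        assert slope == pytest.approx(-1.0)

    def test_attenuation_matches_closed_form(self, rng):
        # two noisy measures of one latent trait: slope -> var_l/(var_l+var_e)
        rows = []
        var_l, var_e = 1.0, 0.5
        for i in range(300):
            for wk in range(8):
                latent = rng.normal(0, np.sqrt(var_l))
                za = latent + rng.normal(0, np.sqrt(var_e))
                zb = latent + rng.normal(0, np.sqrt(var_e))
                rows.append((f"I{i}", wk, "a", "strength", za, za))
                rows.append((f"I{i}", wk, "b", "strength", zb, zb))
        panel = panel_from_rows(rows)
        slope, _, _ = cross_definition_regression(panel, "strength", "a", "b")
        assert slope == pytest.approx(var_l / (var_l + var_e), abs=0.05)


class TestSweep:
    def test_singleton_grid_matches_direct_call(self, small_world):
        streams = simulate_weekly_panel(small_world)
        params = AssociationParams(150.0, delta_i=300.0)
        table = sweep_time_window(streams, "arrival", [150.0], delta_i=300.0,
                                  n_boot=50, seed=7)
        panel = weekly_metric_panel(streams, "arrival", params)
        direct = estimate_repeatability(panel, "strength", "arrival",
                                        n_boot=50, seed=7)
        row = table[(table.metric == "strength")].iloc[0]
        assert row.R == pytest.approx(direct.R)

    def test_rejects_gmm(self, small_world):
        with pytest.raises(ValueError):
            sweep_time_window([], "gmm", [1.0])


def test_zscore_idempotent_on_standardized_cells(rng):
    from flocknet.repeatability import _zscore
    v = rng.normal(0, 1, 50)
    z = _zscore(v)
    np.testing.assert_allclose(_zscore(z), z, atol=1e-12)
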