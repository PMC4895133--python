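import json

import numpy as np
import pytest
from scipy import stats

import connectopo as ct


class TestOffsetPowerFit:
    def test_noiseless_recovery(self):
        x = np.linspace(0.01, 1.0, 20)
        fit = ct.fit_offset_power(x, 2.0 + 3.0 * x ** 0.5)
        assert np.allclose(fit.params, (2.0, 3.0, 0.5), atol=1e-6)
        assert fit.residual_sse < 1e-12

    def test_linear_special_case(self):
        x = np.linspace(0.1, 2.0, 10)
        fit = ct.fit_offset_power(x, 5.0 * x)
        a, b, c = fit.params
        assert a == pytest.approx(0.0, abs=1e-6)
        assert b == pytest.approx(5.0, abs=1e-6)
        assert c == pytest.approx(1.0, abs=1e-6)

    def test_recovery_under_noise(self):
        rng = np.random.default_rng(17)
        x = np.linspace(0.01, 1.0, 20)
        y = 2.0 + 3.0 * x ** 0.5
        y = y + rng.normal(0, 0.01 * np.ptp(y), x.size)
        fit = ct.fit_offset_power(x, y)
        assert 0.4 <= fit.params[2] <= 0.6

    def test_fixed_exponent_matches_ols_oracle(self):
        x = np.linspace(0.1, 1.0, 8)
        y = 1.0 + 2.0 * x + np.sin(np.arange(8)) * 0.1
        fit = ct.fit_offset_power(x, y, fix_exponent=1.0)
        res = stats.linregress(x, y)
        assert fit.params[0] == pytest.approx(res.intercept, abs=1e-9)
        assert fit.params[1] == pytest.approx(res.slope, abs=1e-9)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            ct.fit_offset_power([1, 2, 3], [1, 2, 3])


class TestShiftedPowerGrowth:
    def test_noiseless_recovery(self):
        N = np.array([1e3, 3e3, 1e4, 3e4, 1e5, 1e6])
        fit = ct.fit_shifted_power_growth(N, 1.0 + 0.01 * N ** 0.4)
        assert np.allclose(fit.params, (1.0, 0.01, 0.4), rtol=1e-5)
        assert not fit.degenerate

    def test_constant_series_degenerate(self):
        N = np.array([1e3, 1e4, 1e5, 1e6])
        fit = ct.fit_shifted_power_growth(N, np.full(4, 2.5))
        assert fit.degenerate

    def test_growing_dimension_series(self):
        """Dimension estimates from growing ER graphs yield C > 0."""
        sizes, dims = [], []
        for n in (400, 1000, 2500, 6000):
            g = ct.largest_connected_component(
                ct.erdos_renyi_graph(n, 5 * n, seed=n))
            curve = ct.ball_growth(g, seeds=200, seed=1)
            est = ct.fit_dimension(curve)
            sizes.append(g.n_nodes)
            dims.append(est.D)
        fit = ct.fit_shifted_power_growth(np.array(sizes), np.array(dims))
        assert fit.params[2] > 0


class TestZeroSlopeTest:
    def test_proportional_series_significant(self):
        x = np.arange(1.0, 11.0)
        slope, p = ct.zero_slope_test(x, 3.0 * x)
        assert slope == pytest.approx(3.0)
        assert p < 1e-6

    def test_constant_series_convention(self):
        slope, p = ct.zero_slope_test([1, 2, 3, 4], [2.0, 2.0, 2.0, 2.0])
        assert (slope, p) == (0.0, 1.0)

    def test_hand_computed_regression_oracle(self):
        # x = 1..5, y as below: slope = -0.05, t = -1, p = 2*sf(1, df=3)
        slope, p = ct.zero_slope_test(np.arange(1.0, 6.0),
                                      [2.1, 1.9, 2.2, 2.0, 1.8])
        assert slope == pytest.approx(-0.05, abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(1.0, 3), abs=1e-10)

    def test_zero_variance_x_errors(self):
        with pytest.raises(ValueError):
            ct.zero_slope_test([1, 1, 1], [1, 2, 3])

    def test_pvalues_uniform_under_null(self):
        """Size check: under independent noise the p-values are U(0,1)."""
        rng = np.random.default_rng(5)
        x = np.arange(1.0, 6.0)
        pvals = [ct.zero_slope_test(x, rng.normal(size=5))[1]
                 for _ in range(2000)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestAnalyzeGraph:
    @pytest.fixture(scope="class")
    def bundle_and_dir(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("bundle")
        g = ct.largest_connected_component(
            ct.erdos_renyi_graph(1500, 9000, seed=8))
        cfg = ct.AnalysisConfig(graph=g, out_dir=str(out),
                                stages=("degree", "dimension", "smallworld"),
                                seed=3, kc_grid=[0, 1, 2], robustness=True,
                                families=("EXP", "WBL", "GWB"))
        return ct.analyze_graph(cfg), out, g

    def test_all_reports_written_and_parseable(self, bundle_and_dir):
        bundle, out, _ = bundle_and_dir
        for name in ("degree_fits.json", "dimension.json", "smallworld.json",
                     "report.json"):
            json.loads((out / name).read_text())
        for name in ("degree_deltas.tsv", "degree_params.tsv",
                     "dimension.tsv", "smallworld.tsv",
                     "smallworld_perturbed.tsv"):
            lines = (out / name).read_text().splitlines()
            assert len(lines) >= 2

    def test_robustness_bookkeeping(self, bundle_and_dir):
        bundle, _, g = bundle_and_dir
        # removing 10% of undirected edges drops <k> by ~10%
        ratio = (bundle["smallworld_perturbed"]["mean_k"]
                 / bundle["smallworld"]["mean_k"])
        assert ratio == pytest.approx(0.9, abs=0.02)

    def test_rerun_is_byte_identical(self, bundle_and_dir, tmp_path):
        _, out, g = bundle_and_dir
        cfg = ct.AnalysisConfig(graph=g, out_dir=str(tmp_path),
                                stages=("degree", "dimension", "smallworld"),
                                seed=3, kc_grid=[0, 1, 2], robustness=True,
                                families=("EXP", "WBL", "GWB"))
        ct.analyze_graph(cfg)
        for name in ("degree_deltas.tsv", "dimension.tsv", "smallworld.tsv",
                     "smallworld_perturbed.tsv", "degree_fits.json"):
            assert (tmp_path / name).read_text() == (out / name).read_text()

    def test_unknown_stage_errors(self):
        g = ct.erdos_renyi_graph(50, 100, seed=0)
        with pytest.raises(ValueError, match="unknown stage"):
            ct.analyze_graph(ct.AnalysisConfig(graph=g, stages=("bogus",),
                                               out_dir="/tmp/x"))


class TestAnalysisConfigFromFile:
    def test_key_value_format(self, tmp_path):
        p = tmp_path / "run.cfg"
        p.write_text("graph_path = g.edges\nseed = 9\n"
                     "stages = degree,smallworld\nkc_grid = 0,1,2\n"
                     "robustness = true\n")
        cfg = ct.AnalysisConfig.from_file(p)
        assert cfg.graph_path == "g.edges"
        assert cfg.seed == 9
        assert cfg.stages == ("degree", "smallworld")
        assert cfg.kc_grid == [0, 1, 2]
        assert cfg.robustness is True
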