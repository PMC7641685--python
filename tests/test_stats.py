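import numpy as np
import pytest
from scipy import stats as sps

from mammocad.stats import (CIBound, load_run_table, mean_diff_lower_bound,
                            normal_probability_points, quartiles,
                            reproduce_published_analysis, summarize,
                            var_ratio_lower_bound)


@pytest.fixture(scope="module")
def run_table():
    return load_run_table()


class TestFixture:
    def test_shape_and_ranges(self, run_table):
        assert len(run_table) == 60
        assert set(run_table["arm"]) == {"OS", "DA", "CS", "DACS"}
        for m in ("AC", "SE", "SP", "AUOC"):
            assert run_table[m].between(0, 100).all()

    def test_round_trips_through_tsv(self, run_table, tmp_path):
        from mammocad.experiments import load_results, save_results
        p = tmp_path / "t.tsv"
        save_results(p, run_table)
        assert load_results(p).equals(run_table)


class TestSummarize:
    def test_spot_values(self, run_table):
        s = summarize(run_table).set_index(["arm", "metric"])
        assert round(s.loc[("OS", "AC"), "mean"], 1) == 77.9
        assert round(s.loc[("DACS", "AC"), "mean"], 1) == 92.1
        assert round(s.loc[("DACS", "AC"), "stdev"], 1) == 1.8

    def test_constant_column_zero_stdev(self):
        import pandas as pd
        t = pd.DataFrame({"arm": ["A"] * 3, "AC": [90, 90, 90],
                          "SE": [1, 2, 3], "SP": [1, 2, 3],
                          "AUOC": [1, 2, 3]})
        s = summarize(t).set_index("metric")
        assert s.loc["AC", "stdev"] == 0.0

    def test_single_run_rejected(self):
        import pandas as pd
        t = pd.DataFrame({"arm": ["A"], "AC": [90], "SE": [1], "SP": [1],
                          "AUOC": [1]})
        with pytest.raises(ValueError):
            summarize(t)


class TestVarRatioBound:
    def test_identical_samples(self, rng):
        x = rng.normal(80, 4, 15)
        b = var_ratio_lower_bound(x, x)
        # ratio 1, bound = 1 / F_{0.95;14,14}
        assert b.statistic == pytest.approx(1.0)
        assert b.bound == pytest.approx(0.403, abs=1e-3)

    def test_scale_equivariance(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 15)
        b1 = var_ratio_lower_bound(x, y)
        b2 = var_ratio_lower_bound(3.0 * x, y)
        assert b2.bound == pytest.approx(9.0 * b1.bound)

    def test_zero_denominator_variance(self):
        with pytest.raises(ZeroDivisionError):
            var_ratio_lower_bound([1.0, 2.0], [5.0, 5.0])

    def test_short_sample_rejected(self):
        with pytest.raises(ValueError):
            var_ratio_lower_bound([1.0], [1.0, 2.0])

    def test_p_value_directions(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 5, 15)
        less = var_ratio_lower_bound(x, y, alternative="less")
        greater = var_ratio_lower_bound(x, y, alternative="greater")
        assert less.p_value < 0.05 < greater.p_value
        assert less.p_value + greater.p_value == pytest.approx(1.0)


class TestMeanDiffBound:
    def test_identical_samples(self, rng):
        x = rng.normal(80, 4, 15)
        b = mean_diff_lower_bound(x, x)
        n = len(x)
        expected = -sps.t.ppf(0.95, 2 * n - 2) * x.std(ddof=1) * np.sqrt(2 / n)
        assert b.bound == pytest.approx(expected)
        assert b.bound < 0

    def test_translation_equivariance(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 1, 15)
        b1 = mean_diff_lower_bound(x, y)
        b2 = mean_diff_lower_bound(x + 7.5, y)
        assert b2.bound == pytest.approx(b1.bound + 7.5)

    def test_agrees_with_scipy_t_test(self, rng):
        x = rng.normal(90, 2, 15)
        y = rng.normal(78, 4, 15)
        b = mean_diff_lower_bound(x, y)
        t = sps.ttest_ind(x, y, equal_var=True, alternative="greater")
        assert b.p_value == pytest.approx(t.pvalue)
        assert b.statistic == pytest.approx(t.statistic)


class TestCIBoundValidation:
    def test_bad_alpha(self):
        with pytest.raises(ValueError):
            CIBound(("a", "b", "mean_diff"), alpha=1.5, bound=0.0,
                    p_value=0.5, statistic=0.0)


class TestReport:
    def test_flags_identify_non_reproducing_rows(self, run_table):
        report = reproduce_published_analysis(run_table)
        flags = report["flags"]
        assert flags["H04"]["reproduces"]
        for h in ("H01", "H02", "H03"):
            assert flags[h]["reproduces"]
        # the two rows whose printed bounds do not regenerate
        assert not flags["H05"]["reproduces"]
        assert not flags["H06"]["reproduces"]
        assert flags["H05"]["recomputed"] == pytest.approx(14.19, abs=0.01)
        assert flags["H06"]["recomputed"] == pytest.approx(2.39, abs=0.01)

    def test_headline_values(self, run_table):
        report = reproduce_published_analysis(run_table)
        assert round(report["headline"]["accuracy_gain_lower_bound"], 1) == 12.2
        assert round(report["headline"]["precision_gain_lower_bound"], 1) == 2.2


class TestPlottingExports:
    def test_normal_probability_points(self, rng):
        x = rng.normal(0, 1, 15)
        v, q = normal_probability_points(x)
        assert np.all(np.diff(v) >= 0) and np.all(np.diff(q) > 0)
        assert len(v) == len(q) == 15

    def test_quartiles(self):
        qs = quartiles([1, 2, 3, 4, 5])
        assert qs["median"] == 3 and qs["min"] == 1 and qs["max"] == 5
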