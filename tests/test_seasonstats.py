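import numpy as np
import pandas as pd
import pytest

from deepclick import seasonstats as ss


def make_monthly(percent, years=range(2015, 2019)):
    """Monthly frame from a function month,year -> percent."""
    rows = [
        {"year": y, "month": m, "percent_present": percent(m, y)}
        for y in years
        for m in range(1, 13)
    ]
    return pd.DataFrame(rows)


class TestMonthlyPercentPresence:
    def _frames(self, n_days, present_days, start="2020-01-01"):
        days = pd.date_range(start, periods=n_days, freq="D")
        log = pd.DataFrame({"day_id": days, "recorded": True})
        calls = pd.DataFrame(
            {"day_id": days[:present_days], "present": [True] * present_days}
        )
        return calls, log

    def test_simple_fraction(self):
        calls, log = self._frames(31, 10)
        out = ss.monthly_percent_presence(calls, log)
        assert out.loc[0, "percent_present"] == pytest.approx(100 * 10 / 31)

    def test_zero_present(self):
        calls, log = self._frames(31, 0)
        assert ss.monthly_percent_presence(calls, log).loc[0, "percent_present"] == 0.0

    def test_denominator_is_recording_days_not_calendar(self):
        days = pd.date_range("2020-01-01", periods=31, freq="D")
        log = pd.DataFrame({"day_id": days, "recorded": [True] * 28 + [False] * 3})
        calls = pd.DataFrame({"day_id": days[:14], "present": True})
        out = ss.monthly_percent_presence(calls, log)
        assert out.loc[0, "n_recording_days"] == 28
        assert out.loc[0, "percent_present"] == pytest.approx(50.0)

    def test_month_without_recording_days_is_missing(self):
        days = pd.date_range("2020-01-01", periods=60, freq="D")
        log = pd.DataFrame({"day_id": days, "recorded": days.month == 1})
        calls = pd.DataFrame({"day_id": days[:5], "present": True})
        out = ss.monthly_percent_presence(calls, log).set_index("month")
        assert np.isnan(out.loc[2, "percent_present"])

    def test_call_on_non_recording_day_errors(self):
        days = pd.date_range("2020-01-01", periods=10, freq="D")
        log = pd.DataFrame({"day_id": days, "recorded": False})
        calls = pd.DataFrame({"day_id": [days[0]], "present": [True]})
        with pytest.raises(ValueError, match="non-recording"):
            ss.monthly_percent_presence(calls, log)


class TestRunningMean3:
    def test_center_and_endpoints(self):
        out = ss.running_mean3([30.0, 60.0, 30.0])
        assert out[1] == pytest.approx(40.0)
        assert out[0] == pytest.approx(45.0)  # 2-point mean at the edge

    def test_constant_unchanged(self):
        assert np.allclose(ss.running_mean3([7.0] * 10), 7.0)

    def test_variance_never_increases(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=36)
            assert np.var(ss.running_mean3(x)) <= np.var(x) + 1e-12

    def test_preserves_bounds(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 48)
        out = ss.running_mean3(x)
        assert out.min() >= 0 and out.max() <= 100


class TestSeasonalModel:
    def test_pure_sinusoid_fits_perfectly(self):
        df = make_monthly(lambda m, y: 45 + 15 * np.cos(2 * np.pi * (m - 1) / 12))
        fit = ss.fit_seasonal_model(df)
        assert fit.deviance_explained > 0.99
        assert fit.p_value < 0.001
        assert np.argmax(fit.fitted_monthly_curve) == 0  # January peak

    def test_noisy_sinusoid_detected(self):
        rng = np.random.default_rng(3)
        df = make_monthly(
            lambda m, y: 45 + 10 * np.cos(2 * np.pi * (m - 1) / 12) + rng.normal(0, 5)
        )
        fit = ss.fit_seasonal_model(df)
        assert fit.p_value < 0.01
        assert fit.deviance_explained > 0.3

    def test_too_short_series_errors(self):
        df = make_monthly(lambda m, y: 50.0, years=[2020])
        with pytest.raises(ValueError):
            ss.fit_seasonal_model(df)


class TestClassifyIci:
    @pytest.mark.parametrize(
        "ici,label",
        [
            (0.5, "small"),
            (0.59, "small"),
            (0.6, "intermediate"),
            (0.7, "intermediate"),
            (0.8, "intermediate"),
            (0.81, "large"),
            (1.0, "large"),
        ],
    )
    def test_examples(self, ici, label):
        assert ss.classify_ici(ici) == label

    def test_partition_of_positive_axis(self):
        rng = np.random.default_rng(0)
        for ici in rng.uniform(0.01, 5.0, 500):
            assert ss.classify_ici(ici) in {"small", "intermediate", "large"}

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            ss.classify_ici(0.0)


class TestIciMonthlyDistribution:
    def _seq_frame(self, icis, month=1, year=2020):
        return pd.DataFrame({"mean_ici": icis, "month": month, "year": year})

    def test_unit_area_and_concentration(self):
        df = self._seq_frame(np.full(50, 1.0))
        out = ss.ici_monthly_distribution(df)
        width = out["ici"].iloc[1] - out["ici"].iloc[0]
        assert np.sum(out["mean_density"]) * width == pytest.approx(1.0, abs=1e-6)
        assert out.loc[out["mean_density"].idxmax(), "ici"] == pytest.approx(1.0, abs=0.05)

    def test_two_equal_modes_symmetric(self):
        df = self._seq_frame(np.concatenate([np.full(40, 0.5), np.full(40, 1.0)]))
        out = ss.ici_monthly_distribution(df)
        d = out.set_index("ici")["mean_density"]
        m1 = d.iloc[int(np.abs(d.index.to_numpy() - 0.5).argmin())]
        m2 = d.iloc[int(np.abs(d.index.to_numpy() - 1.0).argmin())]
        assert m1 == pytest.approx(m2)

    def test_trimodal_mixture_recovers_three_peaks(self):
        from scipy.signal import find_peaks

        rng = np.random.default_rng(2)
        icis = np.concatenate(
            [
                rng.normal(0.5, 0.03, 300),
                rng.normal(1.0, 0.03, 300),
                rng.normal(1.8, 0.03, 300),
            ]
        )
        out = ss.ici_monthly_distribution(self._seq_frame(icis))
        peaks, _ = find_peaks(out["mean_density"].to_numpy(), height=0.5)
        assert len(peaks) == 3


class TestAnovaLogIci:
    def _balanced(self, n_months=12, n_years=8, effect=0.0, seed=0, reps=3):
        rng = np.random.default_rng(seed)
        rows = []
        for m in range(1, n_months + 1):
            for y in range(2015, 2015 + n_years):
                for _ in range(reps):
                    rows.append(
                        {
                            "month": m,
                            "year": y,
                            "mean_ici": float(np.exp(rng.normal(0, 0.3) + effect * m / 12)),
                        }
                    )
        return pd.DataFrame(rows)

    def test_df_convention_on_12x8_design(self):
        out = ss.anova_log_ici(self._balanced())
        assert out["df_month"] == 11
        assert out["df_year"] == 7
        assert out["df_resid"] == 12 * 8 - 11 - 7 - 1

    def test_identical_cells_give_zero_F(self):
        df = self._balanced(effect=0.0)
        df["mean_ici"] = 1.0
        out = ss.anova_log_ici(df)
        assert out["F_month"] == pytest.approx(0.0, abs=1e-20)
        assert out["F_year"] == pytest.approx(0.0, abs=1e-20)

    def test_strong_month_effect_detected(self):
        out = ss.anova_log_ici(self._balanced(effect=2.0, seed=1))
        assert out["p_month"] < 0.001

    def test_single_level_errors(self):
        df = self._balanced()
        with pytest.raises(ValueError):
            ss.anova_log_ici(df[df["month"] == 1])


class TestRegressIciPresence:
    def test_exact_line(self):
        x = np.arange(1.0, 13.0)
        fit = ss.regress_ici_presence(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.p_value < 1e-10

    def test_constant_x_errors(self):
        with pytest.raises(ValueError):
            ss.regress_ici_presence(np.ones(12), np.arange(12.0))

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            ss.regress_ici_presence([1.0, 2.0], [1.0, 2.0])
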