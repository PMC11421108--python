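"""Monthly presence aggregation, seasonality testing, and ICI demographics.

Daily presence calls are aggregated to the monthly percent of *recording*
days with at least one qualifying click sequence.  Seasonality is tested with
a cyclic-smooth model of month (harmonic basis, period 12) with year as a
random intercept.  Mean inter-click interval (ICI) of each sequence carries
demographic information: short ICIs indicate small body size (females and
juveniles, ICI < 0.6 s), long ICIs large body size (adult males,
ICI > 0.8 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeasonalFit",
    "RegressionResult",
    "monthly_percent_presence",
    "running_mean3",
    "fit_seasonal_model",
    "classify_ici",
    "ici_monthly_distribution",
    "anova_log_ici",
    "regress_ici_presence",
    "harmonic_basis",
]

#: demographic class bounds (s): small < 0.6, large > 0.8, intermediate otherwise
ICI_SMALL_MAX = 0.6
ICI_LARGE_MIN = 0.8


@dataclass(frozen=True)
class SeasonalFit:
    deviance_explained: float
    p_value: float
    fitted_monthly_curve: np.ndarray  # 12 values, months 1..12


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    r: float


def monthly_percent_presence(
    daily_calls: pd.DataFrame, recording_log: pd.DataFrame
) -> pd.DataFrame:
    """Monthly percent of recording days with presence.

    ``daily_calls`` needs columns ``day_id`` (date-like) and ``present``;
    ``recording_log`` needs ``day_id`` and boolean ``recorded``.  Only
    recording days enter the denominator; months without any recording day
    are emitted with a missing percent.  A call for a non-recording day is an
    inconsistency and raises.
    """
    calls = daily_calls.copy()
    calls["day_id"] = pd.to_datetime(calls["day_id"])
    log = recording_log.copy()
    log["day_id"] = pd.to_datetime(log["day_id"])
    recorded = set(log.loc[log["recorded"].astype(bool), "day_id"])
    bad = calls.loc[~calls["day_id"].isin(recorded), "day_id"]
    if len(bad):
        raise ValueError(f"daily call supplied for non-recording day {bad.iloc[0].date()}")
    call_map = calls.set_index("day_id")["present"].astype(bool)

    log["present"] = log["day_id"].map(call_map).fillna(False).astype(bool)
    log["year"] = log["day_id"].dt.year
    log["month"] = log["day_id"].dt.month
    rows = []
    for (year, month), grp in log.groupby(["year", "month"]):
        n_rec = int(grp["recorded"].sum())
        n_pres = int(grp.loc[grp["recorded"].astype(bool), "present"].sum())
        rows.append(
            {
                "year": year,
                "month": month,
                "n_recording_days": n_rec,
                "n_present_days": n_pres,
                "percent_present": 100.0 * n_pres / n_rec if n_rec else np.nan,
            }
        )
    return pd.DataFrame(rows)


def running_mean3(series) -> np.ndarray:
    """Centered 3-month running mean; endpoints average the available neighbors."""
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(3, center=True, min_periods=1).mean().to_numpy()


def harmonic_basis(month, n_harmonics: int = 3) -> np.ndarray:
    """Cyclic (Fourier) basis of the monthly cycle: sin/cos pairs, period 12."""
    m = np.asarray(month, dtype=float)
    cols = []
    for k in range(1, n_harmonics + 1):
        cols.append(np.sin(2 * np.pi * k * m / 12.0))
        cols.append(np.cos(2 * np.pi * k * m / 12.0))
    return np.column_stack(cols)


def fit_seasonal_model(monthly: pd.DataFrame) -> SeasonalFit:
    """Cyclic smooth of month with year random intercept.

    ``monthly`` needs columns ``year``, ``month``, ``percent_present``.
    The month effect is a 6-dimensional harmonic basis; the p-value is a
    likelihood-ratio test of the month term (ML fits, chi-square df 6);
    deviance explained is relative to the intercept-only model, computed from
    the fixed-effects fit.  Requires >= 24 months spanning >= 2 years;
    months with a missing percent (no recording days) are dropped.
    """
    import statsmodels.api as sm

    df = monthly.dropna(subset=["percent_present"]).copy()
    if len(df) < 24 or df["year"].nunique() < 2:
        raise ValueError("need >= 24 months spanning >= 2 years")
    y = df["percent_present"].to_numpy(dtype=float)
    X = harmonic_basis(df["month"].to_numpy())
    Xc = sm.add_constant(X)

    ols = sm.OLS(y, Xc).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(ols.resid**2))
    curve = _fitted_curve(ols.params)
    if tss <= 0 or rss <= 1e-10 * max(tss, 1.0):
        # degenerate: the cyclic smooth reproduces the series exactly
        dev = 1.0 if tss > 0 else 0.0
        return SeasonalFit(deviance_explained=dev, p_value=0.0 if tss > 0 else 1.0,
                           fitted_monthly_curve=curve)

    groups = df["year"].to_numpy()
    dev = 1.0 - rss / tss
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.MixedLM(y, Xc, groups=groups).fit(reml=False)
            null = sm.MixedLM(y, np.ones((len(y), 1)), groups=groups).fit(reml=False)
        lr = max(0.0, 2.0 * (full.llf - null.llf))
        p = float(stats.chi2.sf(lr, df=X.shape[1]))
        curve = _fitted_curve(np.asarray(full.fe_params))
    except np.linalg.LinAlgError:
        # year-level variance collapses to the boundary; the random intercept
        # is inestimable and the fixed-effects F-test is the right reduction
        p = float(ols.f_pvalue)
        curve = _fitted_curve(ols.params)
    return SeasonalFit(deviance_explained=dev, p_value=p, fitted_monthly_curve=curve)


def _fitted_curve(params: np.ndarray) -> np.ndarray:
    months = np.arange(1, 13)
    Xm = np.column_stack([np.ones(12), harmonic_basis(months)])
    return Xm @ np.asarray(params)[: Xm.shape[1]]


def classify_ici(mean_ici: float) -> str:
    """Demographic class from mean ICI: small (< 0.6 s), large (> 0.8 s),
    intermediate on the closed interval [0.6, 0.8]."""
    if mean_ici <= 0:
        raise ValueError("mean_ici must be positive")
    if mean_ici < ICI_SMALL_MAX:
        return "small"
    if mean_ici > ICI_LARGE_MIN:
        return "large"
    return "intermediate"


def ici_monthly_distribution(
    sequences: pd.DataFrame, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-month relative density of sequence mean ICI over a fixed grid.

    ``sequences`` needs columns ``mean_ici``, ``month``, ``year``.  Each
    (year, month) cell is a histogram density normalized to unit area; the
    returned frame gives mean/min/max density across same-calendar-month
    years at each grid midpoint.  Months with no sequences are omitted.
    """
    if grid is None:
        grid = np.arange(0.25, 2.55, 0.05)
    mids = 0.5 * (grid[:-1] + grid[1:])
    rows = []
    for month, mgrp in sequences.groupby("month"):
        dens = []
        for _, ygrp in mgrp.groupby("year"):
            h, _ = np.histogram(ygrp["mean_ici"], bins=grid, density=True)
            dens.append(h)
        dens = np.array(dens)
        rows.append(
            pd.DataFrame(
                {
                    "month": month,
                    "ici": mids,
                    "mean_density": dens.mean(axis=0),
                    "min_density": dens.min(axis=0),
                    "max_density": dens.max(axis=0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def anova_log_ici(sequences: pd.DataFrame) -> dict:
    """Two-way ANOVA (no interaction) of ln(ICI) on month and year.

    Per-sequence ICIs are first aggregated to month x year cell means, so the
    factors' degrees of freedom follow the between-cells convention
    (levels - 1 each).  Returns F, p and df for both factors plus residual df.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = sequences.copy()
    if df["month"].nunique() < 2 or df["year"].nunique() < 2:
        raise ValueError("need >= 2 levels of both month and year")
    df["ln_ici"] = np.log(df["mean_ici"].astype(float))
    cells = df.groupby(["month", "year"], as_index=False)["ln_ici"].mean()
    n_cells = len(cells)
    df_m = cells["month"].nunique() - 1
    df_y = cells["year"].nunique() - 1
    if n_cells - df_m - df_y - 1 < 1:
        raise ValueError("singular design: not enough cells for residual df")
    model = ols("ln_ici ~ C(month) + C(year)", data=cells).fit()
    table = sm.stats.anova_lm(model, typ=2)
    # identical cell means: both effect and residual SS vanish; F is 0, not 0/0
    for term in ("C(month)", "C(year)"):
        ss_term = table.loc[term, "sum_sq"]
        if not np.isfinite(table.loc[term, "F"]) and (
            not np.isfinite(ss_term) or ss_term < 1e-20
        ):
            table.loc[term, "F"] = 0.0
            table.loc[term, "PR(>F)"] = 1.0
    return {
        "F_month": float(table.loc["C(month)", "F"]),
        "p_month": float(table.loc["C(month)", "PR(>F)"]),
        "df_month": int(table.loc["C(month)", "df"]),
        "F_year": float(table.loc["C(year)", "F"]),
        "p_year": float(table.loc["C(year)", "PR(>F)"]),
        "df_year": int(table.loc["C(year)", "df"]),
        "df_resid": int(table.loc["Residual", "df"]),
    }


def regress_ici_presence(monthly_mean_ici, monthly_percent) -> RegressionResult:
    """Ordinary least squares of monthly percent presence on monthly mean ICI."""
    x = np.asarray(monthly_mean_ici, dtype=float)
    y = np.asarray(monthly_percent, dtype=float)
    if x.size != y.size:
        raise ValueError("paired series must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 paired monthly values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: x is constant")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        r=float(fit.rvalue),
    )
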