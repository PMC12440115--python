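"""Comparison statistics for dispersion predictions against measurements.

The workflow mirrors how line-source dispersion output is judged against
monitor data: convert concentrations to ppb, average hourly predictions to
daily values, pair them with daily measurements by site and date, then score
each site or distance stratum with an ordinary-least-squares fit of measured
on predicted values (slope, intercept, R^2) and Willmott's index of
agreement. A site-level regression relates performance to local covariates
(land use, terrain, traffic, location).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: Conversion factor from ug/m^3 to ppb for NO2 at 25 degC and 1 atm
#: (molar volume 24.465 L/mol over molar mass 46.006 g/mol, rounded).
UGM3_TO_PPB_NO2 = 0.53

#: Distance strata (km) between monitoring site and nearest weather station;
#: half-open [a, b) bins, final bin closed on the left.
DISTANCE_EDGES_KM = [0.0, 2.0, 10.0, 20.0, 35.0, np.inf]
DISTANCE_LABELS = ["<2km", "2-10km", "10-20km", "20-35km", ">=35km"]


@dataclass
class EvalSummary:
    """Per-site or per-stratum agreement summary."""

    n: int
    slope: float
    intercept: float
    r_squared: float
    ioa: float


def ugm3_to_ppb(values, factor: float = UGM3_TO_PPB_NO2):
    """Convert concentrations from ug/m^3 to ppb by a fixed factor."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("concentrations must be finite")
    out = arr * factor
    return float(out) if arr.ndim == 0 else out


def daily_average(hourly: pd.Series) -> pd.DataFrame:
    """Average an hourly series to daily values.

    Returns a frame indexed by date with columns ``value`` (mean of the
    available hours) and ``n_hours`` (how many hours contributed; < 24 marks
    an incomplete day, e.g. when unfillable hours were dropped).
    """
    if not isinstance(hourly.index, pd.DatetimeIndex):
        raise ValueError("hourly series must be indexed by timestamps")
    clean = hourly.dropna()
    if clean.empty:
        raise ValueError("no valid hours to average")
    grouped = clean.groupby(clean.index.normalize())
    out = pd.DataFrame({"value": grouped.mean(), "n_hours": grouped.size()})
    out.index.name = "date"
    return out


def simple_linreg(pred, obs) -> tuple[float, float, float]:
    """OLS of observations on predictions: ``obs = slope * pred + intercept``.

    Returns ``(slope, intercept, r_squared)`` with R^2 the squared Pearson
    correlation. Requires n >= 3 and non-constant predictions.
    """
    x = np.asarray(pred, dtype=float)
    y = np.asarray(obs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pred and obs must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a regression")
    if np.ptp(x) == 0:
        raise ValueError("predictions have zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def index_of_agreement(obs, pred) -> float:
    """Willmott's index of agreement d in [0, 1]; 1 iff prediction == observation.

    ``d = 1 - sum((P - O)^2) / sum((|P - Obar| + |O - Obar|)^2)`` with Obar
    the observed mean. Two identical constant series (zero denominator) are
    perfect agreement by definition.
    """
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("obs and pred must be 1-d arrays of equal length")
    if o.size < 2:
        raise ValueError("need at least 2 pairs")
    obar = o.mean()
    num = np.sum((p - o) ** 2)
    den = np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2)
    if den == 0:
        return 1.0
    return float(1.0 - num / den)


def evaluate_pairs(pred, obs) -> EvalSummary:
    """Regression and agreement summary for one set of prediction pairs."""
    x = np.asarray(pred, dtype=float)
    slope, intercept, r2 = simple_linreg(x, obs)
    return EvalSummary(
        n=int(x.size),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        ioa=index_of_agreement(obs, x),
    )


def stratify_by_distance(pairs: pd.DataFrame) -> pd.DataFrame:
    """Pooled per-stratum summaries by site-to-station distance.

    ``pairs`` needs columns ``predicted``, ``observed`` and
    ``station_distance_km``. Site-days are pooled within each stratum; bins
    with too few pairs (or constant predictions) report NaN statistics but a
    true count. Every finite non-negative distance maps to exactly one bin.
    """
    for col in ("predicted", "observed", "station_distance_km"):
        if col not in pairs.columns:
            raise ValueError(f"pairs table is missing column {col!r}")
    bins = pd.cut(
        pairs["station_distance_km"],
        DISTANCE_EDGES_KM,
        labels=DISTANCE_LABELS,
        right=False,
        include_lowest=True,
    )
    rows = []
    for label in DISTANCE_LABELS:
        sub = pairs.loc[bins == label]
        try:
            summ = evaluate_pairs(sub["predicted"].to_numpy(), sub["observed"].to_numpy())
            rows.append(
                {"stratum": label, "n": summ.n, "slope": summ.slope,
                 "intercept": summ.intercept, "r_squared": summ.r_squared,
                 "ioa": summ.ioa}
            )
        except ValueError:
            rows.append(
                {"stratum": label, "n": len(sub), "slope": np.nan,
                 "intercept": np.nan, "r_squared": np.nan, "ioa": np.nan}
            )
    return pd.DataFrame(rows).set_index("stratum")


def summarize_by_site(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-site agreement summaries with the site metadata carried along."""
    meta_cols = [
        c for c in pairs.columns
        if c not in ("site_id", "date", "predicted", "observed")
    ]
    rows = []
    for site_id, sub in pairs.groupby("site_id"):
        summ = evaluate_pairs(sub["predicted"].to_numpy(), sub["observed"].to_numpy())
        row = {"site_id": site_id, "n": summ.n, "slope": summ.slope,
               "intercept": summ.intercept, "r_squared": summ.r_squared,
               "ioa": summ.ioa}
        for c in meta_cols:
            row[c] = sub[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_id")


def relative_ioa_difference(ioa_a, ioa_b):
    """Relative difference (%) between two agreement indices: 100 (a - b) / a.

    Positive means the first input (e.g. forecast-driven meteorology)
    outperformed the second (e.g. station observations); negative the
    opposite.
    """
    a = np.asarray(ioa_a, dtype=float)
    b = np.asarray(ioa_b, dtype=float)
    if np.any(a <= 0):
        raise ValueError("reference IOA must be positive")
    out = 100.0 * (a - b) / a
    return float(out) if a.ndim == 0 else out


def site_covariate_regression(
    table: pd.DataFrame,
    response: str = "ioa",
    covariates: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OLS of a site-level statistic on site covariates.

    Returns a frame indexed by term (``const`` + covariates) with columns
    ``coef``, ``std_err``, ``p_value`` and ``significant`` (p < ``alpha``).
    Zero-variance or exactly collinear covariates raise ``ValueError`` naming
    the offender(s); the site count must exceed the number of covariates.
    """
    if covariates is None:
        covariates = [
            c for c in table.columns
            if c != response and pd.api.types.is_numeric_dtype(table[c])
        ]
    if response not in table.columns:
        raise ValueError(f"response column {response!r} not in table")
    data = table[[response, *covariates]].dropna()
    n, p = len(data), len(covariates)
    if n <= p + 1:
        raise ValueError(f"need more sites ({n}) than model terms ({p + 1})")
    X = data[covariates].to_numpy(dtype=float)
    for j, c in enumerate(covariates):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {c!r} has zero variance")
    corr = np.corrcoef(X, rowvar=False)
    for i in range(p):
        for j in range(i + 1, p):
            if abs(corr[i, j]) > 1 - 1e-10:
                raise ValueError(
                    f"covariates {covariates[i]!r} and {covariates[j]!r} are collinear"
                )
    model = sm.OLS(data[response].to_numpy(dtype=float), sm.add_constant(X))
    fit = model.fit()
    out = pd.DataFrame(
        {
            "coef": fit.params,
            "std_err": fit.bse,
            "p_value": fit.pvalues,
        },
    )
    out.index = ["const", *covariates]
    out["significant"] = out["p_value"] < alpha
    return out
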