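"""Change detection on weekly tweet counts: AR prewhitening + CUSUM.

Weekly counts of query hits are serially correlated (arrival pulses span
several weeks, and chatter begets chatter), which violates the independence
assumption of control charts.  The procedure therefore runs in four steps:

1. inspect the ACF and PACF of the weekly series;
2. fit an autoregressive model AR(p), with p either chosen automatically
   from the PACF or supplied by hand;
3. check the residuals for independence (residual ACF and a Ljung-Box
   portmanteau test);
4. run a two-sided CUSUM chart on the standardized residuals
   z_t = e_t / sigma_hat with reference value k and decision interval h.

The chart accumulates C+_t = max(0, C+_{t-1} + z_t - k) and
C-_t = min(0, C-_{t-1} + z_t + k); the process is out of control when C+
exceeds the upper decision bound h (UDB) or C- falls below -h (LDB).  The
defaults k = 0.5, h = 5 are the conventional settings for detecting a
one-standard-deviation shift (k = shift/2, five-sigma decision interval).

AR fitting is conditional least squares: ordinary least squares of y_t on
(1, y_{t-1}, ..., y_{t-p}) over t = p..n-1, yielding n - p residuals whose
mean is zero by the normal equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.ar_model import AutoReg

from .tweetstore import CoveragePeriod, TweetRecord

__all__ = [
    "WeeklySeries",
    "ARFit",
    "CusumChart",
    "Diagnostics",
    "ConstantSeriesError",
    "weekly_counts",
    "acf",
    "pacf",
    "significance_bound",
    "select_order",
    "fit_ar",
    "diagnose",
    "standardize",
    "cusum",
    "detect_events",
    "detect_arrivals",
]

DEFAULT_K = 0.5
DEFAULT_H = 5.0


class ConstantSeriesError(ValueError):
    """Autocorrelation is undefined for a constant series."""


@dataclass(frozen=True)
class WeeklySeries:
    """Zero-filled weekly hit counts with a missing-coverage mask.

    ``missing`` marks weeks lying entirely inside a capture gap (their zero
    is absence of data, not absence of tweets); ``partial`` flags weeks
    that overlap a gap on some but not all days.
    """

    week_starts: tuple[date, ...]
    counts: np.ndarray
    missing: np.ndarray
    partial: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        missing = np.asarray(self.missing, dtype=bool)
        partial = (
            np.zeros(len(counts), dtype=bool)
            if self.partial is None
            else np.asarray(self.partial, dtype=bool)
        )
        if not (len(self.week_starts) == len(counts) == len(missing) == len(partial)):
            raise ValueError("week_starts, counts and masks must align")
        for a, b in zip(self.week_starts, self.week_starts[1:]):
            if (b - a).days != 7:
                raise ValueError("week starts must be consecutive, 7 days apart")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts[missing].any():
            raise ValueError("missing weeks carry no count")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "missing", missing)
        object.__setattr__(self, "partial", partial)

    def __len__(self) -> int:
        return len(self.week_starts)

    def longest_observed_segment(self) -> tuple[int, int]:
        """(start, stop) of the longest run of non-missing weeks, half-open."""
        best = (0, 0)
        run_start = None
        for i, miss in enumerate(list(self.missing) + [True]):
            if not miss and run_start is None:
                run_start = i
            elif miss and run_start is not None:
                if i - run_start > best[1] - best[0]:
                    best = (run_start, i)
                run_start = None
        return best


@dataclass(frozen=True)
class ARFit:
    order: int
    intercept: float
    coefficients: np.ndarray
    residuals: np.ndarray
    sigma: float
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, float))
        object.__setattr__(self, "residuals", np.asarray(self.residuals, float))
        if len(self.residuals) != self.n - self.order:
            raise ValueError("conditional fit must yield n - p residuals")


@dataclass(frozen=True)
class Diagnostics:
    n_acf_exceedances: int
    ljung_box_stat: float
    ljung_box_pvalue: float
    independent: bool


@dataclass(frozen=True)
class CusumChart:
    z: np.ndarray
    k: float
    h: float
    c_plus: np.ndarray
    c_minus: np.ndarray
    violations: tuple[tuple[int, str], ...]

    def upper_violations(self) -> list[int]:
        return [i for i, d in self.violations if d == "upper"]


def _monday_on_or_before(day: date) -> date:
    return day - timedelta(days=day.weekday())


def weekly_counts(
    hits: Sequence[TweetRecord],
    period: CoveragePeriod,
    week_start_day: int = 0,
) -> WeeklySeries:
    """Bucket hits into calendar weeks covering the period (Monday start).

    Weeks whose every in-period day falls in a capture gap are masked
    missing; weeks overlapping a gap on some days keep the count from the
    available days and are flagged partial.
    """
    first = _monday_on_or_before(period.start)
    if week_start_day:
        offset = (period.start.weekday() - week_start_day) % 7
        first = period.start - timedelta(days=offset)
    starts: list[date] = []
    cur = first
    while cur < period.end:
        starts.append(cur)
        cur += timedelta(days=7)
    counts = np.zeros(len(starts), dtype=int)
    for rec in hits:
        day = rec.date
        if not period.contains(day):
            raise ValueError(f"hit {rec.id} outside coverage period")
        if period.in_gap(day):
            continue  # captured nothing reliable that day
        idx = (day - first).days // 7
        counts[idx] += 1
    missing = np.zeros(len(starts), dtype=bool)
    partial = np.zeros(len(starts), dtype=bool)
    for i, ws in enumerate(starts):
        days = [ws + timedelta(days=d) for d in range(7)]
        days = [d for d in days if period.start <= d < period.end]
        gap_days = sum(period.in_gap(d) for d in days)
        if days and gap_days == len(days):
            missing[i] = True
            counts[i] = 0
        elif gap_days:
            partial[i] = True
    return WeeklySeries(tuple(starts), counts, missing, partial)


def _autocovariance(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(x)
    xm = x - x.mean()
    return np.array([(xm[: n - k] * xm[k:]).sum() / n for k in range(max_lag + 1)])


def significance_bound(n: int) -> float:
    """Approximate 95% white-noise band for sample (P)ACF: 1.96 / sqrt(n)."""
    return 1.96 / np.sqrt(n)


def acf(series: Sequence[float], max_lag: int) -> np.ndarray:
    """Sample autocorrelations r_0..r_max_lag (biased denominator, r_0 = 1)."""
    x = np.asarray(series, float)
    if len(x) <= max_lag:
        raise ValueError("series must be longer than max_lag")
    gamma = _autocovariance(x, max_lag)
    if gamma[0] == 0.0:
        raise ConstantSeriesError("autocorrelation undefined for constant series")
    return gamma / gamma[0]


def pacf(series: Sequence[float], max_lag: int) -> np.ndarray:
    """Partial autocorrelations via the Durbin-Levinson recursion.

    Entry 0 is 1 by convention; entry 1 equals the lag-1 autocorrelation
    exactly.  For an AR(p) process pacf[p] estimates phi_p and entries
    beyond p fluctuate around zero.
    """
    rho = acf(series, max_lag)
    out = np.ones(max_lag + 1)
    if max_lag == 0:
        return out
    phi_prev = np.zeros(max_lag + 1)
    phi_prev[1] = rho[1]
    out[1] = rho[1]
    for k in range(2, max_lag + 1):
        num = rho[k] - np.dot(phi_prev[1:k], rho[1:k][::-1])
        den = 1.0 - np.dot(phi_prev[1:k], rho[1:k])
        phi_k = np.zeros(max_lag + 1)
        phi_k[k] = num / den
        for j in range(1, k):
            phi_k[j] = phi_prev[j] - phi_k[k] * phi_prev[k - j]
        out[k] = phi_k[k]
        phi_prev = phi_k
    return out


def select_order(series: Sequence[float], max_lag: int = 8) -> int:
    """Automatic AR order: largest lag whose |PACF| exceeds the significance
    band, with the band Bonferroni-adjusted for the ``max_lag`` lags jointly
    inspected.

    This mechanizes how a PACF plot is actually read: an analyst looks for
    the cutoff and discounts isolated spikes that barely clear the per-lag
    95% band, since examining several lags at once inflates the chance of
    such spikes.  Controlling the family-wise level keeps the selected
    order from being dragged upward by that multiplicity.  A hand-chosen
    order can always be passed straight to :func:`fit_ar` instead.
    """
    from scipy.stats import norm

    x = np.asarray(series, float)
    p_vals = pacf(x, max_lag)
    bound = norm.ppf(1.0 - 0.025 / max_lag) / np.sqrt(len(x))
    above = [lag for lag in range(1, max_lag + 1) if abs(p_vals[lag]) > bound]
    return max(above) if above else 0


def fit_ar(series: Sequence[float], p: int) -> ARFit:
    """Conditional least-squares AR(p) fit.

    p = 0 degenerates to mean-centering.  The guard n >= 5p + 10 keeps the
    design matrix comfortably overdetermined for short weekly series.
    """
    y = np.asarray(series, float)
    n = len(y)
    if p < 0:
        raise ValueError("order must be >= 0")
    if n < 5 * p + 10:
        raise ValueError(f"series too short for AR({p}): need >= {5 * p + 10} points")
    if np.ptp(y) == 0.0:
        raise ConstantSeriesError("cannot fit AR to a constant series")
    if p == 0:
        resid = y - y.mean()
        return ARFit(0, float(y.mean()), np.array([]), resid,
                     float(np.std(resid, ddof=1)), n)
    res = AutoReg(y, lags=p, trend="c").fit()
    resid = np.asarray(res.resid, float)
    return ARFit(
        order=p,
        intercept=float(res.params[0]),
        coefficients=np.asarray(res.params[1:], float),
        residuals=resid,
        sigma=float(np.std(resid, ddof=1)),
        n=n,
    )


def diagnose(fit: ARFit, max_lag: int = 10) -> Diagnostics:
    """Residual-independence report: ACF exceedances + Ljung-Box at max_lag.

    The residuals pass ("independent") when at most one of the first
    max_lag residual autocorrelations leaves the 95% band and the
    portmanteau p-value exceeds 0.05.
    """
    e = fit.residuals
    if len(e) <= max_lag:
        raise ValueError("residual series must be longer than max_lag")
    r = acf(e, max_lag)
    bound = significance_bound(len(e))
    n_exc = int(np.sum(np.abs(r[1:]) > bound))
    lb = acorr_ljungbox(e, lags=[max_lag], model_df=0)
    stat = float(lb["lb_stat"].iloc[0])
    pval = float(lb["lb_pvalue"].iloc[0])
    return Diagnostics(n_exc, stat, pval, independent=(n_exc <= 1 and pval > 0.05))


def standardize(fit: ARFit) -> np.ndarray:
    """z_t = e_t / sigma_hat; unit sample standard deviation by construction."""
    if fit.sigma == 0.0:
        raise ZeroDivisionError("cannot standardize: residual sd is zero")
    return fit.residuals / fit.sigma


def cusum(z: Sequence[float], k: float = DEFAULT_K, h: float = DEFAULT_H) -> CusumChart:
    """Tabular two-sided CUSUM of standardized residuals.

    C+_t = max(0, C+_{t-1} + z_t - k); C-_t = min(0, C-_{t-1} + z_t + k);
    a violation is recorded wherever C+ > h (upper) or C- < -h (lower).
    """
    z = np.asarray(z, float)
    if not np.isfinite(z).all():
        raise ValueError("standardized residuals must be finite")
    c_plus = np.zeros(len(z))
    c_minus = np.zeros(len(z))
    cp = cm = 0.0
    violations: list[tuple[int, str]] = []
    for t, zt in enumerate(z):
        cp = max(0.0, cp + zt - k)
        cm = min(0.0, cm + zt + k)
        c_plus[t] = cp
        c_minus[t] = cm
        if cp > h:
            violations.append((t, "upper"))
        if cm < -h:
            violations.append((t, "lower"))
    return CusumChart(z, k, h, c_plus, c_minus, tuple(violations))


def detect_events(
    chart: CusumChart,
    weeks: WeeklySeries,
    order: int,
    segment_start: int = 0,
) -> list[tuple[date, str]]:
    """Map chart violations back to calendar weeks.

    Residual index t corresponds to week segment_start + order + t: the
    conditional AR fit consumes the first ``order`` weeks of the fitted
    segment as lagged regressors.
    """
    n_weeks = len(weeks.week_starts) - segment_start
    if len(chart.z) != n_weeks - order:
        raise ValueError(
            f"chart length {len(chart.z)} != weeks in segment {n_weeks} minus order {order}"
        )
    return [
        (weeks.week_starts[segment_start + order + t], direction)
        for t, direction in chart.violations
    ]


def detect_arrivals(
    weeks: WeeklySeries,
    order: int | None = None,
    k: float = DEFAULT_K,
    h: float = DEFAULT_H,
    max_lag: int = 8,
) -> dict:
    """Full pipeline on one weekly series: order selection (optional), AR
    fit, diagnostics, CUSUM, and calendar-mapped events.

    Fits on the longest contiguous run of non-missing weeks; shorter
    gap-separated segments are ignored.  Returns a dict with keys
    ``order, fit, diagnostics, chart, events, segment``.
    """
    lo, hi = weeks.longest_observed_segment()
    y = weeks.counts[lo:hi].astype(float)
    if order is None:
        order = select_order(y, max_lag=min(max_lag, max(1, len(y) // 4)))
    if len(y) < 5 * order + 10:
        raise ValueError(
            f"observed segment of {len(y)} weeks too short for AR({order})"
        )
    fit = fit_ar(y, order)
    diag = diagnose(fit, max_lag=min(10, len(fit.residuals) - 1))
    chart = cusum(standardize(fit), k=k, h=h)
    sub = WeeklySeries(
        weeks.week_starts[lo:hi],
        weeks.counts[lo:hi],
        weeks.missing[lo:hi],
        weeks.partial[lo:hi],
    )
    events = detect_events(chart, sub, fit.order)
    return {
        "order": fit.order,
        "fit": fit,
        "diagnostics": diag,
        "chart": chart,
        "events": events,
        "segment": (lo, hi),
    }
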