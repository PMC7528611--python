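"""Circadian rhythmicity detection and peak metrics for long-term recordings.

A unit is called rhythmic when its firing-rate profile over ≥ 26 h is better
fit by a sinusoid ``r(t) = m + A·cos(2π(t − φ)/T)`` with period constrained to
20–28 h than by a first-order polynomial ``r(t) = a + b·t``.  "Better fit" is
decided by an information criterion computed from the least-squares residuals
of both models on a coarsely re-binned series (15-min bins by default; at the
raw 60-s binning the residuals are Poisson-dominated and the comparison is
noisy).  The default criterion is BIC; AICc and an extra-sum-of-squares F-test
are available for sensitivity analysis.

For rhythmic units, the time of peak firing, peak width (duration above 50%
of peak within the surrounding 24-h window), peak-trough amplitude and 24-h
mean rate are measured on the 60-s binned series smoothed with a 2-h boxcar,
with the peak searched over one fitted period centred mid-recording so a
recording slightly longer than one cycle contributes exactly one peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .data_io import RecordingSession, SpikeTrain, projected_zt

__all__ = [
    "RateSeries",
    "RhythmResult",
    "binned_rate",
    "smooth_boxcar",
    "fit_sinusoid",
    "fit_rhythm_models",
    "peak_metrics",
    "rhythm_table",
    "MIN_SPAN_H",
    "PERIOD_BOUNDS_H",
]

MIN_SPAN_H = 26.0
PERIOD_BOUNDS_H = (20.0, 28.0)


@dataclass
class RateSeries:
    bin_starts: np.ndarray  # s
    bin_width: float  # s
    rate: np.ndarray  # Hz
    smoothed: bool = False
    smoothing_window: float = 0.0  # h

    @property
    def span_hours(self) -> float:
        return (self.bin_starts[-1] + self.bin_width - self.bin_starts[0]) / 3600.0

    @property
    def centers_h(self) -> np.ndarray:
        return (self.bin_starts + self.bin_width / 2) / 3600.0


@dataclass
class RhythmResult:
    unit_id: str
    rhythmic: bool
    period: float  # h (nan when not rhythmic)
    phase: float  # h, fitted acrophase offset of the sinusoid
    amplitude_fit: float  # Hz, fitted sinusoid amplitude
    peak_time_zt: float  # h
    peak_time_rec: float  # h since recording start
    peak_width: float  # h
    peak_trough_amplitude: float  # Hz
    mean_rate_24h: float  # Hz
    criterion_sin: float
    criterion_lin: float
    flag: str = ""  # "", "degenerate", "no_convergence"


def binned_rate(
    train: SpikeTrain, bin_width: float = 60.0, duration: float | None = None
) -> RateSeries:
    """Firing rate (Hz) in contiguous fixed-width bins from t = 0.

    An empty train yields an all-zero series over ``duration``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t = train.spike_times
    if duration is None:
        duration = float(t[-1]) + bin_width if t.size else bin_width
    n_bins = int(np.ceil(duration / bin_width - 1e-9))
    counts = np.bincount(
        np.minimum((t / bin_width).astype(np.int64), n_bins - 1), minlength=n_bins
    ) if t.size else np.zeros(n_bins, dtype=np.int64)
    return RateSeries(
        bin_starts=np.arange(n_bins) * bin_width,
        bin_width=bin_width,
        rate=counts / bin_width,
    )


def smooth_boxcar(series: RateSeries, window_h: float = 2.0) -> RateSeries:
    """Centred moving average; edges use the available (truncated) window.

    When the window spans an even number of bins the kernel is made symmetric
    by giving the two outermost bins half weight (an even flat kernel would
    shift the series by half a bin and distort ramps); constants and affine
    segments away from the edges pass through unchanged either way.
    """
    w = int(round(window_h * 3600.0 / series.bin_width))
    if w < 1:
        raise ValueError("smoothing window must be at least one bin")
    if w % 2:
        kernel = np.ones(w)
    else:
        kernel = np.ones(w + 1)
        kernel[0] = kernel[-1] = 0.5
    num = np.convolve(series.rate, kernel, mode="same")
    den = np.convolve(np.ones_like(series.rate), kernel, mode="same")
    return replace(
        series, rate=num / den, smoothed=True, smoothing_window=window_h
    )


def _rebin(series: RateSeries, bin_width: float) -> RateSeries:
    factor = int(round(bin_width / series.bin_width))
    if factor <= 1:
        return series
    n = series.rate.size // factor
    rate = series.rate[: n * factor].reshape(n, factor).mean(axis=1)
    return RateSeries(
        bin_starts=series.bin_starts[0] + np.arange(n) * bin_width,
        bin_width=bin_width,
        rate=rate,
    )


def _sinusoid_rss(t_h: np.ndarray, y: np.ndarray, period: float):
    """Profile least squares at fixed period (linear in mean/cos/sin)."""
    omega = 2 * np.pi / period
    X = np.column_stack([np.ones_like(t_h), np.cos(omega * t_h), np.sin(omega * t_h)])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(res[0]) if res.size else float(np.sum((y - X @ beta) ** 2))
    return rss, beta


def fit_sinusoid(
    t_h: np.ndarray, y: np.ndarray, period_bounds: tuple[float, float] = PERIOD_BOUNDS_H
) -> tuple[float, float, float, float, float]:
    """Constrained-period least-squares cosinor fit.

    Profiles the residual sum of squares over a period grid, refines the best
    grid point by bounded scalar minimisation, and returns
    ``(rss, mean, amplitude, acrophase_h, period_h)`` with amplitude ≥ 0.
    """
    grid = np.arange(period_bounds[0], period_bounds[1] + 1e-9, 0.25)
    rss_grid = [_sinusoid_rss(t_h, y, T)[0] for T in grid]
    T0 = grid[int(np.argmin(rss_grid))]
    lo = max(period_bounds[0], T0 - 0.3)
    hi = min(period_bounds[1], T0 + 0.3)
    opt = minimize_scalar(
        lambda T: _sinusoid_rss(t_h, y, T)[0], bounds=(lo, hi), method="bounded"
    )
    T = float(opt.x) if opt.fun <= min(rss_grid) else float(T0)
    rss, (m, a, b) = _sinusoid_rss(t_h, y, T)
    amp = float(np.hypot(a, b))
    phase = float(np.mod(np.arctan2(b, a) * T / (2 * np.pi), T))
    return rss, float(m), amp, phase, T


def _information_criterion(rss: float, n: int, p: int, kind: str) -> float:
    rss = max(rss, 1e-300)
    base = n * np.log(rss / n)
    if kind == "aicc":
        return base + 2 * p + 2 * p * (p + 1) / max(n - p - 1, 1)
    if kind == "bic":
        return base + p * np.log(n)
    raise ValueError(f"unknown criterion {kind!r}")


def fit_rhythm_models(
    series: RateSeries,
    fit_bin_s: float = 900.0,
    criterion: str = "bic",
    f_alpha: float = 0.01,
    smooth_h: float = 2.0,
    prep_time_zt: float = 0.0,
    unit_id: str = "",
) -> RhythmResult:
    """Sinusoid-vs-linear model comparison plus peak metrics for one unit.

    ``series`` must be the raw (unsmoothed) 60-s binned series spanning at
    least 26 h.  ``criterion`` is ``"bic"`` (default), ``"aicc"`` or
    ``"ftest"`` (extra-sum-of-squares F-test at ``f_alpha``, treating the
    linear model as the 2-parameter null).
    """
    if series.smoothed:
        raise ValueError("fit_rhythm_models expects an unsmoothed series")
    if series.span_hours < MIN_SPAN_H - 1e-9:
        raise ValueError(
            f"series spans {series.span_hours:.2f} h; >= {MIN_SPAN_H} h required"
        )
    coarse = _rebin(series, fit_bin_s)
    t_h, y = coarse.centers_h, coarse.rate
    n = y.size

    # linear competitor
    lin_coef = np.polyfit(t_h, y, 1)
    rss_lin = float(np.sum((y - np.polyval(lin_coef, t_h)) ** 2))
    rss_sin, m, amp, phase, period = fit_sinusoid(t_h, y)

    if criterion == "ftest":
        df1, df2 = 2, n - 4
        if rss_sin <= 0:
            rhythmic = True
            c_sin, c_lin = 0.0, np.inf
        else:
            f = ((rss_lin - rss_sin) / df1) / (rss_sin / df2)
            p_val = float(stats.f.sf(max(f, 0.0), df1, df2))
            rhythmic = p_val < f_alpha
            c_sin, c_lin = p_val, f_alpha
    else:
        c_sin = _information_criterion(rss_sin, n, 4, criterion)
        c_lin = _information_criterion(rss_lin, n, 2, criterion)
        rhythmic = c_sin < c_lin

    result = RhythmResult(
        unit_id=unit_id,
        rhythmic=bool(rhythmic),
        period=period if rhythmic else np.nan,
        phase=phase if rhythmic else np.nan,
        amplitude_fit=amp if rhythmic else np.nan,
        peak_time_zt=np.nan,
        peak_time_rec=np.nan,
        peak_width=np.nan,
        peak_trough_amplitude=np.nan,
        mean_rate_24h=float(np.mean(y)),
        criterion_sin=float(c_sin),
        criterion_lin=float(c_lin),
    )
    if rhythmic:
        smoothed = smooth_boxcar(series, smooth_h) if smooth_h > 0 else series
        metrics = peak_metrics(smoothed, period, prep_time_zt)
        result.peak_time_zt = metrics["peak_time_zt"]
        result.peak_time_rec = metrics["peak_time_rec"]
        result.peak_width = metrics["peak_width"]
        result.peak_trough_amplitude = metrics["peak_trough_amplitude"]
        result.mean_rate_24h = metrics["mean_rate_24h"]
        result.flag = metrics["flag"]
    return result


def peak_metrics(
    series: RateSeries, period: float = 24.0, prep_time_zt: float = 0.0
) -> dict:
    """Peak time, half-maximum width, peak-trough amplitude and 24-h mean.

    The peak is the global maximum of ``series`` within one ``period``-long
    window (capped at 24 h, so fitted periods longer than the recording can
    never pull in boxcar edge artifacts) centred on the series midpoint; the
    width is the total duration within the surrounding 24-h window over which
    the rate exceeds half the peak rate.  An all-zero (or constant) series
    yields NaN metrics with a ``degenerate`` flag.
    """
    t_h = series.centers_h
    mid = (t_h[0] + t_h[-1]) / 2
    half_span = min(period, 24.0) / 2
    in_window = (t_h >= mid - half_span) & (t_h <= mid + half_span)
    rate_w = series.rate[in_window]
    if rate_w.size == 0 or np.ptp(series.rate) == 0:
        return {
            "peak_time_rec": np.nan, "peak_time_zt": np.nan, "peak_width": np.nan,
            "peak_trough_amplitude": np.nan, "mean_rate_24h": float(np.mean(series.rate)),
            "flag": "degenerate",
        }
    i_peak = np.flatnonzero(in_window)[int(np.argmax(rate_w))]
    peak_t = float(t_h[i_peak])
    peak_rate = float(series.rate[i_peak])

    day = (t_h >= peak_t - 12.0) & (t_h <= peak_t + 12.0)
    rate_day = series.rate[day]
    width = float(np.sum(rate_day > 0.5 * peak_rate) * series.bin_width / 3600.0)
    return {
        "peak_time_rec": peak_t,
        "peak_time_zt": float(projected_zt(peak_t * 3600.0, prep_time_zt)),
        "peak_width": width,
        "peak_trough_amplitude": peak_rate - float(np.min(rate_day)),
        "mean_rate_24h": float(np.mean(rate_day)),
        "flag": "",
    }


def rhythm_table(
    session: RecordingSession,
    bin_width: float = 60.0,
    fit_bin_s: float = 900.0,
    criterion: str = "bic",
    smooth_h: float = 2.0,
    classes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-unit rhythmicity verdicts and peak metrics for a long-term session.

    Optionally joins a classification table (``unit_id, cell_class,
    opto_phenotype`` columns) on unit id.
    """
    rows = []
    for train in session.trains:
        series = binned_rate(train, bin_width, session.duration)
        res = fit_rhythm_models(
            series,
            fit_bin_s=fit_bin_s,
            criterion=criterion,
            smooth_h=smooth_h,
            prep_time_zt=session.prep_time_zt,
            unit_id=train.unit_id,
        )
        rows.append(
            {
                "unit_id": train.unit_id,
                "slice_id": train.slice_id,
                "rhythmic": res.rhythmic,
                "period_h": res.period,
                "peak_zt_h": res.peak_time_zt,
                "peak_rec_h": res.peak_time_rec,
                "width_h": res.peak_width,
                "amplitude_hz": res.peak_trough_amplitude,
                "mean_hz": res.mean_rate_24h,
                "criterion_sin": res.criterion_sin,
                "criterion_lin": res.criterion_lin,
                "flag": res.flag,
                "region": session.unit_region(train.unit_id),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "unit_id", "slice_id", "rhythmic", "period_h", "peak_zt_h", "peak_rec_h",
            "width_h", "amplitude_hz", "mean_hz", "criterion_sin", "criterion_lin",
            "flag", "region",
        ],
    )
    if classes is not None and len(classes):
        table = table.merge(
            classes[["unit_id", "cell_class", "opto_phenotype"]],
            on="unit_id",
            how="left",
        )
    return table
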