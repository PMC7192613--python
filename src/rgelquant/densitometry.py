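"""Lane-profile conditioning: background, spline smoothing, 1-mm intervals, cutoff.

The quantitation chain expects a background-subtracted, smoothed profile
resampled into fixed-width electrophoretic-distance intervals (default
Δd = 1 mm), with a signal-to-noise cutoff distance d_max beyond which the
intensity-to-count conversion would amplify noise (small sizes divide small
intensities). The cutoff defines the minimum detectable fragment size
sz_min = exp((d_max − a)/b) that the truncation correction later compensates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import LSQUnivariateSpline

from .calibration import LadderCalibration
from .profiles import IntensityProfile

__all__ = [
    "IntervalSeries",
    "subtract_background",
    "smooth_profile",
    "resample_intervals",
    "determine_cutoff",
]

logger = logging.getLogger(__name__)


@dataclass
class IntervalSeries:
    """Fixed-width distance intervals with characteristic sizes and intensities.

    ``intensity`` is the integrated smoothed densitometry over each interval
    (AU·mm); ``size`` is the fragment size at the interval midpoint under the
    attached calibration. Intervals with midpoint beyond ``d_max`` are flagged
    excluded and take no part in downstream sums.
    """

    mid: np.ndarray               # interval midpoints, mm
    width: float                  # Δd, mm
    size: np.ndarray              # characteristic size at midpoint, nt
    intensity: np.ndarray         # integrated smoothed intensity, AU·mm
    excluded: np.ndarray          # bool mask, True beyond the cutoff
    calibration: LadderCalibration
    d_max: float | None = None
    sz_min: float | None = None
    lane_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("interval width must be positive")

    @property
    def included(self) -> np.ndarray:
        return ~self.excluded

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mid_mm": self.mid,
            "width_mm": np.full(self.mid.size, self.width),
            "size_nt": self.size,
            "intensity_au": self.intensity,
            "excluded_flag": self.excluded.astype(int),
        })


# ---------------------------------------------------------------------------
# background subtraction


def _iterative_poly_baseline(x: np.ndarray, y: np.ndarray, degree: int,
                             n_iter: int = 50, clip_sd: float = 3.0) -> np.ndarray:
    """Robust polynomial baseline by iterative trimming of band points.

    Fit, then drop every point lying more than ``clip_sd`` robust SDs above
    the fit, refit, repeat to convergence. Bands (large positive excursions)
    are excluded while the fit stays centred on the baseline noise, so the
    estimate is unbiased in signal-free stretches no matter how large the
    bands are.
    """
    # stage 1: asymmetric least squares pushes the line to the lower envelope
    # (band points, which sit far above, get weight p << 1)
    p = 0.01
    w = np.ones(x.size)
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    for _ in range(n_iter):
        base = np.polynomial.polynomial.polyval(x, coeffs)
        w_new = np.where(y > base, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
        coeffs = np.polynomial.polynomial.polyfit(x, y, degree, w=w)
    # stage 2: unbiased OLS through the points the envelope identifies as
    # baseline (within a few noise SDs above it); bands stay excluded
    base = np.polynomial.polynomial.polyval(x, coeffs)
    resid = y - base
    neg = resid[resid < 0]
    sigma = max(1.4826 * np.median(np.abs(neg)) if neg.size else 0.0, 1e-12)
    mask = resid < clip_sd * sigma
    if mask.sum() >= degree + 2:
        coeffs = np.polynomial.polynomial.polyfit(x[mask], y[mask], degree)
    return np.polynomial.polynomial.polyval(x, coeffs)


def subtract_background(profile: IntensityProfile, method: str = "linear_baseline",
                        empty: IntensityProfile | None = None,
                        degree: int = 1) -> IntensityProfile:
    """Remove the lane baseline; negative residuals are clipped to 0.

    Methods: ``constant`` subtracts the profile minimum; ``linear_baseline``
    fits a low-order polynomial lower envelope by iterative clipping;
    ``empty_lane`` subtracts an empty-lane profile (interpolated onto the
    lane's grid). The estimate is recorded in the output metadata.
    """
    x, y = profile.distances, profile.intensities
    if method == "constant":
        base = np.full_like(y, float(y.min()))
        desc = f"constant {y.min():.6g}"
    elif method == "linear_baseline":
        base = _iterative_poly_baseline(x, y, degree)
        desc = f"poly degree {degree}"
    elif method == "empty_lane":
        if empty is None:
            raise ValueError("empty_lane background method requires an empty-lane profile")
        base = np.interp(x, empty.distances, empty.intensities)
        desc = f"empty lane {empty.lane_id}"
    else:
        raise ValueError(f"unknown background method {method!r}")
    out = np.clip(y - base, 0.0, None)
    return profile.replace(out, background_method=method, background_estimate=desc,
                           background_mean=float(np.mean(base)))


# ---------------------------------------------------------------------------
# smoothing spline


def _gradient_quantile_knots(x: np.ndarray, y: np.ndarray, n_knots: int) -> np.ndarray:
    """Interior knots at quantiles of the cumulative absolute gradient.

    Knots crowd where the profile changes fast; a small uniform floor keeps
    flat stretches from being left knot-free. Knots are snapped to data
    positions with at least two samples between neighbours so the
    least-squares fit is well posed.
    """
    # gradient of a lightly pre-smoothed trace: on raw data the noise
    # gradient would dominate and scatter the knots, and placement must be
    # stable when smoothing runs on an already-smoothed profile
    step = float(np.median(np.diff(x)))
    grad = np.abs(np.gradient(ndimage.gaussian_filter1d(y, sigma=max(1.0 / step, 1.0)), x))
    # blend with a uniform floor (~1/3 of total weight) so flat stretches
    # keep knots; pure gradient weighting starves them on smooth curves
    weight = grad + max(grad.mean(), 1e-12) * 0.5 + 1e-300
    cdf = np.cumsum(weight)
    cdf = (cdf - cdf[0]) / (cdf[-1] - cdf[0])
    q = np.linspace(0.0, 1.0, n_knots + 2)[1:-1]
    idx = np.searchsorted(cdf, q)
    idx = np.clip(idx, 4, x.size - 5)
    # enforce >= 3 samples between knots (and from the boundaries)
    for i in range(1, idx.size):
        idx[i] = max(idx[i], idx[i - 1] + 3)
    idx = idx[idx <= x.size - 5]
    return x[idx]


def smooth_profile(profile: IntensityProfile, n_knots: int = 15,
                   placement: str = "gradient") -> IntensityProfile:
    """Cubic least-squares spline with ``n_knots`` interior knots; clipped at 0.

    ``placement="gradient"`` places knots at quantiles of the cumulative
    absolute intensity gradient (deterministic stand-in for free-knot
    optimisation); ``"uniform"`` spaces them evenly.
    """
    x, y = profile.distances, profile.intensities
    if x.size < n_knots + 4:
        raise ValueError(f"need at least {n_knots + 4} samples to place {n_knots} knots")
    if placement == "gradient":
        knots = _gradient_quantile_knots(x, y, n_knots)
    elif placement == "uniform":
        knots = np.linspace(x[0], x[-1], n_knots + 2)[1:-1]
    else:
        raise ValueError(f"unknown knot placement {placement!r}")
    try:
        spline = LSQUnivariateSpline(x, y, knots, k=3)
    except ValueError:
        # degenerate adaptive placement; uniform knots always satisfy the
        # interlacing condition on a regular grid
        knots = np.linspace(x[0], x[-1], n_knots + 2)[1:-1]
        spline = LSQUnivariateSpline(x, y, knots, k=3)
    smoothed = np.clip(spline(x), 0.0, None)
    return profile.replace(smoothed, smoothing=f"lsq_spline_{len(knots)}knots_{placement}")


# ---------------------------------------------------------------------------
# interval resampling


def resample_intervals(profile: IntensityProfile, cal: LadderCalibration,
                       delta_d: float = 1.0, lane_id: str | None = None) -> IntervalSeries:
    """Integrate the smoothed profile over Δd-wide intervals.

    Interval intensity is the trapezoidal integral over the interval (equal to
    mean intensity × Δd); the characteristic size is taken at the interval
    midpoint, sz = exp((mid − a)/b).
    """
    if delta_d <= 0:
        raise ValueError("delta_d must be positive")
    x, y = profile.distances, profile.intensities
    n = int(np.floor((x[-1] - x[0]) / delta_d + 1e-9))
    if n < 1:
        raise ValueError("profile narrower than one interval")
    edges = x[0] + delta_d * np.arange(n + 1)
    cum = np.concatenate([[0.0], np.cumsum(np.diff(x) * 0.5 * (y[1:] + y[:-1]))])
    intensity = np.diff(np.interp(edges, x, cum))
    mid = 0.5 * (edges[:-1] + edges[1:])
    size = cal.size_at(mid)
    return IntervalSeries(
        mid=mid, width=float(delta_d), size=size, intensity=intensity,
        excluded=np.zeros(n, dtype=bool), calibration=cal,
        lane_id=lane_id if lane_id is not None else profile.lane_id,
        metadata=dict(profile.metadata))


# ---------------------------------------------------------------------------
# signal-to-noise cutoff


def _rolling_sd(y: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(y).rolling(window=max(window, 2), center=True, min_periods=2).std()
    return s.bfill().ffill().to_numpy()


def determine_cutoff(series: IntervalSeries, lane_profile: IntensityProfile,
                     empty_profile: IntensityProfile | None = None,
                     window: float = 3.0, ratio_threshold: float = 1.5,
                     manual_dmax: float | None = None) -> IntervalSeries:
    """Set d_max where raw-lane fluctuations fall to empty-lane levels.

    d_max is the smallest distance beyond which the rolling SD (window in mm)
    of the raw lane stays below ``ratio_threshold`` times the empty lane's
    noise level for every subsequent window. Two robustness measures keep
    noise from masquerading as signal: the empty lane's rolling SD is
    median-smoothed, and exceedance runs shorter than half a window are
    ignored (real bands exceed the threshold in sustained stretches; noise
    only in short bursts). A ``manual_dmax`` override honours supervised
    cutoff selection; if no crossing is found, d_max is the lane end and a
    warning is recorded.
    """
    x = lane_profile.distances
    warn = None
    if manual_dmax is not None:
        d_max = float(manual_dmax)
    else:
        if empty_profile is None:
            raise ValueError("automatic cutoff requires an empty-lane profile")
        w = max(int(round(window / lane_profile.step)), 2)
        sd_lane = _rolling_sd(lane_profile.intensities, w)
        empty = empty_profile.interpolate_to(x)
        sd_empty = _rolling_sd(empty.intensities, w)
        sd_empty = (pd.Series(sd_empty).rolling(window=5 * w, center=True, min_periods=1)
                    .median().to_numpy())
        quiet = sd_lane < ratio_threshold * np.maximum(sd_empty, 1e-12)
        # drop exceedance runs shorter than two windows: a single noise patch
        # keeps the rolling SD elevated for about one window, while genuine
        # band signal exceeds the threshold in much longer stretches
        min_run = max(2 * w, 2)
        loud = np.flatnonzero(~quiet)
        if loud.size:
            splits = np.split(loud, np.flatnonzero(np.diff(loud) > 1) + 1)
            for run in splits:
                if run.size < min_run:
                    quiet[run] = True
        tail_quiet = np.flip(np.logical_and.accumulate(np.flip(quiet)))
        hits = np.flatnonzero(tail_quiet)
        if hits.size:
            d_max = float(x[hits[0]])
        else:
            d_max = float(x[-1])
            warn = "no signal-to-noise crossing found; cutoff set to lane end"
            logger.warning("lane %s: %s", series.lane_id, warn)
    sz_min = float(series.calibration.size_at(d_max))
    excluded = series.mid > d_max
    meta = dict(series.metadata)
    meta.update(cutoff_window_mm=window, cutoff_ratio_threshold=ratio_threshold,
                cutoff_manual=manual_dmax is not None)
    if warn:
        meta["cutoff_warning"] = warn
    logger.info("lane %s: d_max=%.2f mm, sz_min=%.1f nt, %d/%d intervals excluded",
                series.lane_id, d_max, sz_min, int(excluded.sum()), excluded.size)
    return dc_replace(series, excluded=excluded, d_max=d_max, sz_min=sz_min,
                      metadata=meta)
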