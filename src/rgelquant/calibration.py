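"""Log-linear electrophoretic mobility calibration from the ladder lane.

Migration distance of single-stranded DNA on a denaturing gel is, over the
resolving range, linear in the log of fragment size. The calibration is an
ordinary least-squares fit of distance on ln(size) over the ladder peaks,

    d = a + b·ln(sz)   ⇒   sz = exp((d − a) / b),

fit in exactly that direction (d is the noisy observable; inverting the fit
analytically is not the same as regressing ln(sz) on d).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, signal, stats

from .profiles import IntensityProfile

__all__ = ["LadderCalibration", "detect_ladder_peaks", "fit_ladder", "size_at"]

logger = logging.getLogger(__name__)


@dataclass
class LadderCalibration:
    """Fitted migration model d = a + b·ln(sz).

    a is the distance (mm) at which a 1-nt fragment would run; b (mm per
    ln-nt) is negative when distance is measured from the well.
    """

    a: float
    b: float
    peaks: list = field(default_factory=list)   # (distance mm, size nt) used in fit
    r_squared: float = float("nan")
    residual_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.b == 0:
            raise ValueError("calibration slope b must be nonzero")

    def size_at(self, d):
        """Fragment size (nt) at distance d (mm): exp((d − a)/b)."""
        return np.exp((np.asarray(d, dtype=float) - self.a) / self.b)

    def distance_of(self, sz):
        """Inverse map: band-center distance of a fragment of size sz."""
        return self.a + self.b * np.log(np.asarray(sz, dtype=float))

    def in_fitted_range(self, d) -> np.ndarray:
        """True where d lies within the distance span of the fitted peaks."""
        if not self.peaks:
            return np.ones_like(np.asarray(d, dtype=float), dtype=bool)
        dd = np.array([p[0] for p in self.peaks])
        d = np.asarray(d, dtype=float)
        return (d >= dd.min()) & (d <= dd.max())

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "r_squared": self.r_squared,
                "residual_sd": self.residual_sd,
                "peaks": [[float(d), float(s)] for d, s in self.peaks]}

    @classmethod
    def from_dict(cls, payload: dict) -> "LadderCalibration":
        return cls(a=float(payload["a"]), b=float(payload["b"]),
                   peaks=[tuple(p) for p in payload.get("peaks", [])],
                   r_squared=float(payload.get("r_squared", float("nan"))),
                   residual_sd=float(payload.get("residual_sd", float("nan"))))


def size_at(d, cal: LadderCalibration):
    """Functional alias for :meth:`LadderCalibration.size_at`."""
    return cal.size_at(d)


def detect_ladder_peaks(ladder_profile: IntensityProfile,
                        expected_sizes: Sequence[float],
                        smooth_sigma_mm: float = 0.3,
                        prominence: float | None = None):
    """Find ladder band centers and assign them to the expected sizes.

    Bands are local maxima of the lightly smoothed profile passing a
    prominence filter (default 5× the median absolute deviation of the
    profile). Assignment is by rank order of distance — the largest expected
    size gets the smallest distance — which is valid because mobility is
    monotone in size. Expected sizes left without a detected band are
    reported via a warning, never silently dropped.

    Returns a list of ``(distance_mm, size_nt)`` pairs, size-descending.
    """
    sizes = sorted(set(float(s) for s in expected_sizes), reverse=True)
    if len(sizes) < 2:
        raise ValueError("need at least 2 expected ladder sizes")
    y = ladder_profile.intensities
    if np.ptp(y) == 0:
        raise ValueError("no peaks: ladder profile has zero variance")
    step = ladder_profile.step
    if smooth_sigma_mm > 0:
        y = ndimage.gaussian_filter1d(y, sigma=smooth_sigma_mm / step)
    if prominence is None:
        mad = float(np.median(np.abs(y - np.median(y))))
        prominence = 5.0 * mad
    idx, props = signal.find_peaks(y, prominence=max(prominence, 1e-12))
    if idx.size < 2:
        raise ValueError(f"no peaks: detected {idx.size} band(s), need >= 2")
    if idx.size > len(sizes):
        raise ValueError(
            f"detected {idx.size} bands but only {len(sizes)} expected sizes; "
            "raise the prominence threshold or extend the size list")
    # refine each center by a parabolic fit through the 3 samples at the apex
    centers = []
    for i in idx:
        if 0 < i < y.size - 1:
            y0, y1, y2 = y[i - 1], y[i], y[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            centers.append(ladder_profile.distances[i] + shift * step)
        else:
            centers.append(ladder_profile.distances[i])
    centers = sorted(centers)
    pairs = [(float(d), s) for d, s in zip(centers, sizes)]
    unmatched = sizes[len(centers):]
    if unmatched:
        logger.warning("ladder lane %s: no band detected for expected sizes %s",
                       ladder_profile.lane_id, unmatched)
    return pairs


def fit_ladder(peaks: Sequence[tuple]) -> LadderCalibration:
    """OLS fit of distance on ln(size) over the ladder peaks.

    Returns the calibration with intercept a, slope b, r² and the residual SD
    of distance (0 for a two-point exact interpolation).
    """
    peaks = [(float(d), float(s)) for d, s in peaks]
    if len(peaks) < 2:
        raise ValueError("need at least 2 ladder peaks")
    d = np.array([p[0] for p in peaks])
    sz = np.array([p[1] for p in peaks])
    if np.any(sz <= 0):
        raise ValueError("ladder sizes must be positive")
    x = np.log(sz)
    if np.ptp(x) == 0:
        raise ValueError("degenerate ladder: all peaks share one size")
    res = stats.linregress(x, d)
    resid = d - (res.intercept + res.slope * x)
    dof = max(len(peaks) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid ** 2) / dof)) if len(peaks) > 2 else 0.0
    r2 = 1.0 if len(peaks) == 2 else float(res.rvalue ** 2)
    cal = LadderCalibration(a=float(res.intercept), b=float(res.slope),
                            peaks=sorted(peaks), r_squared=r2,
                            residual_sd=residual_sd)
    logger.info("ladder fit: a=%.3f mm, b=%.3f mm/ln-nt, r^2=%.5f over %d peaks",
                cal.a, cal.b, cal.r_squared, len(peaks))
    return cal
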