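"""Lane densitometry profiles and their on-disk TSV dialect.

A lane profile is the 1-D intensity-versus-distance trace read off a stained
gel lane: distance in mm from the well, intensity in arbitrary densitometer
units (AU). Profiles are the common currency of every pipeline stage.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["IntensityProfile", "ProfileParseError", "read_profile", "write_profile"]


class ProfileParseError(ValueError):
    """Malformed profile file; message carries the offending line number."""


@dataclass
class IntensityProfile:
    """Ordered (distance mm, intensity AU) samples for one gel lane.

    Distances are strictly increasing; intensities are finite. Metadata is a
    free-form provenance map (simulator config, background estimates, ...).
    """

    distances: np.ndarray
    intensities: np.ndarray
    lane_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.distances.ndim != 1 or self.distances.shape != self.intensities.shape:
            raise ValueError("distances and intensities must be 1-D and equal length")
        if self.distances.size < 2:
            raise ValueError("profile needs at least 2 samples")
        if not np.all(np.isfinite(self.distances)):
            raise ValueError("non-finite distances")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensities")
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")

    def __len__(self) -> int:
        return self.distances.size

    @property
    def step(self) -> float:
        """Median sampling interval in mm."""
        return float(np.median(np.diff(self.distances)))

    def integral(self) -> float:
        """Trapezoidal integral of intensity over distance (AU·mm)."""
        return float(np.trapezoid(self.intensities, self.distances))

    def interpolate_to(self, distances: np.ndarray) -> "IntensityProfile":
        """Linear interpolation onto a new distance grid (clamped at the ends)."""
        d = np.asarray(distances, dtype=float)
        y = np.interp(d, self.distances, self.intensities)
        return IntensityProfile(d, y, lane_id=self.lane_id, metadata=dict(self.metadata))

    def replace(self, intensities: np.ndarray, **metadata) -> "IntensityProfile":
        """Copy with new intensities on the same grid; metadata entries merged."""
        meta = dict(self.metadata)
        meta.update(metadata)
        return IntensityProfile(self.distances.copy(), np.asarray(intensities, dtype=float),
                                lane_id=self.lane_id, metadata=meta)


def read_profile(path) -> IntensityProfile:
    """Read a two-column distance/intensity table (TSV or CSV, ``#`` comments).

    Rows are sorted by distance on read. Non-numeric rows and duplicate
    distances raise :class:`ProfileParseError` naming the line.
    """
    path = Path(path)
    distances: list[float] = []
    intensities: list[float] = []
    lines: list[int] = []
    meta: dict = {"source": str(path)}
    with io.open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta.setdefault(key.strip(), val.strip())
                continue
            fields = line.replace(",", "\t").split()
            if len(fields) < 2:
                raise ProfileParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                d, y = float(fields[0]), float(fields[1])
            except ValueError:
                raise ProfileParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}") from None
            distances.append(d)
            intensities.append(y)
            lines.append(lineno)
    if len(distances) < 2:
        raise ProfileParseError(f"{path}: fewer than 2 data rows")
    d = np.array(distances)
    y = np.array(intensities)
    ln = np.array(lines)
    order = np.argsort(d, kind="stable")
    d, y, ln = d[order], y[order], ln[order]
    dup = np.flatnonzero(np.diff(d) == 0)
    if dup.size:
        raise ProfileParseError(
            f"{path}:{ln[dup[0] + 1]}: duplicate distance {d[dup[0]]:g} mm")
    lane_id = meta.pop("lane_id", path.stem)
    return IntensityProfile(d, y, lane_id=lane_id, metadata=meta)


def write_profile(profile: IntensityProfile, path, header: dict | None = None) -> None:
    """Write the gel TSV dialect: ``# key: value`` provenance lines then two columns."""
    path = Path(path)
    entries = {"lane_id": profile.lane_id}
    entries.update({k: v for k, v in profile.metadata.items() if np.isscalar(v) or isinstance(v, str)})
    if header:
        entries.update(header)
    with io.open(path, "w", encoding="utf-8") as fh:
        for key, val in entries.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# distance_mm\tintensity_au\n")
        for d, y in zip(profile.distances, profile.intensities):
            fh.write(f"{d:.6g}\t{y:.10g}\n")
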