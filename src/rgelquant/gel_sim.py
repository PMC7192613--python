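"""Synthetic alkaline gels: alkali fragmentation of an rNMP-bearing genome.

Hot alkali cleaves single-stranded DNA at every embedded ribonucleotide, so a
genome carrying ``n_rnmp`` rNMPs shatters into ``n_rnmp + n_molecules``
fragments (molecule ends also terminate fragments). Under uniform rNMP
placement the fragment-size distribution is that of uniform spacings, i.e.
exponential with mean ``genome_size / n_rnmp`` in the many-break limit.

The renderer is the forward model the quantitation pipeline inverts: a
fragment of size ``sz`` migrates to ``d = a + b·ln(sz)`` (b < 0 with distance
measured from the well), carries stain mass proportional to its length, and is
broadened into a Gaussian band. Lanes come back as densitometry profiles in AU
per mm plus additive polynomial background and Gaussian detector noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .profiles import IntensityProfile

__all__ = [
    "GenomeBreakConfig",
    "GelRenderConfig",
    "DEFAULT_LADDER_SIZES",
    "FULL_1KB_PLUS_SIZES",
    "simulate_breaks",
    "simulate_fragments",
    "migration_distance",
    "render_lane",
    "render_ladder_lane",
    "render_empty_lane",
]

#: Invitrogen 1 kb Plus band sizes (nt).
FULL_1KB_PLUS_SIZES = (100, 200, 300, 400, 500, 650, 850, 1000, 1650, 2000,
                       3000, 4000, 5000, 6000, 7000, 8000, 9000, 10000, 12000)

#: Default simulated ladder: the 1 kb Plus bands within the gel's resolving
#: range. Above ~5 kb the default migration slope packs bands closer than the
#: band broadening resolves (compression zone), so they are left out of the
#: simulated reference lane by default.
DEFAULT_LADDER_SIZES = tuple(s for s in FULL_1KB_PLUS_SIZES if s <= 5000)


@dataclass
class GenomeBreakConfig:
    """Alkali-fragmentation model for one lane's worth of genomic DNA.

    genome_size
        Haploid genome length in nt (yeast: ~24 Mb).
    n_rnmp
        Number of embedded ribonucleotides, i.e. alkali break points.
    placement
        ``"uniform"`` or ``"clustered"``. Clustered placement routes
        ``hotspot_break_fraction`` of the breaks into ``n_hotspots`` regions
        jointly spanning ``hotspot_span_fraction`` of the genome; used for
        robustness checks of the uniform-breakage correction.
    n_molecules
        Starting DNA molecules (chromosome-arm pieces); their ends terminate
        fragments too. Default 16, the haploid yeast chromosome count.
    n_background_breaks
        Extra rNMP-independent alkali breaks (the control-strain background
        that quantitation subtracts), uniform, default 0.
    """

    n_rnmp: int
    genome_size: int = 24_000_000
    placement: str = "uniform"
    n_hotspots: int = 10
    hotspot_break_fraction: float = 0.9
    hotspot_span_fraction: float = 0.01
    n_molecules: int = 16
    n_background_breaks: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if self.n_rnmp < 0 or self.n_background_breaks < 0:
            raise ValueError("break counts must be non-negative")
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")
        if self.placement not in ("uniform", "clustered"):
            raise ValueError(f"unknown placement {self.placement!r}")
        n_cuts = self.n_rnmp + self.n_background_breaks + self.n_molecules
        if self.genome_size / n_cuts < 1.0:
            raise ValueError("expected fragment size below 1 nt; too many breaks")


@dataclass
class GelRenderConfig:
    """Forward model of one alkaline-gel lane.

    a, b
        Migration intercept (mm) and slope (mm per ln-nt); b < 0 when distance
        is measured from the well and large fragments migrate less.
    band_sigma
        Gaussian band-broadening SD in mm.
    intensity_scale
        Stain response: AU·mm of integrated band intensity per nt of fragment
        mass (intensity is proportional to mass, not molecule count).
    background
        Polynomial baseline coefficients, lowest order first (AU, AU/mm, ...).
    noise_sd
        Additive Gaussian detector noise SD in AU.
    """

    a: float = 180.0
    b: float = -13.0
    band_sigma: float = 0.8
    lane_length: float = 155.0
    sample_step: float = 0.1
    intensity_scale: float = 1e-3
    background: Sequence[float] = (5.0, -0.02)
    noise_sd: float = 3.0
    ladder_sizes: Sequence[int] = DEFAULT_LADDER_SIZES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_step <= 0:
            raise ValueError("sample_step must be positive")
        if self.lane_length <= 0:
            raise ValueError("lane_length must be positive")
        if self.band_sigma < 0:
            raise ValueError("band_sigma must be non-negative")

    def grid(self) -> np.ndarray:
        """Densitometry sampling positions, 0 to lane_length inclusive-ish."""
        n = int(np.floor(self.lane_length / self.sample_step)) + 1
        return np.arange(n) * self.sample_step

    def noiseless(self) -> "GelRenderConfig":
        return replace(self, background=(0.0,), noise_sd=0.0)


# ---------------------------------------------------------------------------
# fragmentation


def _draw_distinct_positions(n: int, genome_size: int, rng: np.random.Generator,
                             sampler) -> np.ndarray:
    """Draw n distinct integer cut positions in [1, genome_size-1] via sampler."""
    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        extra = sampler(n - out.size)
        out = np.unique(np.concatenate([out, extra]))
        out = out[(out >= 1) & (out < genome_size)]
    return out


def simulate_breaks(cfg: GenomeBreakConfig, rng: np.random.Generator | None = None):
    """Place break points and molecule ends on the genome.

    Returns ``(rnmp_positions, background_positions, molecule_ends)`` —
    distinct sorted integer cut positions in (0, genome_size).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    G = cfg.genome_size

    def uniform(k):
        return rng.integers(1, G, size=k)

    if cfg.placement == "clustered" and cfg.n_rnmp > 0:
        span = max(1, int(round(G * cfg.hotspot_span_fraction / cfg.n_hotspots)))
        starts = rng.integers(0, max(1, G - span), size=cfg.n_hotspots)

        def clustered(k):
            in_hot = rng.random(k) < cfg.hotspot_break_fraction
            pos = rng.integers(1, G, size=k)
            hot_idx = rng.integers(0, cfg.n_hotspots, size=k)
            hot_pos = starts[hot_idx] + rng.integers(0, span, size=k)
            return np.where(in_hot, hot_pos, pos)

        sampler = clustered
    else:
        sampler = uniform

    taken = np.empty(0, dtype=np.int64)

    def draw(k, fn):
        nonlocal taken
        got = np.empty(0, dtype=np.int64)
        while got.size < k:
            cand = _draw_distinct_positions(k - got.size, G, rng, fn)
            cand = np.setdiff1d(cand, taken, assume_unique=False)
            got = np.unique(np.concatenate([got, cand]))
        taken = np.concatenate([taken, got])
        return np.sort(got)

    rnmp = draw(cfg.n_rnmp, sampler)
    background = draw(cfg.n_background_breaks, uniform)
    ends = draw(cfg.n_molecules - 1, uniform)
    return rnmp, background, ends


def simulate_fragments(cfg: GenomeBreakConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Fragment sizes (nt) from one alkali-fragmentation draw.

    Sizes are positive integers partitioning the genome exactly:
    ``len == n_rnmp + n_background_breaks + n_molecules`` and
    ``sum == genome_size``.
    """
    rnmp, background, ends = simulate_breaks(cfg, rng)
    cuts = np.concatenate([[0], np.sort(np.concatenate([rnmp, background, ends])),
                           [cfg.genome_size]])
    sizes = np.diff(cuts).astype(np.int64)
    assert sizes.sum() == cfg.genome_size
    return sizes


# ---------------------------------------------------------------------------
# rendering


def migration_distance(sizes, cfg: GelRenderConfig) -> np.ndarray:
    """Band center d = a + b·ln(sz) for each fragment size."""
    return cfg.a + cfg.b * np.log(np.asarray(sizes, dtype=float))


def _deposit_mass(centers: np.ndarray, masses: np.ndarray,
                  cfg: GelRenderConfig) -> tuple[np.ndarray, float]:
    """Integrate Gaussian bands over each sampling cell; returns AU/mm trace.

    Cell i spans [d_i - h/2, d_i + h/2]; each band contributes
    mass · [Φ((hi-c)/σ) − Φ((lo-c)/σ)] to the cell, so total deposited
    intensity·mm equals total mass up to tails truncated beyond the lane.
    """
    grid = cfg.grid()
    h = cfg.sample_step
    cell_mass = np.zeros_like(grid)
    total_mass = float(masses.sum())
    if cfg.band_sigma == 0.0:
        idx = np.round(centers / h).astype(int)
        ok = (idx >= 0) & (idx < grid.size)
        np.add.at(cell_mass, idx[ok], masses[ok])
    else:
        lo = grid - h / 2.0
        hi = grid + h / 2.0
        sigma = cfg.band_sigma
        # chunk fragments to bound the (n_frag × n_grid) erf workspace
        for start in range(0, centers.size, 4096):
            c = centers[start:start + 4096, None]
            m = masses[start:start + 4096, None]
            frac = ndtr((hi[None, :] - c) / sigma) - ndtr((lo[None, :] - c) / sigma)
            cell_mass += (m * frac).sum(axis=0)
    deposited = float(cell_mass.sum())
    truncated = total_mass - deposited
    return cell_mass / h, truncated


def _finish_lane(signal: np.ndarray, cfg: GelRenderConfig, lane_id: str,
                 rng: np.random.Generator, meta: dict) -> IntensityProfile:
    grid = cfg.grid()
    baseline = np.polynomial.polynomial.polyval(grid, np.asarray(cfg.background, dtype=float))
    noise = rng.normal(0.0, cfg.noise_sd, size=grid.size) if cfg.noise_sd > 0 else 0.0
    meta = dict(meta)
    meta.update(a=cfg.a, b=cfg.b, band_sigma=cfg.band_sigma,
                sample_step=cfg.sample_step, noise_sd=cfg.noise_sd)
    return IntensityProfile(grid, signal + baseline + noise, lane_id=lane_id, metadata=meta)


def render_lane(fragments, cfg: GelRenderConfig,
                rng: np.random.Generator | None = None,
                lane_id: str = "lane") -> IntensityProfile:
    """Render a fragment population into a noisy densitometry profile.

    Integrated band intensity (before background/noise) is
    ``intensity_scale × Σ sizes`` minus any tails migrating past the lane end,
    which are recorded in ``metadata['truncated_mass_au_mm']``.
    """
    sizes = np.asarray(fragments, dtype=float)
    if sizes.size and sizes.min() < 1:
        raise ValueError("fragment sizes must be >= 1 nt")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    centers = migration_distance(sizes, cfg)
    masses = sizes * cfg.intensity_scale
    signal, truncated = _deposit_mass(centers, masses, cfg)
    meta = {"kind": "sample", "n_fragments": int(sizes.size),
            "total_mass_au_mm": float(masses.sum()),
            "truncated_mass_au_mm": truncated}
    return _finish_lane(signal, cfg, lane_id, rng, meta)


def render_ladder_lane(cfg: GelRenderConfig,
                       rng: np.random.Generator | None = None,
                       mass_per_band: float = 500.0,
                       lane_id: str = "ladder"):
    """Render the size-reference lane; equal stain mass per band.

    Returns ``(profile, truth)`` where truth maps band size (nt) to its true
    center (mm) for roundtrip checks.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sizes = np.asarray(cfg.ladder_sizes, dtype=float)
    centers = migration_distance(sizes, cfg)
    masses = np.full(sizes.size, mass_per_band)
    signal, truncated = _deposit_mass(centers, masses, cfg)
    meta = {"kind": "ladder", "truncated_mass_au_mm": truncated}
    profile = _finish_lane(signal, cfg, lane_id, rng, meta)
    truth = {int(s): float(c) for s, c in zip(sizes, centers)}
    return profile, truth


def render_empty_lane(cfg: GelRenderConfig,
                      rng: np.random.Generator | None = None,
                      lane_id: str = "empty") -> IntensityProfile:
    """Background + detector noise only; drives the signal-to-noise cutoff."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    signal = np.zeros(cfg.grid().size)
    return _finish_lane(signal, cfg, lane_id, rng, {"kind": "empty"})
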