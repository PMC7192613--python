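# Methods

## The measurement

Single ribonucleotides (rNMPs) embedded in genomic DNA are alkali-labile:
hot KOH cleaves the single-stranded backbone at every embedded rNMP. When
total DNA from a strain that accumulates rNMPs (e.g. an RNase-H2-null,
`rnh201Δ` background) is alkali-treated and resolved on a denaturing
alkaline agarose gel, the single-stranded fragment-size distribution encodes
the genomic rNMP density: more rNMPs, shorter fragments. `rgelquant` inverts
a stained-lane densitometry trace into an absolute estimate of rNMPs per
haploid genome, with the yeast genome size G = 24 Mb as the default.

The chain, in the order it runs:

1. **Calibration.** The ladder lane gives peak positions for known band
   sizes. Electrophoretic distance is modelled as log-linear in size,
   `d = a + b·ln(sz)`, fitted by OLS of `d` on `ln(sz)` — in that direction,
   because `d` is the noisy observable and asymmetric least squares is not
   direction-symmetric. Inversion is analytic: `sz = exp((d − a)/b)`. With
   distance measured from the well, `b < 0`; the fit assumes no sign.
2. **Lane conditioning.** The raw trace is background-subtracted (see
   below), clipped at zero, smoothed with a cubic least-squares spline with
   15 interior knots, clipped again, and integrated over fixed Δd = 1 mm
   distance intervals. Each interval's characteristic size is taken at its
   midpoint through the calibration.
3. **Cutoff.** Intensity→count conversion divides by size, so noise at the
   gel bottom (tiny sizes) would explode. A cutoff distance d_max is placed
   where raw-lane fluctuations fall to empty-lane levels; it implies a
   minimum detectable size `sz_min = exp((d_max − a)/b)`.
4. **Counting.** Stain intensity is proportional to DNA mass, so an interval
   with integrated intensity `I_sz` holds `n_sz = I_sz / sz` fragments in
   arbitrary molar units. Counts are made loading-independent by scaling so
   the included intervals hold exactly 1 Gb of mass:
   `n_sz(per 1 Gb) = n_sz · 10⁹ / Σ(sz·n_sz)`. The preliminary per-genome
   count is `N = Σ n_sz(per 1 Gb) · G / 10⁹`.
5. **Truncation correction.** Fragments below sz_min ran past the cutoff.
   Under uniform break placement (Poisson breakage, exponential sizes) the
   missing count is restored by
   `N_corr = N · (2 − exp{−sz_min · Σ n_sz(per 1 Gb)/10⁹})`, a factor in
   [1, 2). When breaks cluster, the formula *under*-corrects, so the
   estimate is conservative — never an overestimate. The sum runs over the
   included (above-cutoff) intervals, which preserves that conservativeness.
6. **Control subtraction.** Alkali also nicks DNA independently of rNMPs.
   The matched control strain's corrected count is subtracted
   (`N_net = max(0, N_corr − N_corr,control)`), correct-then-subtract by
   default; subtract-then-correct is available
   (`subtract_order="subtract_then_correct"`) since either order is
   defensible. Densities are reported per 10⁹ nt: `N_net · 10⁹ / G`.
7. **Distribution views.** Per-Gb counts summed into half-open 50-nt bins
   and normalized to unit total, with bins whose lower edge falls below
   sz_min dropped *before* normalization; cross-gel comparisons are first
   restricted to bins above the largest sz_min involved and renormalized.
   Within-lane fraction profiles (each sample divided by the lane sum)
   support strand-specific Southern comparisons.
8. **Polymerase shares.** With steric-gate variants (Pol α-L868M, δ-L612M,
   ϵ-M644G) incorporating rNMPs at known in-vitro frequencies F = 1/40,
   1/300, 1/100 rNMP per dNMP, the excess count of each variant strain over
   the all-WT-polymerase strain, ΔN = N_polx − N_base, divided by F and
   normalized, gives each polymerase's percentage of genome synthesis.

## Numerical choices

**Background.** Three methods. `constant` subtracts the profile minimum
(suited to noise-free or pre-cleaned traces — on a noisy lane the minimum
sits ~3σ below the baseline). `linear_baseline` (default) fits a low-order
polynomial in two stages: asymmetric least squares (IRLS with weight
p = 0.01 on points above the fit) drives the line to the lower envelope,
then an unbiased OLS refit on the points within 3 robust SDs of that
envelope re-centres it on the baseline noise. The two-stage form matters:
envelope fits alone are biased low by ~2σ, and naive iterative clipping is
unstable when one band dominates the lane. `empty_lane` subtracts the
empty-lane trace directly. Negative residuals are clipped to zero
(counts cannot be negative).

**Smoothing.** A cubic least-squares regression spline
(`scipy.interpolate.LSQUnivariateSpline`) with 15 interior knots. Knots are
placed at quantiles of the cumulative absolute gradient of a lightly
pre-smoothed (σ = 1 mm) copy of the trace — dense where the profile changes
fast — blended with a uniform floor carrying about a third of the total
weight so flat stretches keep knots. This is a deterministic surrogate for
free-knot optimization; no penalty term is added because 15 fixed knots
already regularize, and accuracy is judged by integral fidelity (within 3%
of the noise-free integral on simulated lanes), not knot positions. Because
of the clip at zero and re-derived knots, smoothing is only *near*-idempotent:
re-smoothing changes the integral by well under 1%, not exactly 0.
Uniform placement is available (`placement="uniform"`).

**Cutoff.** Automatic rule: rolling SD of the raw lane over a 3 mm window,
compared against 1.5× the empty lane's rolling SD; d_max is the first
distance beyond which the lane stays below threshold. Two robustness
measures: the empty lane's rolling SD is median-smoothed (its own sampling
fluctuations are not signal), and exceedance runs shorter than two windows
are ignored — a single noise patch elevates a rolling SD for about one
window, while genuine band signal exceeds for much longer. Without these
the cutoff occasionally ran to the lane end, and noise rectified by the
zero-clip at tiny sizes inflated counts severely. The cutoff is always
overridable per lane (`manual_dmax` / `--dmax`), mirroring supervised
practice.

**Interval grids.** Counting uses Δd = 1 mm; halving Δd changes the
estimate by <1%. Distribution views use the fine 0.1 mm grid: above
~650 nt a 1 mm interval spans several 50-nt bins and midpoint assignment
would alias.

**Ties and degenerate inputs.** Ladder peaks are assigned to expected sizes
by rank order of distance (mobility is monotone in size); unassigned
expected sizes are warned about, never silently dropped; detection fails if
more peaks than expected sizes survive the prominence filter (5× the MAD by
default). A two-point ladder is an exact interpolation with zero residual.
Zero-variance ladders, zero-mass lanes, non-positive sizes, and empty
common support all raise errors rather than propagate.

## The synthetic-gel generator

Since the study's gel images are not deposited, validation runs on a
forward model of the assay. `simulate_fragments` places `n_rnmp` break
points on a G = 24 Mb single-stranded genome — uniformly, or clustered
(default robustness setting: 90% of breaks in 10 hotspots jointly spanning
1% of the genome) — plus `n_molecules` = 16 molecule ends (the haploid
chromosome count; ends terminate fragments too) and an optional
rNMP-independent background break count for control-strain emulation.
Sizes are exact integer partitions of the genome; under uniform placement
they converge to Exponential(G/n_rnmp).

`render_lane` maps each fragment to `d = a + b·ln(sz)` (defaults
a = 180 mm, b = −13 mm per ln-nt, a 155 mm lane — the gel length used for
this assay — sampled every 0.1 mm), deposits stain mass proportional to
fragment length into Gaussian bands (σ = 0.8 mm) by exact per-cell error
function integrals, and adds a linear baseline plus Gaussian detector noise
(σ = 3 AU against band peaks of hundreds to ~1000 AU/mm, i.e. peak
signal-to-noise well above 20). The ladder lane renders the 1 kb Plus band
list with equal mass per band; bands above 5 kb are excluded from the
default simulated ladder because at this slope they sit closer than the
band broadening resolves (the compression zone), matching the practice of
calibrating within the resolving range. All randomness flows from one
explicitly passed seeded generator; rendering is bit-reproducible.

What the generator does **not** emulate: lane warping/smiling, spatially
varying background or noise, stain saturation, diffusion during the run,
partial alkali digestion, and sequence-dependent breakage. Passing tests
therefore demonstrate that the *inversion chain* is correct and unbiased
under the model's assumptions — not that those assumptions hold for any
particular real gel, where the supervised cutoff and baseline inspection
remain important.

## Validation summary (all computed by the test suite)

- End-to-end recovery: uniform breakage at n_rnmp ∈ {2,000; 8,403; 20,136}
  on 24 Mb, rendered and quantified blind, recovers the true fragment count
  within ±10% (typically within ±4%).
- Conservativeness: over 20 clustered-breakage gels, mean N_corr stays at
  or below the mean true count.
- Exact identities: mass normalization Σ sz·n(per Gb) = 10⁹; correction
  factor 1.5 exactly when sz_min·Σn/10⁹ = ln 2; noise-free ladder fits with
  r² = 1; scale invariance of every estimate under lane intensity
  rescaling; all distributions and fraction profiles sum to 1.

## Known limitations

- Absolute totals for real gels depend on a supervised d_max; the automatic
  rule is a default, not a replacement for inspection.
- The truncation correction assumes uniform breakage; under strong
  clustering it is deliberately conservative and can undercount severely
  (hotspot fragments below sz_min are unrecoverable from the gel).
- Counts in intervals holding few fragments carry Poisson noise that no
  densitometry can remove; per-interval comparisons are only meaningful
  where expected counts are large.
- Uncertainty reporting is limited to across-replicate SEM in the batch
  report and optional first-order SEM propagation in the polymerase-share
  calculation.
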