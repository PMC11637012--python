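# Methods

This note documents the models, parameter choices, and numerical decisions
behind `spheroprofile`, and what the synthetic validation does and does not
establish about real data.

## Working representation

All image operations act on a 2-D grid of finite, non-negative intensities
with an isotropic physical pixel size (µm/px). Coordinates are 0-based,
row-major, pixel-centre convention. Multi-channel inputs are converted to
grayscale with BT.601 luma weights (0.299 R + 0.587 G + 0.114 B); a plain
channel mean is available by passing `weights=None`. Images are down-sampled
to a 200 × 200 working grid by exact area averaging (an interval-overlap
matrix product), which is anti-aliased by construction — a thin bright rim
is attenuated proportionally, never dropped as with decimation — and
conserves the global mean to floating precision. Non-square inputs are
forced to the square target (the QC stage emits near-square crops, so the
aspect distortion is bounded); the output pixel size is the geometric mean
of the per-axis sizes.

## QC triage

The historical workflow triaged fields of view by eye. Here each decision
is a deterministic, parameterised test applied in sequence, and every
candidate is accounted for exactly once with its first failing reason:

1. **detect** — Otsu foreground, holes filled, 8-connected components;
   components under `min_area_px` (default 200 px on the working grid,
   ≈ 16 µm equivalent diameter at 2 µm/px — well below any real spheroid)
   are logged as `too_small`. This also absorbs single-pixel noise
   speckles, which Otsu occasionally admits when the foreground fraction
   is small.
2. **full view** — rejected (`not_full_view`) if any pixel lies within
   `border_margin_px` (default 2) of an image edge.
3. **touching** — rejected if the minimum pixel-to-pixel Euclidean
   distance to another candidate is ≤ `gap_px` (default 3).
4. **croppable** — rejected unless the padded square crop
   (side = max(bbox sides) · (1 + 2·`pad_fraction`), default pad 0.15)
   fits inside the field *and* circularity 4πA/P² ≥ 0.4. The circularity
   gate removes fused or highly irregular blobs that would defeat
   centroid-anchored rays; two fully merged equal disks sit near 0.5,
   elongated chains well below 0.4.

Increasing the border margin can only shrink the accepted set
(monotonicity), and relabelling candidates never changes any decision
(order independence); both are tested.

## Circularity

Circularity uses the marching-squares outer contour of the mask, smoothed
with a 7-point circular moving average before measuring length, and is
clipped to [0, 1]. Raw marching-squares contours carry a ≈ 0.5 px staircase
that inflates the perimeter of curved shapes by several percent (a 50 px
raster disk would read ≈ 0.90); chain-code and Crofton estimators
have the opposite problem on squares. The smoothed contour reads ≈ 1.00 on
disks and ≈ 0.83 on a 50 px square (continuum value π/4 ≈ 0.785), accurate
enough on both families for the 0.4 gate and for reporting. The
equivalent-circle diameter is 2·pixel_size·√(area/π).

## Radial profiling

The spheroid mask is segmented by Otsu threshold → hole filling → largest
8-connected component → one 3 × 3 binary closing. Hole filling matters for
edge-high markers, whose dim cores otherwise fall below threshold. The
centroid is the unweighted mean of foreground pixel coordinates; if it
falls outside a (non-convex) mask the record is rejected, since rays could
not be anchored.

K rays (default 20) leave the centroid at angles 2πk/K (angle 0 along the
+column axis, counterclockwise; an `angle_offset` is available). Each ray
terminates at its own mask-boundary crossing — profiles are plotted against
a per-spheroid normalised radius, so per-ray termination, not a fixed
radius, is the consistent choice. The crossing is found by coarse marching
(0.5 px) and bisection to 10⁻³ px on the nearest-pixel membership test; the
returned length is the last in-mask distance, so the final sample sits on
the boundary with background within one pixel beyond. M samples (default
80) are equally spaced on [0, 1] of each ray.

Intensities are sampled by bilinear interpolation with two boundary
refinements, both of which exist because a spheroid's support ends at the
mask while naive interpolation does not know that:

* **mask-aware weights** — the four stencil weights are zeroed outside the
  mask and renormalised. Plain bilinear at the rim mixes in background
  pixels and can drag an edge-high marker's boundary sample toward
  background by half the rim intensity.
* **one-sided rim extrapolation** — renormalised weights read the last
  interior pixel's *centre* value, biasing steep rims inward by up to
  ~0.5 px × gradient. Trailing samples whose stencil crosses the boundary
  are therefore first-order extrapolated along the ray from the last two
  fully-interior samples (the standard one-sided treatment at a domain
  edge), then clipped at zero.

With both refinements the mean profile of analytic linear and quadratic
radial fields (peak 200 on a 200 × 200 grid) is recovered to ≤ 0.4 gray
levels at K = 20, M = 80, comfortably inside the 2-gray-level validation
bound; rotating a test scene by one ray spacing cyclically permutes the
profile rows to within interpolation tolerance.

The K × M matrix is reduced by a column-wise mean and min–max normalised to
[0, 1]. A constant profile cannot be normalised: it maps to all zeros with
a `degenerate` flag (never NaNs), and downstream statistics exclude flagged
spheroids deterministically.

## Size classes and microregion partition

Diameters ≤ 200 µm are *small*, (200, 400] µm *large* (the 200 µm boundary
is inclusive to small, matching integer-µm class labels; configurable);
beyond 400 µm a spheroid is `out_of_range`, warned about, and excluded from
regional statistics, which are defined for the two-class design.

The M profile points split into contiguous core → quiescent → edge blocks
of fractions 25/50/25 % (small) and 60/30/10 % (large). Core and edge sizes
are `round(fraction·M)` with the remainder absorbed by the middle
(quiescent) block, which preserves the printed core/edge fractions exactly
at M = 80 (blocks 20/40/20 and 48/24/8). Each block's representative point
is its midpoint index, `start + (size − 1)//2` — indices (9, 39, 69) and
(23, 59, 75) at M = 80. Regional values are read at those midpoints by
default; a `block_mean` mode is provided because regional averages are the
other natural reading, and the two coincide only for profiles linear within
a block.

## Statistics

Region × size-class tables are analysed with an ordinary two-way
fixed-effects ANOVA (statsmodels OLS; with ≥ 2 observations per cell) and
Tukey HSD pairwise comparisons between regions within each size class and
between size classes within each region, at α = 0.05. No additional
multiplicity layer is applied beyond Tukey. Zero-variance tables are
reported as degenerate rather than raising. Marker-vs-diameter
relationships use simple linear regression (slope, two-sided p, R²).
Validation checks the ANOVA against a from-scratch balanced sums-of-squares
computation (agreement to 10⁻¹⁰) and its null rejection rate over 500
simulated null cohorts (within a 3σ binomial band of 0.05).

## FLIM fitting

Each pixel's TCSPC histogram is modelled as a biexponential decay with a
constant background, I(t) = I0 (A1 e^(−t/τ1) + A2 e^(−t/τ2)) + bg. Bins
before the histogram peak (the excitation rising edge) are discarded and no
instrument-response deconvolution is attempted. Fitting is bounded
least squares (trust-region reflective) with:

* **bin-integrated model** — the model is integrated analytically over each
  time bin rather than point-sampled at bin centres; point sampling leaves
  a relative bias of order (Δt/τ1)²/24 ≈ 6 × 10⁻⁴ at 256 bins / 12.5 ns,
  which would dominate the noiseless-recovery budget.
* **model-based (Pearson) weights** — bin variance is taken as
  max(model, 1), not max(count, 1). Observed-count weights over-weight
  downward fluctuations at low counts and bias lifetimes short by ≈ 0.04 ns
  at 5000 photons/pixel; model-based weights cut the A1/A2 median error
  from ≈ 14 % to ≈ 6 % under the same conditions.
* **bounds and initialisation** encoding free/bound NADH priors:
  τ1 ∈ [0.05, 1.0] ns (init 0.4), τ2 ∈ [1.0, 6.0] ns (init 2.5),
  amplitudes ≥ 0 (init 70/30), background ≥ 0.

Amplitudes are reported normalised (A1 + A2 = 1, scale retained in I0),
with reduced χ². Pixels under the photon threshold (default 100) or with
non-converged fits are flagged invalid, never errors. Stack fitting
optionally sums histograms over a `spatial_bin` × `spatial_bin`
neighbourhood first (default 3, the usual commercial-software binning,
trading resolution for photon statistics — and mixing signal across region
boundaries by one binning radius, which region comparisons should erode
away). The mean lifetime is amplitude-weighted,
τm = (A1τ1 + A2τ2)/(A1 + A2), the convention of standard FLIM analysis
software; an intensity-weighted variant is provided.

## Intensity normalisation and redox ratio

Raw NADH/FAD intensities are normalised by detector sensitivity and laser
power: I / (g(gain) · P^e). The gain curve g comes from a fluorescein
calibration series and is interpolated log-linearly between calibration
points, never extrapolated (out-of-range gains raise). The power exponent
defaults to 2 (two-photon excitation scaling) and is configurable to 1 for
single-photon modalities. The redox ratio FAD/(FAD + NADH) is computed
pixel-wise; pixels whose total signal falls below a floor (default 1 % of
the summed image's 99th-percentile intensity) are flagged invalid to
suppress background, and the ratio is in [0, 1] wherever valid, for any
non-negative inputs and any common rescaling.

## Synthetic ground truth

The generators emulate, with known truth manifests: radially organised
marker disks (core-high, edge-high, flat, or custom laws) with additive
Gaussian noise (read-noise-dominated widefield); multi-spheroid QC fields
with interior, border-clipped, and near-touching (2 px gap) disks; Poisson
decay stacks integrated from the biexponential model, optionally with a
two-region core/annulus layout; and per-region cohort values drawn from
Normal(mean, SD) clipped to [0, 1], defaulting to reference CD80/CD206
effect sizes with n = 30 per cell and diameters uniform within class
bounds. Every generator is a pure function of (spec, seed). Phantoms are
centred on an exact pixel centre so the truth centroid is representable on
the raster.

What the phantoms do *not* model: PSF blur and optical sectioning, texture
and cell-scale intensity structure, autofluorescence background gradients,
instrument response in the decay, detector afterpulsing, and irregular
(non-disk) spheroid shapes. Passing the synthetic suite therefore
establishes the correctness of the algorithms and their numerical
behaviour under realistic noise and geometry, not end-to-end accuracy on
any particular microscope's data.

## Problem sizes used in validation

Validation studies run at: 200 × 200 phantom grids with K = 20, M = 80;
100 random QC fields; 200 fitted pixels per lifetime condition at 5000
photons/pixel (256 bins over 12.5 ns); 16 × 16 two-region decay stacks;
500 null-cohort replicates for ANOVA calibration; and 100 cohort replicates
at n = 30 per cell for direction recovery. These sizes give stable
statistics for every stochastic bound checked.

## Known limitations

* Regions are defined on the 1-D radial axis only; no 2-D region masks.
* Segmentation is global-threshold based; heavily textured or low-contrast
  spheroids may need pre-processing upstream.
* The decay model is strictly two-exponential with constant background; no
  IRF deconvolution, phasor analysis, or three-component fits.
* Proprietary microscope formats (.sdt, .nd2, .lif), z-stacks, and
  time-lapse are out of scope; inputs are TIFF and CSV.
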