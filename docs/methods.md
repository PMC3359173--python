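# Methods

## Profile extraction

The region of interest is an ordered polyline in continuous, 0-based
pixel-center coordinates (x rightward, y downward, origin at the center of
the top-left pixel). ImageJ `.roi` polylines are imported under the same
convention, with integer vertices taken to lie on pixel centers.

A chord-length-parameterized interpolating cubic spline with natural end
conditions is fitted through the anchors (two anchors degrade to a
straight segment). Arc length is measured numerically on a dense parameter
grid (16 subdivisions per pixel of chord length, with the anchor knots
included exactly), inverted to the curve parameter, and the spline is
evaluated at uniform arc-length targets, so every sample lies on the curve
itself rather than on a polyline approximation. The default step is 1.0
pixel — one sample per pixel of arc, matching a per-pixel scan of the
line. The first sample sits on the first anchor; the last may stop up to
one step short of the last anchor. Intensity is sampled bilinearly, which
is what gives walls sub-pixel localization downstream; nearest-neighbor
sampling would quantize wall positions to the pixel grid.

Calibration (µm/pixel, square pixels only) is resolved as: explicit
argument, then TIFF resolution tags, then a default of 1.0 µm/px with a
logged warning. Anisotropic calibration is rejected because all outputs
are expressed on a single distance scale.

## Wall detection

Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `window` | 9 samples | width of the neighborhood a wall peak must dominate |
| `stringency` | 1.5 | multiplier on the in-window minimum a peak must exceed |
| `min_intensity` | 0 | absolute floor (raw units) expected of a wall |

A sample is a raw candidate iff its intensity reaches the window maximum
(window centered on the sample, the sample itself excluded), exceeds the
window minimum times `stringency`, and clears `min_intensity`. Windows are
truncated at the profile ends rather than padded, so no data is invented
near the boundaries. Because the rule uses ≥ against the window maximum,
flat-topped ridges produce runs of consecutive candidates; each maximal
run becomes one wall at its intensity-weighted centroid. Walls closer than
⌈window/2⌉ samples are collapsed onto the higher peak: two maxima within
half a window are shoulders of one ridge, not two walls. Gaps within 1e-6
samples of that threshold count as separated, so floating-point drift in a
centroid cannot flip an exact-threshold case.

The window default of 9 samples spans typical wall-ridge widths (a ridge
of σ ≈ 1.5 px occupies ~6 px) while staying narrower than meristem cells
at usual confocal resolutions (8 µm ≈ 16 px at 0.5 µm/px); it is exposed
on the CLI along with the other two parameters. When the in-window minimum
is 0 (dark, empty stretches) the stringency condition is vacuous and flat
zero regions would qualify wholesale — `min_intensity` is the guard for
exactly that failure mode, which is why it exists as a separate absolute
threshold.

Scale invariance holds by construction: multiplying all intensities and
`min_intensity` by c > 0 leaves the wall set unchanged, since the rule
uses only order and ratios.

Segmentation treats consecutive boundaries as cell walls. By default the
profile start counts as boundary 0 (`include_start_as_wall`), because the
user is expected to start the line on the originating boundary of the
file (in root work, the cortex/endodermis initial) and distances are
reported from there; a detected wall within half a sampling step of the
start supersedes it. Interactive wall painting is replaced by
`add_manual_walls`: explicit positions in µm, tagged `manual`, with
positions within one sampling step of an existing wall rejected (warning,
not error).

## Elongation-onset landmark

The landmark is found on the series (xs, ys) = (cell number, cell length)
by default: the chord joins the first and last data points and the
interior point with the maximum unsigned perpendicular distance to the
chord is the break point. Distances are computed in raw data units —
cells on one axis, µm on the other — not in display or normalized
coordinates; a min-max normalization flag exists but is off by default.
Ties break to the smallest index (the earliest detectable transition),
which makes the estimator deterministic. No smoothing or regression is
applied to the length series first.

Indices are 1-based throughout (`cell_index` counts cells from the
profile start), and `distance_um` anchors to the proximal boundary of the
break cell, which is reproducible and monotone in the index; anchoring to
the cell midpoint would differ by half a cell length.

The cumulative-length mode (xs = start positions) is provided for
comparison but is not the default: long distal cells stretch the abscissa,
flattening the corner and making the break point less consistent.

The estimate is only meaningful when the profile reaches well into the
elongation zone. When fewer than two cells reach ~4× the typical meristem
length (taken as the median of the first quartile of cells), a warning is
logged — not an error, since short profiles are legitimate for plain
measurement.

## Williams Index

Disagreement D between two raters is the mean absolute difference of
their landmark estimates across images — the standard choice for scalar
landmark locations. The index is

I′ = [ (1/n) Σⱼ 1/D₀ⱼ ] / [ (2/(n(n−1))) Σ_{j<j′} 1/D_{jj′} ],

implemented as a ratio of means of reciprocals (the pair prefactor is
exactly the mean over the n(n−1)/2 pairs), which makes the homogeneous
cases float-exact: all D equal → I′ = 1; computer disagreeing half as much
→ I′ = 2. Any zero pairwise D (e.g. the computer column duplicating an
expert) makes a reciprocal undefined and raises an error. No confidence
interval is computed by default; a jackknife-over-images normal-theory
interval is available as a clearly-labelled extension
(`williams_jackknife_ci`).

## Synthetic data

The generator emulates the one thing the pipeline needs from a confocal
image: a file of dark cells separated by bright wall ridges on a noisy
background, with lengths that are constant in the meristem and then rise
steeply.

Length model: `n_meristem` cells (default 30) of mean `L_m` (default
8 µm), then a geometric ramp over `ramp_cells` cells (default 6) reaching
`L_m × elongation_factor` (default 15×, the canonical elongation ratio of
root cells), then `n_elongated` fully elongated cells (default 3, so the
series always contains at least two substantially elongated cells, the
stated requirement for a well-defined corner). Multiplicative lognormal
noise with coefficient of variation `noise_cv` (default 0.1, a realistic
heterogeneity for meristem cell lengths) keeps lengths positive and
scatter proportional to the mean. The ground-truth landmark index is
`n_meristem` — the last cell before elongation begins, which is the
change-point the chord rule targets.

Image model: wall ridges are 1-D Gaussians (σ = `wall_sigma_px`, default
1.5 px; peak `wall_amp`, default 1000) in arc-length distance to the
nearest wall plane, constant across the file's width, along a straight or
arc-shaped axis (the arc spans 1 radian, a gentle bend comparable to a
gravitropically curving root); additive Gaussian background noise
(`bg_noise_sd`, default 10, i.e. 1% of peak), values rounded and clipped
to 16-bit range. Default calibration 0.5 µm/px puts ~16 px between
meristem walls. The returned polyline starts exactly on wall 0 and
overshoots the last wall by a few ridge widths so the final wall is
interior to the profile.

What the generator does **not** emulate: neighboring cell layers and
"ghosting" walls, stain photophysics and depth attenuation, wall-thickness
variation, and curvature of the wall planes themselves. Passing tests
therefore demonstrate correctness of the measurement chain on
well-behaved signal, not robustness to every real-image artifact — on
real data the interactive knobs (stringency, floor, manual walls) exist
precisely because those artifacts occur.

The fixture suite writes seven cases (clean/noisy × straight/curved, a
coarse-pixel and a short-meristem variant, and a truncated variant that
drops the final two cells of the clean series to emulate a profile line
stopped short). Generation is fully deterministic in the seed: ground
truth regenerates byte-identically.

## Numerical choices and degenerate inputs

- Wall candidate comparisons use ≥ exactly as specified by the rule;
  candidate equality with a literal per-sample transcription is asserted
  at scale (1000 random profiles) in the acceptance checks.
- Profiles not longer than the window, polylines with < 2 anchors,
  duplicate consecutive anchors, fewer than 2 boundaries, series of < 3
  cells, and zero pairwise disagreements all raise `ValueError` with a
  specific message rather than returning partial results.
- A constant profile yields no walls for stringency > 1 (v ≥ v·s fails);
  an all-zero profile with `min_intensity` = 0 flags flat runs — by
  design, the floor is the guard there.
- CLI exit codes: 0 success, 2 bad input, 3 degenerate computation.

## Problem sizes

The default validation runs use 1000 random profiles of 500 samples for
the detector-transcription check, 500 random series for the break-point
oracle, 200 replicates for landmark recovery and truncation stability,
and 100 simulated 200-image, 5-expert panels for the Williams Index
study; the synthetic image suite renders files of ~40 cells (~900 µm) at
0.5 µm/px. These sizes give stable percentages (binomial s.e. ≲ 2 points)
while keeping the whole suite fast.
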