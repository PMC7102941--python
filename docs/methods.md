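# Methods

This note records the models behind each module, the defaults and why,
what the synthetic data does and does not emulate, and the numerical
conventions. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## FRET model and correction

A double-labeled sample is imaged in three registered channels: donor
(Cy3), acceptor (Cy5) and raw sensitized-emission FRET. The raw FRET
channel is contaminated by donor bleed-through (a fraction *a* of donor
intensity) and acceptor cross-excitation (a fraction *b* of acceptor
intensity). Both are linear in signal, not offset, so calibration fits a
line **through the origin** of raw-FRET vs. role-channel intensity over
background-subtracted foreground pixels of a single-label control
(background = intensity-histogram mode; foreground defaults to 3 robust
SDs of the role channel). The correction is the Youvan form
`Fc = raw − a·donor − b·acceptor`, clamped at 0 pixelwise (cFRET is a
non-negative efficiency proxy; the clamped-pixel count is reported).
Under shot noise the regression is unbiased, and the tests recover planted
coefficients in {0.1, 0.3, 0.5} within 2 % at ≥10⁴ foreground pixels.

cFRET is computed **per punctum from region-mean intensities**
(`cFRET(%) = mean Youvan / ((mean Cy3 + mean Cy5)/2) × 100`), and
compartments report the mean over their puncta as the primary statistic;
the pooled alternative (summed corrected intensity / compartment area) is
reported alongside, since the choice between averaging puncta and pooling
intensities is genuinely open — both are exposed, puncta-average is
primary. A zero denominator yields NaN, never a silent 0. An optional
third coefficient (marker bleed-through into the donor channel, e.g.
Alexa-488 → Cy3) exists on `CorrectionCoefficients` with default 0; it is
under-specified experimentally and therefore exposed but not applied.

In the simulator the planted FRET image inside each punctum is
`f · (donor + acceptor)/2`, so a perfectly corrected analysis reads back
`cFRET = 100·f`; this makes recovery directly interpretable (a planted
fraction 0.64 should read ~64 %). Clamping of noise-only pixels biases
the zero-FRET reading slightly above 0 under shot noise (~1–2 % absolute
at the default photon scale); the exact-null test therefore runs the
crosstalk-only (noiseless) configuration.

## Synthetic data: what it emulates, what it does not

Geometry is schematic: a disk soma, straight radial dendrite tubes with
stored centerlines, and a glial annulus beyond the dendrite tips. The
analyses consume compartment masks and centerlines, not morphology, so
realism there buys nothing. Noise is Poisson shot noise on photon-scaled
intensities plus optional Gaussian read noise, both **off by default** so
oracle tests can assert exactly. All randomness flows from one seeded
generator per call; identical (config, seed) reproduce outputs
bit-identically.

Not emulated: photobleaching, blinking photophysics, 3D/z-stacks,
non-Gaussian PSFs, channel misregistration, uneven illumination, and
autofluorescence structure. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
every real-world artifact.

Default study conditions planted in the generators:

* pixel size 108 nm; 30 frames at 60 s (time lapse), 6 s for kymographs;
* puncta areas log-normal, median 4786.3 nm², geometric SD 2.95 (basal
  somatic distribution); the printed "SD" of that distribution is treated
  as the unitless geometric SD, which is the only reading consistent with
  a log-scale histogram;
* velocity medians 22.16 / 15.49 / 20.77 nm/s for soma / dendrite / glia,
  with log-sd derived from the corresponding IQRs via
  σ = ln(q3/q1)/(2·0.6745);
* FRET fractions 0.64 / 0.32 / 0.11 for the young / mature / puromycin
  scenario levels (the cFRET percentages reported for those conditions);
* crosstalk defaults a = 0.25, b = 0.10 (typical Cy3 bleed-through and
  Cy5 cross-excitation magnitudes for these filter sets);
* signal-unit area 500 nm² — the smallest punctum the widefield analysis
  resolves at 108 nm pixels (~4–5 px); the paper defines the unit only
  operationally, as the smallest detectable signal.

## Puncta

Detection: white top-hat (disk radius 15 px default) → threshold at
`median + k·1.4826·MAD` of the top-hat image with a relative floor of 1 %
of the top-hat maximum (the MAD collapses to zero on noiseless images);
8-connected components ≥ `min_area` (default 4 px) become puncta with
intensity-weighted centroids. Both threshold terms scale with the image,
so detection is invariant to multiplying the image by any positive
constant. `signal_units = ceil(area/min_area)`: one unit is the minimum
detectable punctum.

Coordinates are 0-based, pixel-centered, y down; areas are pixel counts
(`area_nm2 = area_px · pixel_size²`). The small/large boundary 3000 nm²
is inclusive into "large". Binary-mask co-localization is
`|signal ∧ reference ∧ cell| / |signal ∧ cell|`; the converse fraction is
the same call with arguments swapped and generally differs. The
distance-from-soma profile is the geodesic shortest-path length inside
the soma∪dendrite mask (MCP on a unit-cost grid, soma pixels as sources,
×pixel size); somatic puncta are at 0 and off-mask puncta are excluded
with a warning. This deliberately replaces a full neurite-morphology
pipeline: the measured quantity (distance from the cell body along the
neurite) is preserved while tracing stays out of scope.

The puromycin perturbation replaces each punctum above the split
threshold (default 6 units) with children of ≤ threshold units drawn
uniformly, the last child taking the remainder, so the parent's units are
conserved **exactly** and the punctum count never decreases — the
dissociation signature is a histogram shift (no >100-unit puncta remain,
≤2-unit puncta multiply) at constant total units.

## SMLM

Local density is the inverse area of the first-rank Voronoi cell
(shoelace on the qhull vertices); convex-hull points with unbounded cells
are flagged *border* and excluded from classification rather than given a
clipped density. The clustered/diffuse boundary defaults to 40 in the
units the source analysis used ("localizations per nm²" — kept verbatim
although the magnitude suggests different effective units; it is a plain
config value, and an automatic alternative places the threshold at the
histogram minimum between the two largest log-density modes).
Classification is inclusive: density ≥ threshold → clustered.

The overlap formulas `(R·G)/(R+G−R·G)` and
`(R·G·B)/[R+G+B−R·B−R·G−G·B+R·G·B]`, evaluated pixelwise on {0,1} images
and aggregated by summation, reduce exactly to intersection-over-union;
tests verify this against set arithmetic exhaustively on 2×2 masks and on
random 16×16 masks, plus the identity `overlap3(R,G,G) = overlap2(R,G)`.
The planted-overlap simulator allocates circular patches to the seven
Venn classes of three channels (integer counts solved from the requested
pairwise/triple Jaccard; the achieved fractions and their distance to the
request are recorded in the ground truth), fills member patches at the
clustered density and scatters diffuse points outside all patches.
Measured overlap of rendered clustered masks sits slightly below the
planted region fractions because each channel samples patch borders
stochastically and a few diffuse points are misclassified into the
clustered pool (isolated rendered pixels are removed before overlap);
both planted and measured values are always reported side by side.
Channel registration is assumed perfect, as the channels are simulated on
a common grid.

Localization precision follows the bead protocol: the per-frame centroid
scatter is modeled as an isotropic 2D Gaussian, σ = RMS radial
deviation/√2 (the ML estimator), FWHM = 2√(2 ln 2)·σ ≈ 2.3548 σ. With
4000 centroids at σ = 19.4 nm the estimate is within 3 %.

## Tracking

Linking is greedy globally-nearest-neighbor with a hard displacement
gate, ties broken by (distance, detection id, track id), no gap closing
by default. At the low puncta densities of this preparation the greedy
solution matches the optimal assignment and is fully deterministic, which
matters more for testability than LAP optimality; with noiseless
detections and unambiguous spacing it reconstructs planted tracks
exactly. Speeds are instantaneous — Euclidean step / acquisition interval
(60 s default), no smoothing — averaged per track and pooled per
compartment (median + IQR). Mean instantaneous speed is invariant under
time reversal, and path length ≥ |net displacement| always.

Kymographs resample each frame by linear interpolation at unit-pixel
arc-length steps along a user-supplied polyline, averaged across the
perpendicular width; the dominant-ridge speed (least squares through the
per-row argmax) recovers planted speeds within 5 %. Directional analysis
projects the track onto the path's arc-length coordinate; class
boundaries (static below 500 nm total path; anterograde/retrograde when
|net| ≥ 0.5·path length, else bidirectional) are explicit, configurable
conventions — the qualitative behavior they encode is described but not
quantified by the source material. Localization noise inflates measured
speeds by the Rayleigh floor σ_loc·√π/Δt for a static particle;
`rayleigh_noise_floor` documents this bias and the simulation confirms it
within 5 %.

The motion model is run-and-pause (per-run log-normal speed, direction
±1 along the dendrite axis or 2D elsewhere, optional static fraction).
Pausing is **off by default** so that the planted per-compartment medians
are also the realized medians of per-track mean instantaneous speed; with
pausing enabled the per-track mean is diluted below the run-speed median,
which is the expected behavior, not an error.

## Statistics

The gate tests each group with Shapiro–Wilk (normal iff p > 0.05 in every
group) and variance equality with the two-sided F test (2 groups) or
Bartlett (>2). Dispatch follows the decision table in the module
docstring; "Dunnett with Tukey post hoc" is resolved as: Tukey for
all-pairs comparisons, Dunnett when a control group is named. Welch
(Brown–Forsythe) ANOVA is computed in closed form with Welch–Satterthwaite
degrees of freedom; Dunn's post hoc uses tie-corrected rank z-tests with
Holm adjustment (adjusted p ≥ raw p is guaranteed and property-tested).
Significance is fixed at p ≤ 0.05.

Outlier removal implements the one-sample (location) form of the
FDR-controlled robust outlier procedure: residuals from the median,
robust scale = 68.27th percentile of |residuals| × n/(n−1), two-sided
t-tail probabilities (df = n−1), Benjamini–Hochberg step-up at Q = 1 %.
The regression form is not implemented because the quantities this
pipeline feeds it are plain measurement lists, not model fits. Calibration
(computed by the tests): empirical type-I error of the dispatched
two-group path is within [0.04, 0.06] over 2000 Gaussian null replicates,
and the mean false-flag fraction on clean Gaussian data (n = 100) is
≤ 2 %. Constant data yields no outliers by construction.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale:
512² images for coefficient recovery (~2.5·10⁴ foreground pixels), 500
tracks per compartment, ~10⁴ localizations per SMLM channel, 10⁴-punctum
populations, 2000 statistical null replicates — sizes at which every
stated tolerance has comfortable margin while a full run stays in
minutes. Every stochastic step takes an explicit seed; reports serialize
with sorted keys and no timestamps, so identical configurations reproduce
byte-identical outputs.
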