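# Methods

`poleprof` quantifies where rod-shaped bacteria build new cell wall and how
symmetric that construction is between the two poles, plus the spectral
phasor readout of membrane-environment dyes. Mycobacteria elongate from both
tips at different rates: the old pole (inherited from the mother cell)
incorporates peptidoglycan faster and over a broader zone than the new pole
(created at the last division), the septum sits off-center, and fluorescent
D-amino acid probes such as HADA mark the incorporation zones. The package
implements the whole measurement chain on synthetic images with known ground
truth, so every stage is testable end to end.

## Synthetic scene generator

Cells are capsules (rectangle plus semicircular caps) along a straight or
gently curved centerline (quadratic Bezier, sagitta up to 3% of length,
rescaled so arc length equals the drawn cell length). Default pixel sizes
follow confocal practice for this organism: 0.105 µm/px for channel-mode
scenes and 0.05 µm/px for spectral scenes. Three channels are rendered:

- **membrane** — uniform envelope signal inside the capsule (the
  sulforhodamine-DHPE-like channel used for masks and length measurement);
- **hada** — axial model `I(s) = body + Σ poles + Σ foci` at normalized
  position `s ∈ [0,1]`: each pole contributes a linear ramp
  `A·max(0, 1 − s/e)` falling from amplitude `A` at the tip over extent `e`
  (fraction of length), and the septum and any extra foci are axial
  Gaussians. The true 10-point decay slope of each pole is recorded in the
  ground truth, so slope recovery is checkable without re-deriving it;
- **mscarlet** (optional) — a reporter concentrated at the poles with
  separate old/new-pole weights (default 3:1 toward the old pole).

Signal is blurred with an isotropic Gaussian PSF (default σ = 1.5 px — a
single blur parameter is adequate at this scale) and corrupted with Poisson
shot noise plus Gaussian read noise (σ = 2 counts) over a constant camera
offset (10 counts). Focus amplitudes near 100 counts give SNR ≈ 10 at peaks
under Poisson statistics. Intensity is rendered on a ~2 px apron around the
capsule using a signed axial coordinate, so pole ramps continue smoothly
past the tips instead of cutting to zero at the mask edge; the label mask
itself remains the exact capsule. Without the apron, any interpolated
sampling near the boundary systematically under-reads the pole tips.

Preset phenotypes (lengths are log-normal; reported strain means guided the
defaults, spreads chosen as typical for exponential-phase populations):

| preset | length (µm) | pole ramps | septum | extras |
|---|---|---|---|---|
| `control` | 7.0 ± 1.4 | old: A=100, e=0.18; new: A=90, e=0.10 | A=60 at 0.30–0.45 from the nearer pole | — |
| `delta_fhaA` | 5.5 ± 0.8 | equal: A=50, e=0.14 | A=100 at 0.45–0.50 (near midcell) | — |
| `overexpressor` | 4.5 ± 0.7 | as control | as control | 2 mid-cell foci (A=80) |

40% of cells are septate. Per-cell multiplicative jitter (log-SD 0.12) on
amplitudes and extents creates population spread while preserving the slope
ordering between poles. Extra foci are placed in the 0.25–0.75 span with a
minimum mutual separation of 0.15 of length, so they remain discrete,
resolvable peaks under the PSF even in short cells. All randomness descends
from one root seed through per-cell `SeedSequence` streams, so populations
are bit-reproducible and insensitive to evaluation order.

Spectral scenes emulate an environment-sensitive membrane dye imaged in
lambda mode: 30 channels, centers 423–713 nm in 10 nm steps. Each pixel's
spectrum is `amplitude ×` a unit-sum discretized Gaussian with per-pixel
center (preset mean ± 3 nm jitter; `shifted` preset +30 nm) and width 40 nm,
plus Poisson noise.

### What the generator does not emulate

No time-lapse growth, no 3D optics, no spatially varying background or
uneven illumination, no segmentation errors (labels are exact), no branched
or V-snapping cells, no transversely off-axis foci in the presets, and no
realistic spectral lineshapes beyond a single Gaussian. Passing tests
demonstrate that the measurement chain is correct and well calibrated under
these conditions; they do not certify performance on real images with
imperfect masks or structured background.

## Profile extraction

The mask is skeletonized; the skeleton's longest geodesic path (double-sweep
Dijkstra with Euclidean step weights) is smoothed with a parametric spline
and both ends are extended along the local tangent to the sub-pixel 0.5
crossing of the interpolated mask. Orientation is fixed deterministically
(lexicographically smaller endpoint first); pole identity is assigned
semantically later, so orientation carries no meaning. Cells whose extended
axis covers less than 80% of the region's major axis are flagged and
excluded (bent or branched morphology), as are regions whose minor/major
axis ratio exceeds 0.6 (degenerate, disk-like). Length is axis arc length ×
pixel size.

Intensity is sampled at stations ≤ 1 px apart along the axis, across a
transverse band of `width_px = 10` samples spaced 1 px (≈ 1.06 µm at the
default pixel size), and averaged. Numerical choices, each made because a
simpler option measurably violated the ≤ 2%-of-peak recovery contract
against the analytic axial model:

- **Mask-aware weighting** (default): band samples are weighted by the
  interpolated cell mask, so the average is not diluted where the band
  overhangs the boundary — cells here are ~6 px wide, narrower than the
  10 px band. An unweighted average is available (`weight_mask=None`).
- **Cubic B-spline sampling** (`interp_order=3` default): bilinear sampling
  of a ~1.5 px-wide septum peak carries O(h²·f″) error of 3–5% of peak;
  cubic reduces it an order of magnitude. Bilinear remains available and is
  what the brute-force oracle test checks against.
- **Cubic resampling** of the station trace onto the fixed 101-point
  normalized grid (linear interpolation clips sharp peaks).
- **Symmetric station grid** (`linspace`, spacing ≤ 1 px): reversing the
  axis permutes the stations onto themselves, making extraction commute
  with reversal to ~1e-13.

Background is the median intensity of label-0 pixels per channel, subtracted
per sample before mask weighting (the camera offset extends outside the
cell, so subtracting after the weighted average biases boundary stations);
values are clamped at zero. Population averages use the sample SD (n−1).
No per-cell normalization is applied before averaging (an optional
max-normalization flag exists but is off by default).

## Foci and landmarks

Foci are local maxima of the 1D axial profile with prominence above a
calibrated threshold and pairwise separation ≥ 0.08 of length (shoulder
suppression; the acquisition literature gives no value). Endpoints are
eligible as maxima (pole tips) by padding the trace with its minimum.
Detection runs on the 1D profile rather than 2D images: axial positions are
what all downstream metrics consume, and the 10-px band captures
transversely off-axis foci.

Calibration follows the published protocol: the prominence that maximizes
the fraction of control cells with exactly 2 (non-septate) or 3 (septate)
detected foci, searched over 30 log-spaced multiples (0.02–1.0) of the
control population's median peak value; ties take the middle of the
maximizing plateau. The value is then frozen and applied unchanged to
comparison groups. Below 50% achievable agreement the control population is
rejected as unusable. At least 20 flagged control cells are required.

Pole peaks are the highest local maxima within the terminal 15% of length at
each end (falling back to the endpoint value); the septum is the highest
qualifying interior maximum in the central 70%, with near-ties (within 0.05)
resolved toward the more prominent peak. The relative septum position is
reported as the min-distance convention — distance to the nearer pole as a
fraction of length, in (0, 0.5] — since the oriented alternative is not
identifiable without pole-age information. The pole nearer the septum is
labeled new; poles equidistant within one grid step are ambiguous and
excluded from pole-aligned statistics.

## Asymmetry metrics

The pole decay slope is the magnitude of an ordinary least-squares line
through 10 consecutive resampled grid points (step 0.01 of normalized
length, recorded in output metadata) from the pole peak inward; fits use raw
background-subtracted intensities (per-strain comparisons do not require
normalization; a max-normalization option exists). The pole/septum ratio is
the mean of the two pole peak values over the septum peak value — undefined
(cell excluded) when the septum intensity is zero. Pole-aligned population
profiles reverse each septate, unambiguous cell so the new pole sits at
position 0 before averaging. Second-channel pole intensity is the windowed
mean within ±0.05 of length of each pole peak (a windowed mean is more
noise-stable than the single peak sample), keyed by pole age. Slope-based
pole age labels the gentler slope old (the faster-growing pole spreads
incorporation over a broader zone); slopes within 10% relative difference
are ambiguous. Non-septate cells get slopes fitted toward midcell and are
excluded from ratio and alignment analyses.

## Spectral phasors

For a spectrum `I_k` (k = 0 at the shortest wavelength, K channels):

    G = Σ I_k cos(2πhk/K) / ΣI_k ,  S = Σ I_k sin(2πhk/K) / ΣI_k ,  h = 1

with `Φ = atan2(S, G)` and `M = √(G²+S²)`. Every nonnegative spectrum lands
in the convex hull of the K unit-circle channel phasors, so `M ≤ 1`. The
phase convention (red shift → counterclockwise, Φ increases) is fixed and
documented here; all comparisons are relative, so the convention does not
affect conclusions. Pixels below an intensity threshold (default: Otsu on
the total-intensity image, restricted to labeled pixels when labels exist)
are invalid. Because the phasor of a sum is the intensity-weighted mean of
component phasors, two-reference linear-combination analysis is exact:
per-pixel fractions are the orthogonal projection onto the reference
segment, clipped to [0, 1] (a pixel at the first reference maps to
fraction 1). Reference phasors are supplied by configuration — typically
phasors of pure-component synthetic spectra — since published cursor
positions do not exist. The "fraction" axis is interpreted as the fraction
of the first (ordered/blue-shifted) component. Fraction curves are
intensity-weighted histograms normalized to unit maximum; the center of mass
is computed on the unnormalized mass.

## Group statistics

Per-group normality is assessed with Shapiro–Wilk at α = 0.05 (the original
normality procedure is unstated; this is recorded in the manifest as an
implementation convention). All groups normal → t-test (2 groups) or
one-way ANOVA (≥ 3); otherwise two-sample Kolmogorov–Smirnov or
Kruskal–Wallis. No multiple-testing correction is applied across metrics
(comparisons are reported per metric). Constant groups are treated as
non-normal (Shapiro is undefined there).

## Problem sizes and determinism

The shipped tests and the acceptance script run populations of 40–100 cells
per condition and 50 replicate runs for the detection-power and type-I-rate
checks — sizes at which the binomial uncertainty of a 5% rejection rate over
50 runs is ≈ 3 percentage points, so the type-I check is a coarse
calibration gate, not a precise estimate. The pipeline manifest contains the
resolved config, per-stage cell accounting (cells in = analyzed + excluded,
one reason per exclusion) and SHA-256 checksums of every output, and no
timestamps: identical config and seed reproduce byte-identical outputs.

## Known limitations

- The medial-axis tip extension assumes convex, capsule-like tips; swollen
  or bulged poles would bias tip placement and hence pole-peak values.
- Foci are treated as 1D axial objects; two foci at the same axial position
  on opposite sides of the cell merge into one.
- The linear pole-ramp model makes the "decay slope" well defined; real
  incorporation gradients need not be linear, in which case the 10-point
  slope is a local linearization whose window matters.
- Phasor analysis is restricted to two-component linear unmixing; lifetime
  phasors and generalized polarization indices are out of scope.
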