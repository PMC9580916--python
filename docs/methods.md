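# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `smlmkit`, in the order data flows through the toolkit.

## Coordinate and data conventions

Camera pixel `(i, j)` (row i, column j) spans `[j, j+1) × [i, i+1)` in
`(x, y)`; the center of pixel `(0, 0)` is `(0.5, 0.5)`. This single
convention is used by the simulator, the localizer and all renderers, so an
emitter sitting exactly on a pixel center has fractional coordinate 0.5.
Frames are 0-based internally; CSV dialects (`CsvDialect`) translate
1-based exports and nm-unit positions, and a `half_pixel_offset` flag
absorbs exports whose pixel-center convention differs by 0.5 px.
`track_id = −1` marks unassigned rows so tables stay rectangular.

## Synthetic data

The simulator emulates the statistical structure the analysis assumes, not
a specific instrument:

* **Blinking** is a per-frame two-state Markov chain with switching
  probabilities `k_on`, `k_off`; the long-run on-fraction is
  `k_on/(k_on+k_off)`. Defaults (`k_on = 0.02`, `k_off = 0.5`) keep the
  equilibrium strongly toward the off state, the regime in which temporal
  median filtering is valid. No sub-frame or triplet kinetics.
* **PSF** photons are integrated over pixel areas by differences of
  Gaussian CDFs at the pixel edges (not point-sampled) — this matters when
  testing sub-pixel localization bias. Default `psf_sigma_px = 1.3`,
  a diffraction-limited PSF on a ~100 nm pixel camera.
* **Noise** is Poisson shot noise plus Gaussian read noise on top of a
  background with constant offset, linear spatial gradient and a slow
  per-frame ramp. EMCCD excess noise and sCMOS per-pixel noise maps are
  deliberately out of scope; tests passing here do not certify behaviour
  under EM-register noise statistics.
* **Drift** (`make_smooth_drift`) is a random sum of 2–3 low-frequency
  sinusoids scaled to a target peak amplitude — smooth and slow, like
  thermal stage drift; no jumps, rotation, or heterogeneous motion.
* **Tracking scenes** draw per-axis increments `Normal(0, √(2Dτ))` per
  frame from one or more diffusive populations, with optional per-axis
  localization noise and per-frame blinking dropout.
* **Structural scenes** (`simulate_filament_table`) place emission events
  on a line grid; each event persists a geometric number of consecutive
  frames (mean 4) and is re-localized each frame with i.i.d. noise. The
  persistence makes the scene valid NeNA input; the static structure makes
  it valid FRC input. Real biological structures have curvature, varying
  line density, and unbound background that these scenes lack.

All generators are pure functions of their parameters and a seed.

## Temporal median filter

For pixel p and frame t the median over a window of `i` frames centered on
t is subtracted. The window is forced odd and, near the movie ends, shifted
(never shrunk) to keep exactly `i` frames — the statistic's breakdown point
stays constant. Default `i = 51` (~50 frames is typical; the window must
exceed roughly twice the longest single-emitter on-period). Negative
differences are clamped at 0 by default, with `clamp=False` for feeding the
signed result into detection. The filter must not be used when fluorophores
are on more than ~half the time; the package does not auto-detect this.
Implementation computes all distinct window medians once via a sliding
window view; frames near the edges index the first/last window.

## Detection and phasor localization

Detection runs on the DoG-filtered frame (σ = 1.0 / 2.0 px, bracketing the
PSF), thresholded at `median + k·1.4826·MAD` (k = 3 by default) — the
robust scale resists residual bright emitters. Retained candidates must be
local maxima of the *raw* frame; 3×3 plateau ties go to the smallest
(row, col). Peaks closer than twice the ROI half-size are all dropped (each
ROI must contain one fluorophore), and a border margin excludes ROIs that
would leave the frame.

The ROI (7×7 default) has its minimum subtracted as a local background
estimate; the sub-pixel offset comes from the phase of the first-order DFT
coefficients per axis. Sign and orientation are fixed by two anchor cases:
a centered PSF returns (0, 0) and a delta at integer pixel `(u0, v0)`
returns exactly `(u0−h, v0−h)`. A constant ROI (vanishing first-order
magnitude) is a degenerate fit and the candidate is dropped. Detection may
run on the median-filtered movie while ROIs are always cut from the raw
movie, preserving camera statistics for the position estimate. A
least-squares Gaussian fit exists in the test suite as an accuracy oracle
only; it is not a production path.

## Linking and merging

One linking primitive serves merging (radius ~0.5 px, 1–2 dark frames) and
tracking (larger radius). Frames are processed in order; for target frame t
heads ending at t−1 are matched first, then unmatched heads at t−2, etc.
Each frame pair is resolved globally greedily in ascending distance with
ties to the lower row index — this removes the input-order dependence of a
naive per-localization loop and makes linking deterministic. Merged tracks
collapse to the intensity-weighted mean position, minimum frame, and summed
intensity (total intensity is conserved; position precision improves
~√n). Tracks named in `exclude_ids` (e.g. fiducials) pass through. A
warning fires when > 5 % of merged tracks have average steps above half the
linking radius — the signature of high-density mis-linking.

## Drift correction

**Fiducials**: tracks spanning ≥ `min_presence_fraction` (default 0.9) of
the movie qualify. Each marker's displacement is taken relative to its own
first observation — this avoids bias when markers appear on different
frames — then averaged per frame across markers, interpolated over missing
frames, optionally smoothed by a moving average, and re-zeroed at frame 0.
With m markers of single-frame precision σ the trace noise is ~σ/√m; the
simulated 3-marker/3 nm scenario recovers a 50 nm drift with ≲ 4 nm RMSE.

**Cross-correlation** (static structures only): frames are partitioned into
temporal bins, each bin rendered as a 2D histogram at `zoom` sub-pixels per
camera pixel and smoothed with a 1-render-px Gaussian kernel — sparse
histogram renders otherwise produce a one-pixel-wide correlation peak whose
3-point parabola refinement is biased. Each bin's displacement relative to
bin 0 is the cross-correlation peak (spectral, with wrap-aware parabola
refinement per axis), assigned to the bin's temporal center; per-frame
values come from a cubic spline through the bin centers, flat beyond them.
The dominant error source is drift *within* a bin, which smears the
correlation peak; bins should be chosen so the expected within-bin drift
stays well below one render pixel. The default `bin_frames = n_frames/10`
suits slow drift; the acceptance scenario (0.8 px over 400 frames) uses 40
bins by that rule. Redundant all-pairs correlation, axial drift, and
rotation are out of scope.

## Chromatic correction

A full 6-parameter affine map (moving → reference) is solved by linear
least squares from ≥ 3 control-point pairs; a condition number above 1e8
(collinear design) raises. A translation-only mode serves dual-view
registration. Pairs come from an explicit CSV or the mutual-nearest-
neighbour helper. Correction is applied to localization coordinates, not to
rendered images. Higher-order distortion fields are out of scope.

## Rendering

Render bin `(r, c)` has its center at `((c+0.5)/zoom + xmin,
(r+0.5)/zoom + ymin)`. The histogram adds unit counts (half-open binning);
bilinear splits each unit weight over the 4 surrounding bin centers
(conserved exactly; edge weights are clamped into the raster); Gaussian
rendering adds a unit-integral kernel truncated at 4σ (conserved to
≪ 1 %). Default zoom 10 (≈10–15 typical); choosing render pixels much
smaller than the localization precision invents detail and triggers a
warning in the Gaussian renderer. Rendering with kernel width equal to the
localization precision broadens an imaged point by √2 — quantification
should use the localization list, not images. Scatter plots are available
in the CLI only, for comparison figures.

## Tracking statistics

Jump distances take only consecutive-frame pairs within a track
(gap-spanning pairs excluded). The JD histogram is fitted by least squares
with the Rayleigh mixture (D initialised from quantiles of `r²/4τ`,
fractions via softmax); the fit is repeated at half and double the bin
count and flagged when any D moves > 10 % — histogram fits are
bin-sensitive. Localization error is *not* subtracted, so fitted values are
apparent D*. The mJD route fits a Gaussian mixture to per-track mean jumps
(tracks with ≥ 4 jumps) and converts means via `E[r] = √(πDτ)`, exact only
for pure 2D Brownian motion — a documented approximation, since the mJD of
finite tracks has no closed form. The ensemble MSD is fitted on the first 4
lags only (short-track noise grows with lag), weighted by pair counts, with
the intercept clipped at 0 when estimating σ_loc.

## Clustering

DBSCAN with the neighbour count including the point itself (standard
convention; `count_self=False` provided since conventions differ).
Distances in nm when requested, else px. Cluster expansion is an iterative
worklist — output-identical to the textbook recursion without stack limits.
Determinism: components are numbered by their smallest core row index (BFS
in row order) and an edge point adjacent to several clusters joins the
lowest-labeled one, removing classic DBSCAN order dependence. Known limits:
a single global density threshold (no hierarchy), and degraded behaviour
when density anisotropy matches the search radius.

## Resolution and precision

**FRC**: the table is split uniformly at random (seeded) — an odd/even
frame split would correlate the halves through multi-frame emission and
overestimate resolution; the published spurious-correlation correction
factor is not implemented. Halves are rendered on a shared square raster
(pad factor 1.25); rings are integer-rounded radial frequency indices; the
curve is smoothed by a centered 7-ring moving average before the first
downward 1/7 crossing, linearly interpolated. The render pixel should be of
order half the expected precision (5 nm for 10 nm data); FRC is sensitive
to this choice. Without a crossing inside Nyquist the result is returned as
"not reached" with the curve.

**NeNA**: next-frame nearest-neighbour distances within a 2 px capture
radius (the radius is a documented choice; the core law has no background
terms — the original method's linear + broad background corrections are
omitted). The Rayleigh fit's σ is the per-axis precision. NeNA needs
non-merged data and fails when emitters live ≪ 1 frame. On simulated static
scenes the FRC resolution always respects the 2σ Nyquist bound of the NeNA
precision.

## Numerical and testing notes

Fits run in log-parameter space with softmax fractions, so constraints hold
by construction; approximate covariances come from the Gauss–Newton
Jacobian. All stochastic tests are seeded; oracle tests (sliding-median,
brute-force DBSCAN, direct DFT phase, Gaussian-fit localization) compare
implementations against independently written references. Problem sizes in
the test and acceptance suites (e.g. 10⁴–10⁵ localizations, 400–2000
frames, 10⁴–2·10⁴ jumps) were chosen as the smallest scales at which the
statistical claims are cleanly resolvable; all complete in seconds to a few
minutes on one CPU.
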