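# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices a maintainer should know about.

## Stiffness maps

A stiffness map is a 2D grid of elastic moduli in kPa with an isotropic
pixel size and an operator-supplied ROI (no automatic segmentation is
attempted; tumor contouring is manual in practice).  Statistics are
computed over in-ROI pixels only.  Conventions:

- The stiff-area fraction counts pixels **strictly** above the threshold
  (default 40 kPa, a published cut-off for "very stiff" tumor regions); a
  pixel at exactly 40 kPa is not stiff.
- SD uses the sample estimator (n−1).
- Elastography dropouts (NaN or negative sentinel pixels inside the ROI)
  are excluded from all statistics and reported as a `dropout_fraction`;
  the stiff-fraction denominator is the valid-pixel count, which equals the
  ROI pixel count whenever there are no dropouts.  Infinite pixels are
  treated as data corruption and raise.
- ROI polygons are rasterized with pixel-center membership
  (`skimage.draw.polygon2mask`); for simple (non-self-intersecting)
  contours all fill rules coincide.
- Coordinates are 0-based row-major, (row, col) = (y, x).
- Normalized stiffness divides each timepoint's mean by the first
  timepoint's; the caliper volume is `x·y²/2` with x the longest and y the
  shortest perpendicular diameter (callers passing them swapped get an
  instructive error rather than a silent fix).

## Fiber tracing and architecture metrics

Curvelet-based tracers are effective but their parameters are rarely
reportable; this package instead uses a fully specified ridge/skeleton
pipeline so every step is testable:

1. Gaussian smoothing (default 0.5 µm) and intensity thresholding (Otsu on
   the smoothed image unless an absolute threshold is given).
2. Skeletonization of the binary mask; branch points (≥3 skeleton
   neighbours) are removed and the remaining simple arcs become candidate
   fibers, each walked end-to-end into an ordered path.
3. Sub-pixel path smoothing by moving average (window 7 samples, endpoints
   pinned so lengths are not shortened).
4. Width from the Euclidean distance transform along the path: full width
   = 2 × median distance-to-edge, minus one pixel because the EDT measures
   to the nearest *background pixel center* (half a pixel beyond the true
   edge on each side).
5. Length = path arc length + one local half-width per end.  Skeletonizing
   a round-capped ribbon erodes the skeleton back to roughly the cap
   centers, so the half-width extension recovers the tip-to-tip fiber
   extent.  Fiber length is defined tip-to-tip throughout (generator and
   tracer agree on this definition).
6. Fibers shorter than 20 µm are discarded (typical lower bound for a
   resolvable collagen fiber at this magnification).

Per-fiber orientation is the principal-axis angle of the path point cloud
folded into [0°, 180°), measured from the image x-axis.  The orientation CV
(sample SD / mean of angles in degrees) is deliberately non-circular to
match how the alignment statistic is conventionally computed from
directionality histograms; it is frame-dependent, so comparisons are only
meaningful with a fixed angular reference, and a mean angle of exactly 0°
raises with advice to rotate the frame.  On benchmark renders (20 images ×
5 straight fibers, widths 3–8 µm, lengths 40–120 µm, 0.5 µm pixels) the
tracer's median absolute errors are ≈4.7% (width), ≈0.7% (length) and
≈0.03° (orientation).

Sirius-red quantification classifies red-orange birefringence in HSV
space: hue ≤ 40° or ≥ 320° with value above a darkness floor (default 0.1,
separating tissue from empty glass; the floor is a free parameter because
illumination varies between rigs).  A simpler red-dominance mode
(R > G and R > B) is available for comparison.  Both are invariant to a
common positive rescaling of all channels.

Crosslink (PYD/DPD) autofluorescence is the mean fluorescence over an
SHG-positive mask minus a background estimate; negative values are
reported as-is rather than clipped, since they carry information about the
background estimate.

## AFM indentation

The paraxial Hertz sphere model `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}` is used,
valid for indentations small relative to the bead radius; the default fit
window (0, R] keeps the paraxial error second-order for the 2.25 µm bead
radius default.  The model is linear in E, so the least-squares fit is the
closed-form projection `E = Σ F·g / Σ g²` (clipped at 0), with curves whose
relative residual exceeds 0.5 rejected as non-Hertzian.  Defaults mirror a
standard soft-tissue setup: spring constant 0.6 N/m, 4.5 µm bead diameter,
Poisson ratio 0.5 (incompressible).

Contact-point estimation first removes linear baseline drift (fit to the
leading 10% of samples), then takes the latest split index whose
pre-contact deflection variance is still at the baseline noise floor —
equivalent to maximizing the after/before variance ratio with the flat
pre-contact plateau tie-broken toward the contact onset.  Detection
requires a ×10 variance contrast; flat curves raise.  On noiseless
synthetic approach curves the estimate lands within ±2 samples of the true
contact index and is invariant to baseline offset and linear drift.  The
converted curve uses the *detrended* deflection, so drift does not leak
into force.

Per-sample summaries pool all points of all maps (nine 64-point maps per
sample in the motivating protocol) rather than averaging per-map means;
with balanced maps the two coincide, and pooling keeps the histogram and
the SD defined on the same population.  Histogram bin width defaults to
0.25 kPa.

## Cell tracks

Filters: samples with z < 15 µm (depth below the cut surface) are removed,
then tracks are kept only if their time span is strictly greater than 10%
of the recording (span = t_last − t_first, robust to gaps; a track of
exactly 10% is excluded).  Detection gaps up to 3 frames are bridged by the
straight segment between flanking samples; longer gaps split the track.
Statistics are 3D by default (a 2D-projected mode exists for comparability
with planar trackers): speed = path length / duration in µm/min,
displacement = Euclidean first→last distance, straightness = displacement /
path length (defined as 0 for a zero-length path).

## Synthetic generators

Reproducibility: one integer seed fans out to per-object substreams via
`numpy` seed sequences (`default_rng([seed, k])`), so generating an extra
object never perturbs earlier ones; same seed ⇒ bit-identical output.

- **Stiffness maps**: clipped Gaussian background (default 10 ± 3 kPa, the
  soft-tumor regime) with disc patches set to a patch stiffness (default
  60 kPa — well above the 40 kPa cut); the exact pixel count above 40 kPa
  is returned as ground truth.
- **Fiber renders**: round-capped thick polylines with optional sinusoidal
  waviness, anti-aliased edges, 0.5 µm Gaussian blur and Poisson noise
  over a 5-count background at 100-count fiber amplitude (SNR ≈ 10,
  typical of decent SHG).  Default widths 3–8 µm and lengths 40–120 µm
  cover the thin-to-thick fiber regimes reported across carcinoma models.
  Placement is rejection sampling with a 3 µm separation so fibers are
  individually resolvable; a denser, overlapping packing can be produced
  by relaxing `min_separation_um`/`max_overlap_frac`.
- **Force curves**: exact Hertz forward model on a uniform indentation
  grid with seeded additive and/or multiplicative Gaussian noise; raw
  approach curves solve the cantilever force balance by Newton iteration
  and can include linear drift and deflection noise.
- **Tracks**: 3D persistent random walks with constant step length
  (speed × 30 s frame interval), per-step Gaussian heading rotation about
  a random perpendicular axis, reflective boundaries, and z confined to
  the 15–80 µm imaging window.  Defaults (3 µm/min, 20 min at 30 s frames)
  sit in the reported range of intratumoral T-cell speeds (≈2.3–4.1
  µm/min), and moderate dispersion gives mean straightness ≈ 0.4, matching
  typical tumor observations.

What the generators do **not** emulate: SHG polarization physics and
backscatter, fiber branching and bundling, spatially varying elastography
noise, cell–cell interactions, tissue drift during imaging, and tracking
errors (false links, dropped detections beyond simple gaps).  Passing the
recovery tests therefore shows the estimators are correct on geometrically
realistic inputs, not that the tracer would match a curvelet tracer on raw
tissue images.

In the demo cohort the per-subject latent stiffness scale couples the
stiffness and motility generators deterministically (speed falls 1.5% per
1% stiffness increase), so per-group correlations are near-perfect by
construction up to track-sampling noise; only the sign and approximate
magnitude of the pooled slope are meaningful.

## Statistics

"Student's t" is the classical pooled-variance two-sample test (Welch
behind a flag); Mann–Whitney uses exact enumeration up to n = 8 per group
without ties and the tie-corrected normal approximation otherwise.  ANOVA
and Kruskal–Wallis are exposed as independent omnibus tests, with Dunn's
rank-based test (hand-implemented, tie-corrected) as the post-hoc and Holm
correction available but off by default.  The stiffness–motility layer is
plain OLS per treatment group with Pearson r; two-point fits are returned
but flagged degenerate.

## Problem sizes

Test and benchmark sizes were chosen to estimate each quantity stably at
desk scale: 20 render images (100 fibers), 100 noisy force-curve
replicates, 200 tracks per speed estimate, 80–100 tracks per dispersion
level, 16-subject demo cohorts, and 100 random instances per brute-force
oracle check.

## Known limitations

- The tracer assumes non-branching, mostly separable fibers; heavily
  overlapping networks fragment at branch points into sub-fibers.
- The orientation CV inherits the frame dependence of the underlying
  convention; it is reported, not fixed.
- The Hertz fit ignores finite-thickness and adhesion corrections.
- Reflected persistent-random-walk steps slightly understate path length
  at boundaries (sampled polyline folds at the wall), a bias < 0.5% at the
  default geometry and shared by real trackers.
- The exact-sphere (Sneddon series) indenter mode is not implemented; the
  paraxial model is the single supported contact geometry.
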