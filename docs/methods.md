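# Methods

This note documents the models and procedures implemented in `compeye`,
the parameter choices that matter, what the synthetic generators do and
do not emulate, and the numerical decisions made where the design was
genuinely open.

## Depth-from-focus surface reconstruction

A through-focus image series samples the scene at focal planes spaced
`delta_h` micrometers apart. The focus score at each pixel and layer is
the standard deviation of intensity in a square window (default 5×5 px),
a local-contrast measure that is invariant to adding a constant to all
intensities and monotone in sharpness for natural textures. The surface
height at a pixel is `delta_h` times the score argmax over layers,
refined by fitting a parabola through the three scores around the argmax
(offset clipped to ±0.5 layers; ties and edge layers keep the integer
argmax, with ties resolved toward the lower layer). Heights are measured
from layer 0's focal plane and increase with layer index.

The eye mask keeps pixels whose best score exceeds 0.1× the global
maximum, then keeps the largest connected component and fills holes.
A stack whose focus scores are identically zero (featureless) raises an
explicit error rather than returning a meaningless surface. The
composite image takes each pixel from its best-focus layer.

Known limitation: any window-based focus metric blends the heights of
neighboring pixels, so height error grows with the product of surface
slope and window radius, and with the defocus blur radius. On the
synthetic cap below this yields ≈0.9 µm RMSE — well under one layer
step — but exact layer attribution degrades wherever the local height
range across the window approaches half a layer step.

## Sphere fit and field of view

The sphere fit linearizes the sphere equation into `f = A c` with
`f = [x²+y²+z²]`, `A = [2x, 2y, 2z, 1]`, and
`c = [x0, y0, z0, r²−x0²−y0²−z0²]ᵀ`, solves for `c` by ordinary least
squares, and takes the radius as the mean distance of the points to the
fitted center. Coplanar inputs make the center unidentifiable and raise
an error.

Goodness of fit is the coefficient of determination of observed surface
heights (z) against sphere-predicted heights, with each point explained
by the nearer sphere branch. An R² on radial distances would be
degenerate here: the fitted radius *is* the mean radial distance, so the
residual and total sums of squares coincide and R² would be identically
zero; height-space R² matches how one actually inspects such fits and
equals 1 on exact spheres.

Bead calibration regresses nominal bead radius on pipeline-measured
radius through the origin; on synthetic beads of 50/250/500 µm nominal
radius the scale factor is within 1% of unity.

For the field of view, each masked pixel is mapped to its direction from
the fitted center; the polar axis is the mean direction (centroid ray),
and the chart is azimuthal-equidistant — a point at angular distance θ
and azimuth φ from the axis maps to (θ cos φ, θ sin φ) in degrees — so
chart distances are visual angles. The mask outline is subsampled to at
most 720 points and fitted with a direct algebraic least-squares ellipse
(skimage's `EllipseModel`). The ellipse axis better aligned with the
anatomically vertical chart direction (recorded with the image; default
the chart y axis) is reported as the vertical FOV component; fly eyes
are taller than wide, so this is normally the major axis. The FOV area
is the ellipse area in square degrees.

## Ommatidia detection

The all-in-focus eye image is mean-subtracted inside the mask and
tapered to zero at the mask edge with a raised-cosine (Hann) profile
over ~10 px to suppress boundary ringing; the reciprocal image is the
centered Fourier magnitude spectrum. A hexagonal facet lattice produces
six first-order peaks at radius `2/(√3 s)` cycles/px for spacing `s`
(four peaks at `1/s` for a square lattice).

Detection is gated by the image's 2D autocorrelation (the inverse
transform of the power spectrum, normalized to its zero-lag value): a
periodic lattice produces off-center autocorrelation maxima near its
lattice vectors, whereas white noise produces none above ~1/√N. If no
off-center local maximum reaches the prominence threshold (default 0.1),
a no-lattice error is raised. Otherwise the innermost autocorrelation
peaks give the lattice spacing (sub-pixel parabolic refinement), which
seeds an annulus search on the smoothed spectrum for up to six
fundamental peaks, refined to sub-pixel and symmetrized into ± pairs.

Facet centers are local maxima of the image low-pass filtered at
1.25× the fundamental radius (hard radial cutoff with a raised-cosine
rolloff of 0.4× the cutoff), with minimum separation 0.7 lattice
spacings, restricted to the mask, and refined to sub-pixel. Per-facet
diameter is the median distance to lattice neighbors (neighbors within
0.5–1.5 spacings among the 6 nearest) times the pixel scale — lenses
tile contiguously, so center-to-neighbor spacing is the facet diameter.
The headline facet diameter `D` for downstream optics averages the
`n_center` facets nearest the mask centroid (default 300; if fewer are
found, all are used and a warning is recorded).

## Optical limits and the summation model

From `D` (µm) and `R` (µm): interommatidial angle `Δφ = D/R` (radians;
degrees at interfaces), corneal lens area `A = π(D/2)²` (µm²),
diffraction-limited wavelength `λ_max = 2 D Δφ` with D in nm, and
ommatidial density = count / eye area (mm⁻²).

The spatial-summation model uses a Gaussian modulation transfer
function, `MTF(ν) = exp(−(π Δρ ν)² / (4 ln 2))`, where Δρ is the
half-width acceptance angle in degrees and ν the spatial frequency in
cycles/degree. Neural pooling widens the effective acceptance angle to
`√(Δρ² + p²)` for pooling angle `p` and multiplies the photon catch by
the pooled/unpooled area ratio, so
`SNR(ν) = C · MTF(ν) · √(N · gain)` for contrast C and photon rate N.
Every constant is an explicit parameter. The model's two contractual
properties — pooling lowers the MTF at every ν > 0, and raises SNR only
below a single crossover frequency — are asserted programmatically; the
curves themselves are illustrative, not calibrated to a particular
photoreceptor.

## Allometric statistics

Traits scale as `Y = a X^b`; both are log-transformed and fitted by OLS,
`log Y = log a + b log X`. The exponent is classified from its 95% CI:
CI entirely below 0 → inverse; containing 0 → constant; containing 1 →
isometric; entirely inside (0,1) → hypoallometric; entirely above 1 →
hyperallometric. Display bands are 84% confidence bands for the mean
response, computed in log space and exponentiated — the conventional
level for comparing two regression means at α ≈ 0.05 by band overlap.
They are mean-response bands, not prediction bands.

Trait lengths come from eight landmarks: eye = |ab|, head = |cd|,
conventional thorax = |gh|, thorax segment = |de|, abdomen = |ef|, and
body = |cd| + |de| + |ef| (the three-segment sum is robust to bent
abdomens). A zero-length segment (duplicated landmark) flags the row
invalid rather than raising.

Group comparisons use one-way ANOVA plus all pairwise t tests (pooled
variance by default; Welch by flag) with Šidák–Holm step-down
adjustment: at step k of m ordered p-values, adjusted
p = 1 − (1 − p₍ₖ₎)^(m−k+1), enforced monotone. The implementation
delegates to statsmodels' `holm-sidak` method and is verified against a
hand-computed example.

## Optomotor psychophysics

Per trial, ΔWBA(t) = left(t) − right(t), negated for rightward stimuli
so positive always means steering with the stimulus, and
baseline-corrected by subtracting the mean over the 0.2 s still period.
Left and right presentations of the same grating are folded (averaged
after sign correction). The per-trial response is the mean over 0.5–2 s
after presentation onset (responses lag stimulus onset by ~0.3 s, so
this window covers 0.3–1.8 s of motion). Condition means are normalized
to the maximum condition within each species × lighting × experiment
group, so the best condition maps to 1; values below −1 are possible
only if a non-maximal condition is more strongly negative than the
maximum is positive, and are permitted.

Detection uses a bootstrap over flies — the independent unit under
repeated measures — with B = 10 000 replicates: a condition is detected
iff the lower bound of the 99% CI of its mean exceeds zero. The CI is
the studentized (bootstrap-t) interval rather than the plain percentile
interval: at n ≈ 20 flies the percentile interval's one-sided
false-positive rate is ≈0.011 — about double nominal, because its lower
bound is effectively a z-threshold applied to a t-distributed statistic
— while the studentized interval simulates at the nominal 0.005. With
zero variance across flies the interval degenerates to a point.

Thresholds: contrast sensitivity = 1/C_min (reported to 1 decimal, raw
value retained) with C_min the lowest detected contrast; spatial
acuity = highest detected spatial frequency (right-censored when the
grid top is still detected); temporal acuity = the largest *detected*
frequency whose successor's normalized mean drops by more than 50% —
"significant and substantial" — with the largest detected frequency
returned right-censored when no such drop occurs inside the grid.
Relative change from A to B is (A − B)/A, reported as an integer
percent. All grids are data, not constants.

## Synthetic generators

The generators supply every input with embedded truth; all are
deterministic given their seed.

**Eye and bead stacks.** A spherical cap (default R = 250 µm, 30°
half-angles, 20 layers) is rendered with per-pixel surface height
`√(R² − d²) − z_ref`. The scene texture is a hexagonal lattice of
Gaussian bright spots (facets; default 20 µm spacing, spot σ = 0.2
spacing) over a per-pixel random grain (amplitude 0.5). Defocus is a
Gaussian blur whose σ grows 4 px per layer step of distance from the
surface; each layer interpolates linearly between precomputed blur
levels, so per-pixel sharpness is continuous and maximal exactly at the
nearest layer. The layer step defaults to 6 µm: ~20 steps then span the
depth range a whole fly eye occupies under a stepped-focus microscope,
and the step comfortably exceeds the reconstruction's ~0.9 µm height
noise, keeping the sharpest layer identifiable (≈97% of cap pixels).
These choices matter: fine-grained (uncorrelated) texture gives every
window uniform texture variance, without which locally flat patches are
won by a *defocused* layer whose blur imports energy from bright
neighbors. Bead stacks use the same renderer with grain-only texture, a
40° cap, and pixel scale/layer step scaled to the nominal radius. The
renderer does not emulate specular glints, vignetting, curvature-induced
spacing foreshortening at the cap rim, or sensor shot noise beyond a
small additive Gaussian — so passing tests certify the geometry and
detection pipeline, not robustness to those artifacts.

**Trait tables.** X is log-uniform over 1.5–3 mm (a fly body-length
range); Y = a X^b with lognormal noise (default σ_log = 0.05, about the
residual scatter of insect trait regressions).

**ΔWBA trials.** Per fly × condition × direction, a 3 s, 1 kHz trace
pair: zero-mean still period, then a plateau reached by 0.4 s at
gain_f · r(c) · S(ν_s) · T(ν_t) + ε, with per-fly gain ~ N(1, 0.15),
per-(fly, condition) deviation ε ~ N(0, 0.06) shared across directions,
and white trace noise (SD 0.25 wingbeat units). The contrast response is
a Hill saturation `(c/C50)^q / (1 + (c/C50)^q)` with C50 = 0.24 and
q = 5; spatial tuning is a steep low-pass `exp(−(ν/0.12)⁸)` in CPD;
temporal tuning is band-pass (second-order high-pass cornered at 2 Hz ×
`exp(−(f/25)⁴)` low-pass). The steepness is deliberate: thresholds are
only recoverable exactly when every tested grid value is clearly sub- or
super-threshold, and these defaults put each grid point at ≤0.2× or ≥2×
the detection criterion `z₀.₉₉₅ · fly_sd / √n_flies` (the margin
analysis must use the noncentral-t spread of the detection statistic,
sd ≈ 1.3, not a plain z). Truth thresholds are the grid values where the
expected responses cross that criterion (temporal acuity additionally
applies the >50% drop rule to the expected means). The generator does
not emulate habituation, arousal drift, aliasing near the display's
refresh rate, or direction asymmetries.

## Problem sizes and numerics

Default benchmark sizes: 5 000 points × 20 seeds for noisy sphere
recovery; 3 bead stacks; 10 lattice images over spacings 10–40 px;
500 replicates for allometric calibration; 1 000 simulations for the
null false-positive rate; 50 simulated experiments (20 flies × 10
contrasts × 2 directions × 3 s at 1 kHz) for end-to-end threshold
recovery. These sizes give Monte-Carlo standard errors well inside the
asserted tolerances while keeping the full suite fast.

Numerical choices: focus ties break toward the lower layer; parabolic
offsets are clipped to ±0.5 layer; the sphere system is solved with
`numpy.linalg.lstsq` and rank-checked; FFT peak refinement clips
parabolic offsets to ±0.5 px; percentiles use NumPy's default linear
interpolation; all angle math is in radians internally with degrees at
interfaces.
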