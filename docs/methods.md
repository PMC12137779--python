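# Methods

This note documents the models, estimators, parameters and design choices in
`cdti`, and what the phantom-based tests do and do not establish.

## Registration engine

**Model.** One stationary velocity field `v(p)` per image pair, with the
forward and inverse displacement fields obtained as group exponentials
`exp(v)` and `exp(−v)` by scaling and squaring (default 6 squaring steps).
Because the two fields are exponentials of `±v`, inverse consistency holds by
construction up to the numerical error of the exponential; the residual
`mean |forward ∘ inverse|` is computed for every pair and is typically below
0.01 px (tolerance `ic_tol = 0.1 px`; pairs above `10 × ic_tol` are flagged
downstream, never discarded).

**Similarity.** Both images are locally standardized: Gaussian local mean
removed and divided by the Gaussian local standard deviation
(`lncc_window_sigma`, default 2 px), with a variance floor of
`(0.05 × global SD)²` so flat air regions generate no force.  Classic demons
forces are then computed on the standardized intensities with the symmetric
(mean-gradient) form and per-pixel step normalization.  Minimizing the
pointwise squared difference of locally z-scored images is equivalent to
maximizing windowed normalized cross-correlation, so the metric is invariant
to locally linear intensity relationships — which is what lets b50 frames
register directly to b500 frames with no diffusion-contrast modeling.

**Symmetry.** Each iteration warps the moving image by `exp(v)` and the
fixed image by `exp(−v)`, computes opposed demons updates on the two grids,
and applies half their difference, so the two inputs are treated
interchangeably; swapping them swaps the roles of the forward and inverse
fields (verified to 0.25 px mean).

**Regularization and schedule.** The update is fluid-smoothed
(`sigma_fluid = 2 px`), added to `v`, and `v` is diffusion-smoothed
(`sigma_diffusion = 5 px`) every iteration.  Three pyramid levels
(anti-aliased ×2 downsampling) with fixed iteration counts `[80, 50, 25]`
(coarse→fine) and no early exit: determinism is a contract (identical inputs
give bit-identical fields).  Forces are zeroed on a 2-px border.

The window and stiffness defaults were chosen on phantom pairs with known
motion: respiratory motion in short-axis slices is dominantly bulk
translation with a smooth deformable component, and a small correlation
window with a stiff field recovers it to ~0.1–0.3 px while refusing to chase
the azimuthal intensity modulation that diffusion encoding imprints on the
wall at b = 500 (a per-direction pattern that a compliant field happily
"corrects", distorting the myocardium).  A wider window (4 px) or a softer
field (1.5 px) leaves 0.4–1.7 px residuals on the same pairs.  If the final
similarity is worse than the unregistered start, the identity transform (the
initial iterate) is returned with a warning — non-convergence is not an
error.

## Motion-correction schedules

`moco_naive` registers all frames to the first acquired b50 frame.
`moco_avg` works in three stages: (1) the 12 b50 frames are registered to
the first b50 frame and averaged into a high-SNR reference; (2) each high-b
frame is registered to that reference, then averaged within diffusion
direction; (3) each per-direction average is registered to the reference
once more.  Every frame is resampled exactly once, using the field that maps
reference-grid points into the moving frame, so averaging happens after a
single interpolation.

The averaged output of `moco_avg` carries the stage-1-corrected *individual*
b50 frames (the protocol acquires one average per low-b direction, so there
is nothing to average) plus the stage-3 high-b averages — 24 frames for the
12-direction protocol.  Low-b frames are treated as diffusion-weighted
measurements with their own encoding directions throughout (b = 50 carries
real, if small, attenuation), so the tensor fit is a genuine two-shell fit.

## Tensor fit and maps

Frames are interpolated (cubic spline) from the acquired 2.7 mm grid to a
~1.4 mm map grid before fitting (output grid `ceil(n·spacing/target)` pixels,
field of view preserved).  The fit solves `ln S = ln S0 − b gᵀ D g` per pixel
with `b` scaled by 10⁻³ so `D` comes out in μm²/ms: one OLS pass, then one
weighted pass with weights equal to squared predicted signals, which restores
minimum-variance weighting after the log transform.  Signals at or below
10⁻⁶ of the frame maximum are excluded per pixel; pixels with fewer than 7
usable measurements are dropped.  Eigenvalues are clipped at zero before
MD/FA; a pixel whose top two eigenvalues coincide (relative gap < 10⁻⁸) has
no principal direction and is masked.

## LV geometry, helix angle, HAT

Transmural depth is `100·d_endo/(d_endo + d_epi)` from Euclidean distances
to the densely resampled contours — adequate for convex short-axis walls and
deterministic, in preference to Laplace-equation depth.  The radial unit
vector follows the gradient of the signed wall coordinate; `long` is the
slice normal and `circ = long × rad` closes a right-handed orthonormal
triad.  Helix angle is the signed angle in the circ–long tangent plane
between `circ` and the projection of the primary eigenvector, with the
eigenvector sign fixed so its circumferential component is non-negative
(HA ∈ (−90°, 90°]); pixels whose tangent-plane projection norm is below 0.2
are masked.  HAT is estimated as the ordinary-least-squares slope of HA
against depth within each of 6 equal angular sectors about the LV centroid,
and the global HAT is the mean of sector slopes (sectors with fewer than 10
valid pixels are excluded).  The estimator is the simplest one consistent
with °/% units; nothing downstream depends on the sectorization beyond
robustness to regional dropouts.

## Epicardium line-tracking metric

Profiles are sampled bilinearly along a user-placed head-foot line after
interpolation to the map grid (one sample per interpolated pixel by
default).  Per frame, the epicardium index is the argmax of the *forward*
first difference (`d[i] = p[i+1] − p[i]`, reported at `i`, no pre-filtering)
within a window of ±5 samples around a user-supplied center; ties break
toward the window center.  The population SD (÷N — the frames are the whole
population of interest) of the indices is the motion statistic.  Group
comparisons use two-sided paired t-tests with Bonferroni adjustment
`p_adj = min(1, p·m)`; identical samples return p = 1 by convention.  The
signed maximum is the default (the tracked interface is a rising edge); an
absolute-value option exists for falling edges.

## Phantom

The generator emulates the protocol: per slice 12 low-b frames
(b = 50 s/mm², 12 directions, 1 average) then 96 high-b frames
(b = 500 s/mm², 8 averages, direction-major), matrix 128 × 48 at
2.7 × 2.7 mm, row axis head–foot.  The scene is an elliptical torso
(S0 0.55, D 1.0 μm²/ms iso), a lung region anterior of the heart (S0 0.05 —
the low-signal interface that makes the epicardial edge trackable, as
in vivo), a circular LV wall (S0 1.0, radii 7/16 px) and a blood pool
(S0 0.85, D 3.0 iso).  Myocardial tensors have eigenvalues
(2.0, 1.2, 1.0) μm²/ms (MD 1.40, FA 0.361) with the primary eigenvector
following a linear transmural helix-angle rule +60° (endo) → −60° (epi), so
ground-truth HAT is exactly −1.2 °/%.  Signals follow
`S = S0·exp(−b gᵀDg)` with a 0.5-px Gaussian PSF; directions are
electrostatically spread on the half-sphere (deterministic per seed).

Motion is a sinusoidal row translation (default amplitude 5 px, period 10
frames, phase 0 so the first frame is at the neutral position) with a 20 %
column component and an optional smooth non-rigid component
(`deformation_fraction`, a Gaussian bump of 18-px scale near the heart).
Noise is Rician with `σ = (mean LV b50 signal)/SNR`; default SNR 25, typical
of 8-average spin-echo cardiac DWI at 3 T.  Geometry is defined in
millimetres with pixel centers at `(i+½)·spacing`, so truth maps are
evaluated analytically on any resampled grid — truth is never interpolated.

**What the phantom does not model:** through-plane motion (the pipeline is
2-D by design), cardiac-phase strain, EPI distortion, eddy currents,
realistic respiratory spectra or hysteresis (a hook accepts user-supplied
traces via per-frame jitter), and partial-volume fat.  Passing phantom tests
therefore demonstrates the correctness of the estimators and the
registration contract under known ground truth, not clinical performance.

## Evaluation harness and problem sizes

`end_to_end_recovery` runs phantom → MOCO → fit → maps → tracking and scores
against truth.  Map errors are medians over the analytic wall mask at map
resolution eroded by 2 px, excluding the partial-volume rim that belongs to
no tissue compartment; HAT is estimated on the same eroded core.
Registration endpoint error is the LV-mean magnitude of
`true_motion ∘ estimated_forward` (zero when the correction exactly undoes
the simulated motion).

Multi-seed motion experiments (the SD-collapse and schedule-ordering
comparisons, five seeds each) use a 2-average high-b phantom — 36 frames per
series instead of 108.  Frame count affects only how densely the respiratory
sinusoid is sampled, not the per-frame registration problem, and the reduced
series keeps the full suite to a few minutes; the noiseless exactness run
and the unit tests exercise the full 108-frame protocol.

## Known limitations

* Depth by two-distance normalization is biased for strongly non-convex
  walls; the HAT estimator assumes HA is approximately linear in depth.
* The registration is 2-D: through-plane motion appears as signal
  inconsistency it cannot correct (flagged pairs, not repaired).
* The gradient-direction reference frame is fixed to image coordinates
  (row, col, slice-normal); vendor data may need reorientation before use.
* Outlier frames are flagged (inverse-consistency failure) but never
  discarded; rejection policy is left to the caller.
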