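# Methods

This note documents the models, parameter conventions, numerical choices,
and limitations of `retinastats`. Everything here is implemented in the
package and exercised by the test suite; no empirical claim is made that
the suite does not compute.

## 1. Eye model and visual-field geometry

The eye is a thin lens focused at infinity with focal length `f` and a
spherical retina of radius `r = f/2` centered at `c = (0, 0, -r)` behind
the optical center at the origin. Built-in models: human (`f = 16.67 mm`,
eye height 1.8 m) and cat (`f = 12.5 mm`, eye height 0.25 m).

A visual-field location is addressed by eccentricity φ ∈ [0°, 90°) and
polar angle χ (counter-clockwise from +x, +y up; χ = 90° is the upper
visual field). Its image on the conventional plane `z = -f` is

    p'_P = [ f·tanφ·cosχ,  f·tanφ·sinχ,  -f ]

and on the retinal sphere

    p'_T = [ f·sinφ·cosφ·cosχ,  f·sinφ·cosφ·sinχ,  -f·cos²φ ].

The sphere passes through the optical center, so the sphere point is the
closed-form along-ray intersection `t = 2 (p·c)/|p|²` of the ray through
`p'_P`. The plane tangent to the sphere at `p'_T` has outward normal
`(p'_T - c)/r` (tilted by exactly 2φ against the optical axis) and an
orthonormal in-plane basis whose first vector points along the local
radial (increasing-φ) direction.

### Tangent-plane approximation error

Spherical patches have no global pixel raster, so each patch is analyzed
on its local tangent plane. `tangent_approx_error` enumerates the pixel
centers of a patch on the tangent plane (pixel pitch inherited from the
full planar frame: `2·f·tan(fov/2)/resolution`) and reports the maximal
3D distance to the sphere, pairing points along rays through the optical
center (`pairing="ray"`; `"perpendicular"` gives the minimal-distance
pairing instead). For the human eye, a 120° frame at 5,954 px, and a
128-px patch this yields 0.0536 mm at φ = 30° and 0.0739 mm at φ = 50° —
the scale of the acceptance targets `t1`/`t2`.

### Planar-to-tangent homography

The planar patch around `p'_P` and the tangent patch around `p'_T` are
images of the same scene on two planes through the same center of
projection, hence related by a homography. With `B` and `A` the 3D
embeddings of the centered planar/tangent pixel frames (columns: pixel
axes scaled by the pitch, then the patch center), corresponding pixels
satisfy `A q' ∝ B q`, so `H ∝ A⁻¹B`, normalized to `H[2,2] = 1`.
`warp_to_tangent` applies `H⁻¹` through `skimage`'s `ProjectiveTransform`
with bilinear interpolation; output pixels whose preimage leaves the
source are invalid, and a requested output size larger than the valid
preimage raises (at φ = 50° the worst polar angles support an output
roughly `in_px/4.2` wide, which dictates capture-to-analysis size
ratios). The warp path is validated against an independent oracle that
ray-casts directly through tangent-plane pixel centers (normalized cross
correlation > 0.99 at φ ∈ {30°, 50°}).

## 2. Scenes, trajectories, and gaze

Scenes are procedural and fully deterministic given a seed; they are
generated at run time, never shipped as data.

**Forest.** A Poisson stand of vertical cylinder trunks (density 0.015
per m², radii 0.12–0.40 m) over a fractal-value-noise textured ground
with optional track striping; near-horizontal branches (Poisson mean 8
per trunk, tilt ≤ ±0.12 rad), fallen logs, and low undergrowth clutter
provide horizontal and oblique structure; aerial-perspective fog
(attenuation length 120 m) limits effective depth. The generator was
calibrated once so that central ensembles show the two hallmark
statistics of natural scenes at test scale — a radial power slope α ≈ 2
and a cardinal ({0°, 90°}) bimodal edge-orientation distribution — and
then frozen; it was not adjusted afterwards.

**Random-edge control.** Line segments with i.i.d. uniform 3D
orientations and uniform positions in a slab spanning −12 m to +15 m
around the ground plane (approximately symmetric about eye height), with
no ground and no sky gradient. Any orientation structure in rendered
patches is therefore attributable to perspective projection. The
pipeline sizes this scene to the trajectory's bounding box at constant
volumetric segment density (0.08 per m³) so patch-level edge counts do
not depend on trajectory length.

**Trajectories and gaze.** Avatars follow a correlated random walk at
eye height (speed 1.4 m/s, one pose every 2 s, heading increments
N(0, 15°)). Gaze strategies: `straight` (heading, 0° elevation), `down`
(heading, −30°), and `random` (heading/elevation offsets N(0, 1 rad);
1 rad = 57.2958°). Study-scale defaults are 663 poses and the
17-position grid {0°, 30°, 50°} × 8 polar angles (the center collapses
across polar angle), i.e. 11,271 patches per run.

Rendering is a vectorized ray caster (Lambertian shading, fixed light
direction) over ground, cylinders, and capsule segments, with bounding
cone culling per patch. Patches are converted to CIE-Y luminance from
linear RGB.

Because consecutive poses along one walk re-view the same surfaces,
ensemble statistics converge slowly in pose count;
`run_generate_pooled(config, n_scenes)` pools several short walks
through independently seeded scenes, which is how all test-scale
ensembles are built.

## 3. Second-order statistics

For an ensemble of N patches the mean power spectrum averages
`|FFT2((I - μ)/μ · w)|²`, where μ is the Hamming-weighted patch mean and
`w` a radially symmetric Hamming window (0.54 + 0.46·cos(πρ/ρmax), value
0.08 at the window radius, zero outside). The orthonormal FFT convention
is used, so total spectral power equals windowed-contrast energy
(Parseval).

**Radial slope.** `radial_average` fits the log-log slope α on the
unbinned (log f, log P) pixel pairs in the band 0.05–0.4 cycles/px
(binned profiles are returned for display only). For the elliptical
model below with β = 1 this recovers α = 2 to better than 10⁻³ —
acceptance target `t6`.

**Elliptical power law.** Spectra are summarized by

    Γ(u, v) = A / (u_r² + v_r²/b)^β,

with `(u_r, v_r)` the frequency coordinates rotated by θ. Fitting is
nonlinear least squares in the log-power domain over all non-DC
frequencies below 0.45 cycles/px, multi-started at θ₀ ∈ {0°, 45°, 90°,
135°}, with bounds 10⁻³ < A < 1, 10⁻³ < b < 1, 0.5 < β < 2,
0 ≤ θ < 180°. `b` near 1 means isotropy (flagged at b ≥ 0.98);
`elongation = 1/b` grows with anisotropy. The division-form of `b` is
the default (`b_mode="divide"`); the multiplication form is available
as a switch.

**Orientation conventions.** In the division form, the fitted θ marks
the *spectral ridge*, which is perpendicular to the dominant image
orientation, and the FFT angle is additionally mirrored relative to the
y-up image frame (rows run downward). The image-orientation equivalent
reported in the tables is therefore `theta_edge_deg = (90° − θ) mod
180°`, verified against synthetic oriented stripes.

## 4. Higher-order statistics

Gradients use the matched 5-tap derivative/prefilter pair (rotation
error ≈ 2%); the orientation tensor (Gaussian-smoothed outer product,
5×5, σ = 1.2 px) yields energy (eigenvalue sum), orientedness
(normalized eigenvalue difference), and edge orientation (perpendicular
to the gradient, y-up convention). Edge pixels are those with energy
strictly above the per-image 68th percentile and orientedness strictly
above 0.8, excluding filter borders (and eroded warp-validity borders).

Edge orientations are axial (period 180°). Following the usual
convention they are doubled before any circular fit, and both the fitted
mean *and* the concentration are halved for reporting (the doubled-space
κ₂ is retained on every fit object). The two-component von Mises
mixture is fit by EM in doubled space with deterministic
histogram-mode initialization; degenerate runs (a collapsing weight)
fall back to a single component and are flagged.

## 5. Circular inference

- **Circular–circular association** uses the Fisher–Lee T-linear
  statistic (pairwise sine differences) with a permutation p-value.
  It remains well-defined when a marginal is uniform on the circle —
  which is exactly the situation when correlating orientations with the
  polar angle around a ring — where mean-direction-based statistics
  degenerate. A radial bias predicts orientation = χ mod 180°, so both
  variables are angle-doubled before correlating.
- **Watson–Williams** compares mean directions across groups (classical
  F with the (1 + 3/(8κ)) correction; a flag marks low-concentration
  regimes where the test is invalid). Type-I error is calibrated to
  5% ± 2% in simulation.
- **Two-sample Kuiper** uses the maximal ECDF deviations above plus
  below (rotation invariant) with the standard asymptotic p-value
  series (p = 1 below the small-λ validity cutoff).

## 6. Test-scale configuration

The study-scale defaults (5,954-px frames, 512/128-px patches, 663
poses) are faithful but expensive. The test suite and examples use a
reduced scale chosen once from geometry and budget constraints, not
tuned on outcomes: 1,024-px frames, 48–64-px analysis patches, 8–16
poses per walk, 2–4 pooled scenes; projection comparisons use 224-px
capture patches so the φ = 50° tangent warp has sufficient planar
support (ratio ≥ 4.2). All documented findings (radial bias,
eccentricity growth, cardinal bias, strategy contrast, projection
effect) hold at this scale with the stated significance levels.

## 7. Limitations

- The renderer is a stylized ray caster: no global illumination,
  specularity, foliage, or photometric calibration. Absolute spectral
  amplitudes are not comparable to photographic ensembles; the package's
  claims are about *relative* structure across the visual field.
- On these synthetic ensembles the fitted amplitude A frequently rests
  at its lower bound 10⁻³ (the cross-position power range exceeds the
  parameter box under any single normalization), which lets β absorb
  some amplitude misfit. The bias applies equally to planar and tangent
  projections, so paired contrasts remain meaningful, but absolute
  A/β values should be read with care.
- The elliptical model has a single orientation; genuinely bimodal
  spectra (e.g. cardinal scenes) are summarized by whichever ridge
  dominates.
- The Watson–Williams test assumes comparable concentrations and is
  flagged, not refused, at low concentration; edge pixels within a
  patch are spatially correlated, so its nominal significance levels on
  rendered ensembles are optimistic. The Kuiper and permutation tests
  are used for the headline comparisons.
- Halving the concentration κ alongside the mean when mapping fits back
  from doubled-angle space is a reporting convention kept for
  comparability; the doubled-space κ₂ is always available.
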