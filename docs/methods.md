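# Methods

This note documents the models, the simulation conditions, the numerical
choices, and what the tests do and do not establish.

## Coordinate conventions

All lengths are millimetres in a right-handed eye-centered frame: +z is
anterior along the visual ("length") axis, +x the eye's width, +y its
height. "Anterior crop" and the coronal clipping plane refer to this z
axis.

## Sphere fitting (SF)

The sphere equation is rearranged into a linear observation on
β = (2x₀, 2y₀, 2z₀, r² − ‖c‖²) with row H = (x, y, z, 1) and measurement
‖p‖². A linear Kalman filter with zero process noise performs the online
fit, which makes it exactly recursive least squares: with a diffuse prior
its state equals the batch posterior of the normal equations (verified to
1e-8 in the tests against an independently assembled solve).

Filter defaults: prior β₀ = (0, 0, 0, 144) — a 12 mm eye at the origin —
with covariance 1e4·I; measurement variance (2·r̄·σ)² with r̄ = 12 mm and
σ = 20 µm, the first-order propagation of distance noise through the
linearized observation. All are constructor arguments. The sphere is
reported only once ≥ 4 points have been absorbed ("mature" state).

## Ellipsoid fitting (EF)

The ten quadric coefficients are fit by least squares under the
ellipsoid-specific inequality 4(ab+bc+ac−f²−g²−h²) − (a+b+c)² > 0. The
solver is the direct one standard for this constraint family: center and
isotropically scale the data, build the 10-column design matrix, reduce
the scatter onto the six quadratic coefficients via the Schur complement,
and solve the generalized eigenproblem against the constraint's quadratic
form; the eigenvector with positive constraint value (and smallest
algebraic residual, if several) is kept and de-normalized. If no
eigenvector satisfies the constraint the result is flagged invalid — a
hyperboloid is never silently reported as an ellipsoid.

Geometric recovery normalizes the centered quadric to unit constant;
semi-axes are 1/√λᵢ of the normalized parameter matrix, ordered by
descending length with eigenvector signs fixed to det(R) = +1 for
deterministic output. Stored quadrics carry unit coefficient norm with
trace(A) > 0, removing the scale ambiguity of the algebraic form.

Residuals reported for both SF and EF are geometric RMS distances (not
algebraic), so the transition logic compares the two models on one scale.
EF is O(n) per fit and takes well under 0.1 s for 6000 points.

## Point-to-ellipsoid distance

Exact distances use the orthogonal-projection condition in the principal
frame: F(t) = Σ (dᵢyᵢ/(t+dᵢ²))² − 1 = 0. F is convex and strictly
decreasing on the admissible interval, and t₀ = maxᵢ(dᵢyᵢ − dᵢ²) has
F(t₀) ≥ 0, so Newton iteration from t₀ converges monotonically and
quadratically with no safeguarding; the implementation is vectorized
over points (10⁵+ points per call) and iterates to |F| < 1e-14.
Components exactly on a symmetry plane are nudged by 1e-13·d_max, which
keeps the root unique at an error far below every tolerance used.

## Test eye geometries

Every shape is star-shaped about the eye center and is represented by its
radial function R(u); the implicit form is ‖p‖ − R(p/‖p‖). Meshes come
from radially displacing a subdivided icosphere (vertices exactly on the
surface; watertight until half-clipped at z = 0 for the printed-phantom
geometry).

Regular shapes are axis-aligned ellipsoids. Full diameters follow the
per-diopter rates of axial refractive error — width 0.14, height 0.10,
length 0.30 mm/diopter — applied with sign (growth for myopia, shrinkage
for hyperopia). The emmetropic base is (23.5, 23.0, 21.0) mm, a
distinctly oblate globe consistent with MRI morphometry of emmetropic
retinas. This choice is load-bearing: with the stated rates, −12 D
myopia (fast axial growth) makes the globe nearly spherical while +6 D
hyperopia makes it the most oblate of the three, which is exactly the
ordering of the sphere-fit global errors the simulation reproduces
(hyperopic > emmetropic > myopic). Defaults live in one config block
(`EyeShapeSpec`) and every knob is exposed.

Pathological shapes start from the −12 D myopic ellipsoid (high myopia
being the dominant risk factor for all three):

* **Pointed** — the posterior cap is replaced by a paraboloid
  z = −(A − B s²) (s the normalized transverse radius) whose apex extends
  1.2 mm beyond the ellipsoid pole; depth and slope are matched at the
  junction ring, so the composite is C1. A paraboloid joined at the
  coronal equator instead cannot stay within ~2 mm of the ellipsoid
  anywhere between equator and pole, which produces errors an order
  larger than a realistic posterior pointing.
* **Staphyloma** — an outward bump at the posterior pole with a smooth,
  compactly supported (mollifier) profile: amplitude 1.0 mm, support
  half-angle 45°. Compact support makes the surface *exactly* equal to
  the base ellipsoid outside the bump, a property the tests rely on; a
  Gaussian profile has no such support.
* **Detached** — an inward cosine-squared dome, depth 0.3 mm, angular
  radius 20°, centered 30° off the posterior pole.

Pathology sizes are fixed package defaults representing mild-to-moderate
presentations of each condition; they are part of the study conditions,
not per-experiment knobs (every parameter remains exposed on the spec
object for users who need other presentations).

## Scan simulation

The tip follows the Archimedean spiral f(θ) = (bθ/2π·cosθ, bθ/2π·sinθ, 0)
in the coronal plane through the eye center, b = 0.5 mm, 18 revolutions
(θ ≤ 36π). θ values come from the closed-form arc length so consecutive
points are 0.1 mm apart (the first few chords undercut the arc by up to
~15 % where the spiral's curvature radius is itself ~0.1 mm; from the 6th
segment the spacing is within 1 %).

The instrument is a straight line through the remote center of motion at
the trocar; the RCM sits at the anterior pole on the visual axis
(configurable). Each sample's beam points from the RCM through the tip;
the simulated distance is the range to the first beam-surface
intersection (closed form for ellipsoids, vectorized bisection on the
radial implicit otherwise) plus N(0, σ²) noise with σ = 20 µm, matching
the sensor's axial resolution class. Noise perturbs distances only;
poses are exact (robot repeatability is 5 µm, far below the optical
noise). One measurement is taken per trajectory point, timestamped at
the 2 kHz engine rate; noise is drawn from a counter-based (Philox)
stream keyed on the seed, so runs are bit-for-bit reproducible.

Synthetic A-scans place a Gaussian interface peak (width ≈ the 35 µm
axial resolution) at distance/pitch on Rayleigh speckle, with the
speckle generated in a frame attached to the interface — two A-scans of
the same tissue at different distances are shifted copies, which is the
"similar intensity distribution" assumption template matching needs.
Default depth axis: 60 mm over 1024 samples (pitch ≈ 58.6 µm).

## A-scan distance extraction and synchronization

The initial distance is pitch × the index of the most prominent peak
(prominence ≥ 5× the background MAD by default; configurable). Later
scans are matched to a reference scan by normalized (zero-mean,
unit-norm) cross-correlation with parabolic sub-sample refinement;
estimates below a correlation floor of 0.3 are flagged invalid. Streams
are synchronized by resampling both series to the faster native rate,
cross-correlating, and refining the peak parabolically; the returned τ
satisfies b(t + τ) ≈ a(t) and is antisymmetric under argument exchange.

## Sensor-pose calibration

The sensor pose relative to the robot flange (3 offset components + 2
axis direction components; roll about a 1D beam is unobservable and not
parameterized) is estimated from distances to a plate measured at many
flange poses, using only the constraint that all reconstructed points lie
on one plane. The plate pose is not assumed: the objective is the
smallest principal-component variance of the reconstructed points, which
co-estimates the plane. SLSQP minimizes it, followed by a
Levenberg-Marquardt polish on the out-of-plane residual vector, giving
exact recovery (≤ 1e-6 mm / 1e-8 rad) on noise-free data and a mean
plane residual below 30 µm at 20 µm distance noise with 250 poses. The
fixture sampler draws flange poses in a 30° rotation cone with ±20 mm
translations around a 15 mm standoff; near-parallel beams are resampled
and counted. The sensitivity analysis perturbs the assumed pose
(vertical offset, in-plane beam rotation) on a sphere-scan fixture and
reports the absolute fitted-diameter error; the true pose attains the
grid minimum and the error grows monotonically along each half-axis.

## Adaptive model and transition

Points are appended to a buffer whose scan range (greatest pairwise
distance) is maintained exactly and incrementally; SF updates per point;
EF re-fits every 5 accepted points (cadence configurable, first attempt
at 10 points). Criteria are evaluated on EF ticks only, for determinism:

1. scan range > 20 mm;
2. EF valid and EF geometric RMS < SF geometric RMS on the full buffer;
3. max relative semi-axis change between consecutive EF fits < 0.03 %
   sustained over more than 15 consecutive fits ("more than 15" means the
   16th consecutive stable fit turns the criterion on; an invalid fit or
   a jump resets the streak).

The transition is monotone (never reverts) and requires all three
criteria simultaneously at one tick (no latching); the point count at
that tick is recorded. A per-tick CSV log (range, residuals, variation,
criterion booleans, mode) supports auditing.

## Evaluation metrics

The ground-truth eyes are point clouds by construction, so all three
error metrics are nearest-neighbour distances between sampled clouds:
model and ground truth are sampled on 500×500 uniform (θ, φ) spherical
grids (uniform angles; resolution configurable) and points within 5 mm
of the anterior extreme are cropped. MMAE = measured points → ground
truth; FMAE = measured points → fitted surface; MAE = ground-truth
samples → fitted surface (directional, truth → model). SDs are standard
deviations of the absolute deviations across sample points, pooled over
seeds. This sampled-cloud definition carries a quantization floor of a
few tens of microns which adds in quadrature to the 16 µm half-normal
noise mean — that floor is a deliberate part of the metric, reflecting
the point-cloud ground truth, and is why the simulated MMAE sits near
46 µm rather than 16 µm.

Transition-timing traces (the "optimal transition" = first EF tick where
the EF global MAE drops below the SF's) instead use exact analytic
distances on a coarser 60×60 ground-truth sampling: only the SF/EF
*ordering* enters, and a quantization common to both models cancels from
an ordering, so the cheap exact trace identifies the same crossing.

## Experiment matrix and problem sizes

The default experiment runs 6 shapes × 10 seeds; each run is one full
spiral (≈ 5092 samples), adaptive modeling with EF cadence 5, final
metrics at 500×500, and MAE traces every 10th EF tick at 60×60 — about
4-5 s per run on one CPU. The pytest acceptance layer runs the same
pipeline with 3 seeds. Per-seed and pooled outputs are both retained;
results are deterministic given the seed list. The evaluation CLI also
accepts external measured point clouds for users with their own rigs
(computing MMAE/FMAE against a supplied reference).

## Known limitations

* The metric's NN quantization floor means global MAEs below ~30 µm are
  not resolvable at 500×500 sampling; exact-distance functions are
  available where finer resolution matters.
* The simulator omits pose noise, beam divergence, refraction at
  intraocular interfaces and tissue deformation; passing tests therefore
  demonstrate correctness of the modeling and transition machinery under
  calibrated sensor noise, not robustness to real-world systematics
  (segmentation errors, synchronization residuals, registration).
* An ellipsoid cannot represent local features (detachment dome, fovea,
  optic disc); for such shapes the sphere remains the better global
  model, which the transition criteria are designed to respect.
* The hyperopic eye's strong oblateness makes its optimal transition
  very early (~16 % of the scan), so the criteria-based transition lags
  it by ~44 % of the trajectory — the stability criterion, which binds
  at ~60 % progress for every shape under 20 µm noise, sets that floor.
* Sphere-fit error magnitudes for the regular shapes depend on the
  chosen base dimensions; the defaults are representative of population
  morphometry, not patient-specific measurements.
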