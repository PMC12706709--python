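# Methods

## Signal model and reconstruction

The package targets time-resolved three-directional phase-contrast MRI
acquired with simple asymmetric 4-point encoding: one flow-compensated
reference encoding (magnitude *S*) and three orthogonal motion encodings
(magnitudes *Sᵢ*, phase differences *φᵢ*). Velocity along direction *i*
is `uᵢ = φᵢ/kv` with `kv = π/VENC` (VENC in m/s). The intravoxel
velocity standard deviation follows from the magnitude attenuation of the
encoded signal, `σᵢ = (1/kv)·√(2·ln(S/Sᵢ))`, which is exact when the
velocity distribution inside a voxel is Gaussian per direction — the
assumption under which the phantom generates its signals, so noise-free
round trips are exact to floating precision. TKE density is
`½·ρ·Σσᵢ²` with ρ = 1060 kg/m³.

Numerical policies for the inversion:

- `σᵢ = 0` wherever `Sᵢ ≥ S` (noise can push the ratio below 1) or
  `S = 0`. This rectification makes σ estimates at σ_true = 0
  non-negative by construction — a noise floor, not a bug, and tested as
  a property.
- Where the ratio would imply `σᵢ·kv > 2` (encoded signal below e⁻² of
  the reference) the value is capped and the voxel flagged unreliable;
  the inversion is ill-conditioned there.
- σ estimation uses magnitudes only, so it needs no phase corrections;
  velocity is computed first and then corrected.

**Phase-wrap correction.** For each voxel/frame/direction the candidates
`u + k·2·VENC`, `k ∈ {−1, 0, +1}` are scored by the sum of absolute
differences to the two cyclic temporal neighbors and to the spatial
median of the 6-neighborhood; the cheapest candidate wins, ties keep
`k = 0`. The sweep repeats to a fixpoint (≤ 10 passes): a wrapped jet
core wider than one voxel is peeled from its boundary inward, while a
wrap-free field converges unchanged in one pass (idempotence). The
corrector assumes at most single wraps (|u| < 2·VENC), which the phantom
enforces by construction.

**Background-offset correction.** Per direction, a spatial polynomial
(order 0–3, default 2, monomials on coordinates normalized to [−1, 1]) is
least-squares fitted to the time-averaged velocity inside a static-tissue
mask and subtracted from all frames. The phantom provides the true static
mask (body voxels outside every flow region, zero prescribed velocity);
on real data a mask can be derived from temporal velocity stability
(`pipeline.derive_static_mask`). The static mask must contain at least 50
voxels and at least as many as the basis has terms.

## Synthetic phantom

The phantom emulates the structure of a whole-heart 4D flow exam:
isotropic 2.8 mm voxels, 40 reconstructed time frames and VENC 120 cm/s
by default — typical clinical values for this acquisition type. Five
regions move over the cycle: the ascending aorta as a straight tube
(radius 14 mm at full field of view) with a parabolic axial profile
peaking in systole (1.1 m/s), and four chambers as spheres with
physiological volume curves (LV 60–150 mL, biphasic refilling whose
E-wave slope is ~3× the A-wave slope) carrying Gaussian-profile inflow
jets (LV E-wave peak 1.0 m/s). Turbulence is a uniform σ baseline
(0.02 m/s) plus a jet-shaped Gaussian elevation (peaks 0.18–0.30 m/s),
identical in all three directions. All speeds stay below VENC by default
so the default phantom is wrap-free; `jet_speed_scale > 1` plants single
wraps for testing the corrector. Region positions and sizes scale with
the field of view, so reduced grids give geometrically similar phantoms.

Chamber masks are regenerated each frame as the N voxels nearest the
(moving) center, N fixed by the prescribed volume; this keeps the
voxelized volume within one voxel of the prescription, which a hard
radius threshold cannot guarantee. Noise is complex Gaussian added
independently per encoding (std = mean body-support s₀ / SNR, so air does
not dilute the reference level), making magnitudes Rician and phase
differences re-derived from the noisy complex pair. A low-order
polynomial phase, added identically to all encodings and frames, emulates
background offsets. All randomness flows from the single spec seed.

What the phantom does **not** emulate: k-space truncation and partial
volume at vessel walls, eddy-current and concomitant-field residuals,
respiratory motion, contrast-agent dynamics, segmentation error, and
non-Gaussian intravoxel velocity distributions. Passing round-trip tests
therefore demonstrates correctness of the estimators under their model
assumptions, not robustness to every artifact of real scans.

## Geometry

- Cavity volume = voxel count × voxel volume; EDV/ESV are the extremes of
  the volume curve (frame indices are not prescribed) and stroke volume
  their difference.
- Sphere-equivalent diameter `D = (6V/π)^⅓` for the non-tubular cavities.
- Aortic centerline: mask voxels form a 26-connected graph with edge
  weights scaled by inverse distance-to-wall squared, so the shortest
  path between the two geodesically farthest points (double Dijkstra)
  hugs the medial axis; the path is refined by perpendicular-slab
  centroid averaging (slab ±0.75 voxel, radially capped at the lumen
  radius, end tangents borrowed from the interior), smoothed with a
  3-point moving average and resampled to ~1-voxel arc-length spacing.
  On a voxelized straight tube the result deviates < 0.5 voxel from the
  true axis; on a 90°-bent tube the arc length is within ~2% of the
  analytic value. Masks that are disconnected or thinner than ~1.5
  voxels in radius are rejected as non-tubular.
- Aortic diameter: at 10 evenly spaced centerline points (excluding 10%
  at each end) the mask is intersected with a one-voxel-thick slab normal
  to the local tangent; the plane area is in-slab voxel volume divided by
  slab thickness, and `D = mean(2·√(A/π))`. Accuracy is one voxel size on
  voxelized cylinders, improving with resolution.
- Du Bois body surface area `0.007184·W^0.425·H^0.725` (W kg, H cm).

## Hemodynamic summaries

Per region and frame: TKE_tot = Σ_mask TKE × voxel volume (mJ); TKE_max =
max over the mask of the 3×3×3 median-filtered TKE (filtering on the full
grid before masking, edge replication, so near-wall voxels keep complete
neighborhoods); Vel_avg/Vel_max = mean/max speed over the mask.

Cardiac time points come from the LV segmentation volume curve: peak
systole is the most negative cyclic central difference dV/dt, peak early
filling the most positive dV/dt within the first half of the interval
from the volume minimum to the subsequent maximum (isolating the E-wave
from the atrial kick); ties break toward the earlier frame. The RV uses
the LV-derived frames for consistency. Summaries average over ±1 frame at
40 frames (±2.5% of the cycle; `round(0.025·n)` frames, minimum 1, for
other frame counts). Diameters are taken at the single frame of the
global peak of Vel_avg (mean diameter) and Vel_max (max diameter), not
window-averaged, and Reynolds numbers `Re = ρ·v·D/μ` (μ = 4·10⁻³ Pa·s)
pair the window-averaged velocity summaries with those diameters. Both
constants are overridable within plausible physiologic bounds
(ρ 900–1200 kg/m³, μ 10⁻³–10⁻² Pa·s).

## Cohort statistics

- Pearson correlation with 95% CI from the Fisher z-transform
  (`tanh(atanh r ± z₀.₉₇₅/√(n−3))`), p from the t-distribution with n−2
  df.
- Two-way ANCOVA per (region, lesion) sub-cohort against the shared
  control group: OLS fit of `outcome ~ VHD + age + VHD:age`, controls as
  reference; subjects carrying several lesions enter several fits.
  Degenerate designs (missing group, rank deficiency) are skipped with a
  reason.
- Two-group comparisons gate on Shapiro–Wilk normality at α = 0.05: both
  normal → Student's t, otherwise Wilcoxon rank-sum (exact for tie-free
  samples ≤ 20, normal approximation with tie correction otherwise).
  Summaries use the same gate to choose mean ± SD versus median [Q1, Q3]
  (linear-interpolation quartiles); constant samples are flagged
  degenerate.
- Sex differences use Pearson chi-squared on the 2×2 table without
  continuity correction.
- No multiple-testing correction by default, matching the reporting
  convention of single-study VHD cohorts; Benjamini–Hochberg is available
  as a switch on the ANCOVA table.

The synthetic cohort generator plants known lesion effects, an age trend
and a velocity–TKE correlation, with controls younger than cases as in a
typical retrospective cohort, so recovery of each planted quantity is
testable.

## Problem sizes and tolerances

The test suite uses reduced phantoms (32³ voxels, 8–10 frames) for
routine checks and the full 64³ × 40-frame geometry for the signal-model
round trip; the acceptance script uses 64³ × 40 for round trips, 48³ for
the cylinder oracle, 24³ for correction and determinism checks, 10 noise
seeds at SNR 30, and 400 null replicates for the ANCOVA type-I rate.
Noise-free round trips are asserted at 10⁻¹⁰ (achieved ~10⁻¹⁵); geometry
oracles at one voxel size; the background-correction residual at
10⁻³ m/s RMS; noise recovery within 10% of truth; noiseless ANCOVA
coefficients at 10⁻¹⁰.

## Known limitations

- The unwrap corrector handles single wraps only and can fail where a
  wrapped region has no reliable temporal or spatial anchor.
- Plane areas on coarse masks carry one-voxel-level discretization error;
  very short or sharply kinked vessels may yield fewer than the requested
  number of valid planes.
- Time-point detection requires a usable LV volume curve with at least 8
  frames and nonzero excursion; atypical curves (e.g. fused E/A waves at
  low frame rates) may shift the early-diastole frame by a frame.
- The σ estimator's rectified noise floor biases TKE upward at very low
  true turbulence and low SNR; the bias is negligible at the default
  phantom's SNR but should be kept in mind for real low-SNR data.
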