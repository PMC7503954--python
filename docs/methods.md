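# Methods

`nirdot` reconstructs task-related cortical hemoglobin changes from
dual-wavelength continuous-wave (CW) fNIRS channel data and maps
single-subject activation as thresholded voxel t-scores.  This note
records the model, the numerical choices, and what the synthetic data do
and do not establish.

## Signal chain

1. **Optical density.** Channel DC intensities are mean-normalized and
   log-transformed, `OD(t) = -ln(I(t) / <I>_t)`, making the data
   dimensionless and gain-invariant.
2. **Motion correction.** Samples whose first difference exceeds 8 robust
   (MAD-based) SDs are flagged, dilated by 0.5 s and bridged with a cubic
   spline fitted to 2 s of flanking clean data; a residual baseline offset
   larger than 6 robust SDs is treated as a step artifact and the tail
   re-leveled.  Channels with more than 50 % flagged samples are dropped.
   Unflagged samples outside a logged artifact's influence region are
   returned bit-identical.
3. **Band-pass.** Zero-lag 4th-order Butterworth, 0.01–0.3 Hz, applied
   forward and backward (`sosfiltfilt`) with odd-reflection padding of
   three settling lengths (one settling length = half a period of the low
   cutoff).  After filtering the series is decimated by keeping every 8th
   sample (39.7365 Hz → 4.97 Hz); the retained band ends at 0.3 Hz, well
   under the new Nyquist.
4. **Forward model.** CW photon diffusion
   `-div(D grad Phi) + mu_a Phi = q`, `D = 1/(3(mu_a + mu_s'))`, is solved
   on a regular voxel grid (7-point finite volume, harmonic-mean interface
   diffusion, Robin partial-current boundaries with the internal-reflection
   parameter from the tissue refractive index 1.4).  Sources/detectors are
   modelled as isotropic point sources one transport mean free path below
   the scalp surface; detector fields are obtained by reciprocity.  The
   sparse SPD system is solved by Jacobi-preconditioned conjugate
   gradients to a 1e-10 relative residual.  On a homogeneous slab the
   solver agrees with the extrapolated-boundary semi-infinite Green's
   function within 10 % over 10–40 mm separations at 2 mm voxels.
5. **Jacobian.** Rytov/adjoint absorption sensitivity
   `J[ch, v] = Phi_s(v) Phi_d(v) h^3 / A_sd`, mapping voxel absorption
   change (mm^-1) to channel OD change.  This is the exact first-order
   derivative of the discrete forward model with respect to the absorption
   (mass) term; the weak dependence of D on mu_a is deliberately outside
   the linearization.  Jacobians are cached in HDF5 keyed by a geometry
   hash of the head model.
6. **Sensitivity mask.** Per-voxel aggregate sensitivity is the
   channel-summed |J| averaged over the two wavelengths; voxels within a
   factor 1000 of the maximum are retained.  Statistics are reported only
   inside this mask.
7. **Inversion.** Minimum-norm Tikhonov,
   `x = J^T (J J^T + alpha tr(J J^T)/n_ch I)^-1 y`, with alpha = 0.01;
   the Cholesky factor is reused across time samples.  Regularization is
   spatially uniform (no depth weighting) by default — the minimal
   energy-minimizing solution; a depth-weighted variant was considered and
   left out to keep the estimator's bias transparent.  Time samples are
   inverted independently.
8. **Unmixing.** Per voxel, the 2x2 extinction system converts absorption
   changes at 690/830 nm to O2Hb/HHb (uM).  The extinction table (molar
   base-10 literature values converted to natural-log mm^-1 per uM) and
   DPF defaults (6.0 at 690 nm, 5.8 at 830 nm) live in `constants.py` and
   are shared by the generator and both inversion paths, so round trips
   are exact by construction.
9. **Statistics.**
   * Block designs: per-voxel OLS of the chromophore time course on the
     expected response (stimulation indicator ⊗ canonical double-gamma
     HRF, band-limited identically to the data) plus intercept and linear
     drift; flanking rest minutes are excluded from the fit.  t = beta/SE.
     For band-limited data the degrees of freedom are reduced to
     `n * 2 f_high / f_s` (floor 10) to account for filtering-induced
     autocorrelation; unfiltered data use n - p, under which the
     empirical null rate at t > 1.65 is 5 % (verified on 10,000
     white-noise voxels).
   * Unstructured tasks: chromophore SD in non-overlapping 10 s windows,
     pre-task rest minute vs task epoch, compared with a Welch t
     (task - rest).  The statistic responds to oscillation amplitude only
     and is exactly invariant to sign flips and constant offsets; it is
     thresholded one-sided (only amplitude increases are read as
     activation).
   * Threshold 1.65 = the one-sided standard-normal 0.05 critical value at
     table precision (1.645 → 1.65), uncorrected for multiple comparisons.

## Head model and probe

The head is a regular voxel grid (default 4 mm for end-to-end runs, 2 mm
for unit-scale work) with concentric layers — scalp/skull 10 mm, CSF 2 mm,
gray matter 6 mm, white matter filling the interior — as a slab (flat, for
oracle tests) or a hemisphere (curved scalp, for end-to-end runs).  Tissue
optical properties are a pinned literature compilation (e.g. gray matter
mu_a = 0.0178/0.0186 mm^-1 at 690/830 nm).  The probe is a 15-source,
15-detector interleaved prefrontal array (the instrument's 16th source
cannot be time-multiplexed and is never placed); channels are all pairs
with 10–45 mm separation (128 on the default hemisphere).  Digitized
optode positions are co-registered by closed-form three-fiducial Procrustes
alignment (nasion, left/right pre-auricular; rotation + translation, no
scaling) and snapped to the nearest surface voxel (≤ 15 mm).

## Synthetic data

The generator emulates the study conditions: 39.7365 Hz sampling, the SWG
block protocol (5 blocks of 3×10 s letters + 3×10 s symbols between 1-min
rests) or unstructured 2-min epochs, and a spherical gray-matter
activation of radius 10 mm with peak +1 uM O2Hb and HHb = -O2Hb/2.5
(within the 2–3× neurovascular band).  Nuisance terms: cardiac (1.1 Hz),
respiratory (0.25 Hz) and Mayer (0.1 Hz) oscillations with seeded random
phases in gray matter, random-walk drift, the same oscillation family in
the scalp layer (extracranial interference, gain 1), 0.3 % multiplicative
intensity noise, and Poisson motion events (0.5/min, 0.2 OD spikes, 30 %
baseline steps).  Oscillation amplitudes were set so that post-filter
channel hemoglobin noise SD is ≈ 0.15–0.25 uM.  Voxel dynamics are
represented as low-rank (spatial pattern × time course) components and
pushed through the same Jacobian and extinction table the inverse uses,
then exponentiated to intensities.

What this does *not* show: real heads are not layered hemispheres; real
physiological noise is broadband, spatially heterogeneous and partly
task-locked; real motion couples wavelengths imperfectly; and the forward
model used to generate and to invert is the same (an "inverse crime"
in the strict sense), so end-to-end tests validate the estimator's
statistical behaviour under the stated noise, not model-mismatch
robustness.  The analytic Green's-function and brute-force perturbation
oracles are the model-independent checks.

## Numerical choices and degenerate inputs

* CG tolerance 1e-10 relative; non-convergence raises with the residual.
* Point sources and field evaluations use trilinear weights over inside
  voxels (renormalized at the surface); oracle comparisons are made at
  voxel-center-aligned offsets.
* Ties in the sensitivity mask maximum are all retained;
  `attenuation_factor = 1` keeps exactly the argmax voxel(s); values < 1
  are rejected.
* Zero-variance voxels get t = 0 and a flag rather than NaN.
* Event tables must be sorted and non-overlapping; a zero-thickness layer
  simply removes that tissue; an all-rest design yields an all-zero
  design vector.
* Problem sizes used by the shipped checks: 4 mm hemisphere
  (36×36×20 grid, ~8,800 tissue voxels, 128 channels) for end-to-end
  recovery (20 seeds), 2 mm slabs for solver oracles; these keep a full
  run at a few seconds on one CPU.

## Known limitations

* No short-separation regression or global-signal removal; extracranial
  interference is handled only implicitly by depth-resolved inversion.
* Uniform Tikhonov underestimates depth: reconstructions are biased
  toward the scalp, which the 15 mm centroid criterion absorbs.
* The variance statistic assumes window SDs are approximately independent
  and normal; 6 rest windows is a small sample, so its t is approximate.
* The SNIRF reader covers the subset of the format the pipeline writes
  (CW amplitude, one data block).
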