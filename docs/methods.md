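# Methods

This package quantifies two errors that arise when a fast, correction-based
dose engine drives inverse planning of robotic lung SBRT under breathing
motion:

- **Dose prediction error (DPE)** — for a fixed plan, the difference between a
  DVH index recomputed with a gold-standard-style engine (`4MCrecal`) and the
  same index as scored by the optimizing ray-tracing engine (`4EPLopt`):
  `DPE = X(4MCrecal) − X(4EPLopt)`.
- **Optimization convergence error (OCE)** — the difference between a plan
  directly optimized with the gold-standard-style engine (`4MCopt`) and the
  recalculated ray-tracing plan: `OCE = X(4MCopt) − X(4MCrecal)`.

Both are evaluated on 4D-accumulated dose: per-phase dose with tracking
aperture shifts, pulled back to the end-of-exhale (EOE) reference frame
through displacement fields and summed with phase weights.

## Synthetic 4D phantom (`phantom4d`)

Clinical 4D CT is not shipped; a parametric thorax stands in:

- Regular grid, default 48x48x48 voxels at 3 mm (144 mm field of view).
  Axes: x lateral, y superior-inferior (principal motion), z
  anterior/posterior. All lengths mm, densities g/cc, doses cGy.
- Elliptic-cylinder water body (1.0 g/cc), two ellipsoidal lungs at a
  0.25 g/cc reference density, a spherical soft-tissue GTV inside the left
  lung, cord (with an optional 1.6 g/cc vertebral shield), esophagus, and a
  trachea modeled as a soft-tissue wall around an air lumen — the trachea
  *structure* is the wall, so its D2% is a tissue dose, not a dose to air.
- PTV = GTV dilated by 5 mm (discrete Euclidean ball, anisotropic spacing
  respected), clipped to the body.
- Breathing: ten equal time bins; the GTV centroid follows a 1-cos
  trajectory of configurable peak-to-peak amplitude along −y (inferior at
  inhale); the lungs stretch along the motion axis with the apex fixed and
  the diaphragm side following the excursion. Lung density is rescaled each
  phase so total lung mass is exactly conserved (the validator tolerates 1%
  voxelization drift).
- Displacement fields ("reference point x sits at x+u(x) in phase p") are
  analytic: a rigid GTV translation whose weight decays with the
  distance-transform ratio d_boundary/(d_boundary+d_GTV) to zero at the lung
  boundary, and is exactly zero outside the lung and on the reference phase.
  The per-phase density is constructed analytically rather than by warping
  the reference image, so the DVF is exactly consistent with the GTV motion
  (the tested contract) and approximately consistent with the parenchyma.
- Cohorts: GTV volumes log-uniform over 0.6-77.4 cc, amplitudes uniform over
  1.0-22.5 mm, prescriptions 60 Gy/3 fx or 48 Gy/4 fx (50/50) to 95% of the
  PTV; per-patient seeds derive from the master seed by a fixed offset, and
  the seed also jitters the GTV position inside the feasible lung region.

What the phantom does **not** emulate: CT texture and HU calibration, rib
cage anatomy, hysteresis or irregular breathing, and registration error —
the DVFs are ground truth by construction. Conclusions from passing tests
therefore concern the error-quantification machinery, not registration or
imaging physics.

## Dose engines (`dose_engines`)

Both engines share one beam model: a tissue-phantom-ratio table (default:
parabolic build-up to 1.0 at dmax = 15 mm, then exp(−mu_eff (d − dmax)) with
mu_eff = 0.005/mm), an error-function off-center ratio with a 3 mm penumbra
sigma, calibration 1 cGy/MU at dmax with the target at SAD = 800 mm, and
unit output factors. Measured tables can be injected from CSV; none of the
default numbers are vendor data.

- **Ray-tracing EPL engine.** Dose at x is
  `w · OF · TPR(d_rad(x)) · OCR(r·SAD/w) · (SAD/w)²`, with the radiological
  depth d_rad the density line integral toward the source. It is strictly
  local: no lateral transport couples to density.
- **Kernel surrogate.** The same primary, interpreted as energy release
  (primary x density), is redistributed laterally with Gaussian kernels of
  physical width sigma(x) = sigma0/rho(x), clipped to [sigma0, sigma_max]
  (defaults 3 and 9 mm) and discretized to 4 geometric sigma levels; the
  received energy is divided by local density (floored at 0.05 g/cc) to
  return to dose. In homogeneous water this is the identity on a flat field;
  at soft-tissue/lung interfaces the dense side loses scatter to the wide
  lung kernels — the lateral-electronic-disequilibrium signature. sigma0 = 0
  disables redistribution entirely (null-difference control); a constant
  `bias_cgy` inside a mask can be injected at the accumulated-dose level as
  a known engine discrepancy for parameter-recovery tests.
- **Statistical noise.** Monte-Carlo-style uncertainty is emulated by i.i.d.
  voxel noise with relative SD sigma_at_dmax·Dmax/D(x) (equivalently: a
  uniform absolute SD of sigma_at_dmax·Dmax on nonzero-dose voxels), seeded
  and clipped at zero; the per-voxel relative uncertainty map is
  sigma·Dmax/max(D, 1e-6·Dmax).

Numerics: the bulk calculators evaluate the primary on a beam-aligned
lattice with rays parallel to the central axis (w step 3 mm, lateral spacing
3.5 mm by default; the study pipeline uses 4 mm laterally). At SAD 800 mm
and aperture radii below ~40 mm the cone half-angle is under 3 degrees, so
the parallel-ray depth error is far below the lattice discretization error
(about one millimetre of water-equivalent depth, <1% in dose). The exact
Siddon voxel traversal (`radiological_depth`) is kept as the independent
oracle. Lattices are trimmed to the bounding box of the evaluated region
plus everything upstream that can attenuate. Both engines are exactly
linear in beam weights; energy is conserved by the redistribution up to the
configurable kernel truncation (2.5 sigma by default, 2.0 in the pipeline).

## 4D accumulation (`dose4d`)

Pull-back voxel warping: warped(x) = trilinear(dose_p, x + u_p(x)),
out-of-grid samples zero-filled and counted in the log; accumulation is the
phase-weighted sum with the reference phase contributing unwarped. No
energy/mass remapping is attempted — the deliberate mirror of the simple
voxel-warping accumulation whose errors this analysis studies. Trilinear
interpolation is exact on affine dose fields, which gives closed-form test
oracles (integer shifts, half-voxel shifts of a ramp).

## Sequential prioritized optimization (`planopt`)

Accumulated dose is linear in beam weights, so each clinical objective is a
linear program over the influence matrix (sampled voxels x beams, cGy/MU of
4D-accumulated dose, noise always off). The default priority sequence is

1. PTV coverage: minimize the mean hinge underdose below the prescription;
2. PTV minimum dose: maximize the floor, ceilinged at the prescription level
   (raising the floor above the prescription only inflates hot spots);
3. PTV maximum dose: conformity/homogenization step;
4.-6. cord, esophagus, trachea maximum dose;
7. lung V20Gy surrogate: minimize the mean hinge excess above 20 Gy;
8. total monitor units.

Each solved step freezes its achieved value (within a declared relaxation)
as a constraint on all later steps; the previous solution stays feasible, so
steps can only be skipped (with a logged reason, mirroring clinical practice
when objectives are already met) on numerical failure. Hard caps (cord
18 Gy, esophagus 27 Gy, trachea 30 Gy, PTV/body 160% of prescription) apply
in every step. A tiny total-MU tie-break (1e-6 cGy/MU) makes the solver
vertex unique and the output deterministic. The objective values and
relaxations are this package's declared defaults, not values inferred from
any clinical system.

Candidate beams: Fibonacci-lattice nodes on the anterior hemisphere (SAD
800 mm), one beam per node and collimator, all aimed at the GTV centroid.
The pipeline picks two collimator radii at 0.9x and 1.35x the PTV radius —
wide enough that the target sits in-field for every beam, which keeps the
optimized target dose homogeneous and the prescription normalization
(weights scaled so PTV D95% equals the prescription, evaluated with the
optimizing engine) close to unity. Tracking is emulated by translating each
beam with the phase GTV displacement.

After optimization the three arms are produced per patient: the EPL plan's
accumulated dose (4EPLopt), the same frozen weights recomputed with the
surrogate at the final noise level (4MCrecal, 1% sigma at Dmax), and an
independent surrogate-driven optimization (4MCopt, also finalized at 1%).

## Statistics (`dvh_stats`)

DVH indices use exact voxel quantiles (descending sort, linear
interpolation at fractional ranks); binned cumulative curves are kept for
plotting and agree with the order statistics within one bin. The panel is
GTV D98%, cord/esophagus/trachea D2%, lung V20Gy (lung excludes the GTV).

The minimal equivalence interval grows a symmetric margin from zero in
fixed steps (0.01 Gy for dose indices; 0.01 percentage points for V-type
indices, where the source protocol specifies the step only for dose) until
a paired TOST declares equivalence: both one-sided t-tests reject at
alpha = 0.05. With zero-variance differences the degenerate rule
|mean| < margin applies, so identical arms yield exactly one step. The
margin as a percent of the reference mean (DPE referenced to the 4MCrecal
mean, OCE to the 4MCopt mean) is flagged clinically significant when it
strictly exceeds 3%. Spearman rank correlation (ties mid-ranked, NaN on
constant input) relates the normalized GTV D98% DPE magnitude to GTV
volume.

## Study scale and reproducibility

The shipped study conditions are 10 synthetic patients, 150 nodes x 2
collimators (300 candidate beams), 10 phases, 48^3 grids at 3 mm, LP voxel
samples of <=350 PTV / 80 per OAR / 180 lung / 100 body voxels, noise-free
optimization and 1% final noise. A full study runs in a few CPU-minutes;
every quantity is reproducible bit-for-bit from (config, master seed),
including noise realizations. The cohort size and beam count are an order
of magnitude below a clinical planning system's, so cohort magnitudes
(means, equivalence percentages) characterize the synthetic conditions
rather than reproducing clinical values; the qualitative contrasts (EPL
overestimation of GTV D98%, its growth toward small tumors, the corrective
effect of direct surrogate optimization) are the tested outcomes.

## Known limitations

- The kernel surrogate reproduces the two properties the analysis needs
  (interface underdosage relative to EPL and 1/dose statistical noise); it
  is not a transport code, and absolute error magnitudes scale with sigma0,
  sigma_max and the phantom geometry.
- Single-aim-point cone beams leave a structural hot core in small targets;
  the conformity step and wide apertures mitigate but do not remove it.
- V-type equivalence steps and several objective defaults are declared
  package choices (see above) where the source protocol is silent.
- Dose in air cavities is regularized by the density floor and should not
  be interpreted quantitatively.
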