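# Methods

## Model and scope

`transitdose` implements EPID transit in-vivo dosimetry in a
two-dimensional approximation: all geometry lives in the CT slice
containing the isocenter. Coordinates are continuous centimetres with
the isocenter at the origin; `x` runs along the dose-reconstruction
segment (breast apex toward −x), `y` along the beam central axis away
from the source at `(0, −SAD)`. The lateral (gantry 90°) setup is the
only one modelled; couch rotations, 3D CT volumes and DICOM I/O are out
of scope. TPS doses are inputs, never computed.

The dose model is the calibrated correlation-function formalism:

* `F(w) = a1 w² + a2 w + a3` [CU/Gy], the transit-signal-to-midplane-dose
  ratio versus chord thickness, fitted on cylindrical water phantoms.
  Packaged defaults (6 MV, aS500 EPID at SED 150 cm, pooled 15°/30°
  wedges): `a1 = 5.819e−4`, `a2 = 2.880e−2`, `a3 = 5.480e−1`. The
  pooling is justified by the wedge independence of the measured ratios
  within ±0.5%; the fitter accepts wedge metadata but does not stratify.
* `f(d, r) = f0(r) d + 1`, the EPID scatter correction for a chord
  midpoint displaced `d` from the isocenter. Packaged slopes
  `f0 = {0.998, 1.487, 2.094, 2.756}×10⁻³ cm⁻¹` at
  `r = {6.0, 8.3, 10.7, 14.5}` cm. `f0` is interpolated linearly in `r`
  and clamped (with a warning) beyond the table — extrapolating a
  4-point table is worse than clamping. The calibration radius table
  lists 8.3 cm although the physical phantom is 8.25 cm; the table
  value is used.
* Midpoint dose: `Dm = S't · f(d,r)/F(w) · ((SAD+d)/SAD)²`; off-axis with
  the midpoint at the isocenter: `D = Sto/F(wo)` (small divergence —
  fan lines are nearly parallel to the axis at SED 150).
* Profile reconstruction: `D = Sto · C` with
  `C = f(d,r)/F(w') · ((SAD+d1)/SAD)² · ((SAD+d1)/(SAD+d1+d2))² ·
  exp(−μen/ρ·w2')`. `F` is evaluated at the *radiological* chord
  thickness `w'`; `f(d, r)` uses the central-axis chord's `d` and `r`
  and is held constant along the segment. The midpoint equation is used
  with the thickness the caller supplies; in water phantoms geometric
  and radiological thickness coincide, and the end-to-end workflow
  passes `w'` so that the two reconstruction routes agree on the axis.
* `μen/ρ = 2.73×10⁻² cm²/g` (water, 1.7 MeV mean energy of a 6 MV
  beam), configurable in `PhysicsConstants`.

Sign conventions: `d` and `d1` are source-distance offsets relative to
the SAD (positive = farther from the source); `d2 = dist(source, P') −
dist(source, P0)`, and `w2'` carries the sign of `d2`. All offsets are
measured along the fan line, which is exact rather than the
small-divergence vertical approximation.

## Geometry and numerics

* **Slices** are uniform grids of relative electron density (water = 1)
  sampled bilinearly; outside the grid is air. The body contour is the
  `body_threshold = 0.05` density crossing.
* **Ray tracing** marches each fan line at half the grid spacing;
  radiological thickness is a trapezoid cumulative integral; the
  half-thickness point P' and entry/exit are located by linear
  interpolation. Entry/exit positions are refined to the half-rise of
  the local density step: a near-zero threshold sits at the foot of the
  one-cell interpolation ramp of a discretised surface and would bias
  every chord outward by almost a full cell; the half-maximum is
  unbiased for symmetric ramps. Synthetic grids place cell centres half
  a cell off integer coordinates so that round-number contours fall
  between samples for the same reason.
* **Equivalent radius**: from the central-axis chord and its apex
  sagitta via `r = (w² + 4cp²)/(8cp)`; flat or unresolvable contours
  fall back to the largest calibrated radius with a warning.
* **Interface exclusion**: density steps > 0.2 (relative-density units)
  between adjacent samples at the grid spacing mark an interface; runs
  of flagged steps collapse to one interface position; profile points
  within 1 cm (configurable) are excluded. The air/tissue body edge is
  itself an interface, so near-apex points are excluded too.
* **Fits**: `F(w)` by unweighted least squares (`numpy.polyfit`,
  ≥ 4 samples, ≥ 3 distinct `w`); `f0(r)` per radius by least squares
  with the intercept fixed at 1 (`slope = Σd·y/Σd²` on `y = St/S't − 1`,
  ≥ 3 distinct `d` including a `d = 0` reference). Fit quality is
  recorded as 2× the SD of percent residuals.
* **Alignment**: the clinical 2D image matching is formalised as 1D
  edge registration along the only direction the 2D reconstruction
  consumes. The breast edge is the 50% crossing between the open-beam
  plateau (median of the top decile of samples) and the minimum
  attenuated level, interpolated sub-grid; the shift is the edge
  displacement from the planned reference, rescaled by SAD/SED when
  measured at the EPID plane. Resampling after alignment is linear;
  samples leaving the acquired support become NaN and are excluded
  downstream. The midpoint signal is the mean over the 5-sample
  (profiles) or 5×5-pixel window at the aS500 pitch (0.0784 cm at the
  EPID plane — a configurable default, not a vendor specification).

## Uncertainty budget and tolerances

`UncertaintyBudget` ships the nine 2 SD components of the midpoint
equation for the clinical setup (signal reproducibility 1.1%, F(w) fit
2.0%, f(d,r) fits 0.5%, inverse-square approximation 1.0%, radiological
thickness 1.0%, equivalent-square field 1.0%, linac output 2.0%, EPID
long-term stability 2.0%, portal-image alignment 2.0%) plus a 3.0% TPS
term. Their quadrature evaluates to 4.52%; the conventionally quoted
rounded figure is 4.4%. The module always computes from its inputs and
exposes both (`quadrature_2sd` vs the `PRINTED_MIDPOINT_2SD` constant)
rather than hard-coding the rounded value. Combined with the TPS term
and rounded to whole percent this yields the ±5% clinical tolerance on
`R = Dm/Dm,TPS`; sessions beyond tolerance are flagged in the report
(clinical follow-up actions are out of scope).

## The simulator: what it does and does not emulate

The forward model inverts the calibrated reconstruction relation per fan
line (`Sto = D_true/C`) instead of simulating radiation transport. This
is a deliberate design: round trips are exact at zero noise by
construction, which isolates the geometry, alignment, noise and
statistics behaviour actually under test. Consequences: passing tests
validate the *internal consistency* and the setup-error machinery of the
method, not the physical accuracy of `F(w)` itself (which comes from
measurement); scatter perturbations by low-density lung, wedge-shadow
shifts under misalignment, breathing motion and interface disequilibrium
are *not* emulated, so the simulator cannot reproduce the clinical
lung-dose bias or the wedge-driven PTV underdosage seen with real
fields.

Study conditions packaged as defaults: cylinder radii 6/8.25/10.7/14.5 cm
and displacements within ±4 cm (the calibration design); breast slice
with 7 cm apex radius, apex 3 cm from the beam axis, chest wall with a
density-0.3 lung recessed 1 cm; daily fraction 1.8 Gy at the midpoint;
multiplicative Gaussian signal noise with SD = half the 0.5% (2 SD)
reproducibility; setup-error SDs 3.5 mm (apex-lung) and 5.3 mm
(cranio-caudal, recorded but not corrected in 2D), systematic 1.5 mm.
The open-beam plateau outside the body projection is a fixed 3.0 CU —
enough contrast for edge detection; its absolute level is not modelled.
All randomness flows through explicit seeds; identical seeds give
bit-identical outputs.

Problem sizes used by the test suite and the acceptance script — grid
spacing 0.25 cm, profile sampling 0.1 cm, 20 cylinder cases (4 radii ×
5 offsets, ≈ 3550 profile points), 40-sample correlation fits, 9-point
scatter fits per radius, cohorts of 40–300 sessions — were chosen as the
smallest sets that leave the measured statistics' sampling noise well
below the tolerances they are compared against.

## Known limitations

* 2D slice model: out-of-plane (cranio-caudal) setup errors are recorded
  but cannot be corrected or propagated into dose.
* The correlation function is calibrated on homogeneous water; doses
  reconstructed inside or near the lung carry uncharacterised scatter
  errors, which is why interface-adjacent points are excluded and lung
  doses should be treated as indicative only.
* `F(w)` evaluation outside the calibrated 5–29 cm thickness range and
  `f0` outside the radius table are extrapolations/clamps and warn.
* The 50%-edge criterion assumes a profile containing both an open-beam
  plateau and an attenuated region; fully blocked or fully open profiles
  raise an alignment error, and a cross-correlation fallback is not
  currently implemented (the sharp synthetic and clinical breast edges
  have not required it).
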