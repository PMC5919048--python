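# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Survival model and unit conventions

Cell survival is the Fermi sigmoid `S(E) = 100/(1 + exp((E − E_c)/A))` with
`E_c` (50 %-kill field) and `A` (steepness) given by double exponentials in
pulse count `n` or pulse length `t` (µs).  The packaged coefficient tables
(`src/irepf/data/*.csv`) carry one family per calibrated pulse length
(25/50/75/100 µs, varying `n`) and per calibrated pulse count (1/10/30/60,
varying `t`).

Two conventions matter and are locked in by tests:

* **Field scale.** All sigmoid quantities are handled in kV/cm internally.
  The coefficient amplitudes are stored in kV/cm even though dose–response
  coefficients of this kind are often quoted in V/cm: only the kV/cm reading
  makes the families consistent with the independently known lethal
  thresholds (e.g. `E_c(90) + A(90) ln 99 = 0.98713 kV/cm = 987 V/cm` for the
  100-µs family).  Interfaces facing the field solver and all reported
  thresholds use V/cm.
* **Signed rates.** The tabulated rate constants are applied verbatim as
  signed exponents, `amp · exp(rate · x)` with `rate < 0` for decay.
  Applying an extra minus sign (a common alternative notation) would produce
  divergent growth and is inconsistent with every tabulated threshold.

The calibrated covariate ranges are `n ∈ [1, 60]` and `t ∈ [25, 100]` µs.
Evaluation outside (the case studies use `n = 90`; planning sweeps may use
`t = 10` µs) is permitted but emits `ExtrapolationWarning`: the double
exponentials decay smoothly, so moderate extrapolation is well behaved, but
it is not supported by data.

The inverse `field_at_survival(s) = E_c + A ln((100 − s)/s)` is exact; with
`s = 1 %` it is the equivalent electric-field threshold (EFT).  Because
viability is strictly monotone in `|E|`, the closed form and the
area-matching definition of the EFT agree by construction; both are
implemented and cross-checked (`equivalent_eft`, `equivalent_eft_by_area`).

## Conductivity

Tissue conductivity follows the asymmetric Gompertz curve
`σ(E) = σ0 + (σmax − σ0) exp(−a e^{−bE})`, `E` in V/cm (`b` therefore
carries implicit cm/V).  For cervical tumor tissue, `σ0 = 0.2033 × 1.13 =
0.22973 S/m` (healthy-cervix value scaled by the malignancy factor) and
`σmax = σ0 × 2.8 = 0.64324 S/m` (baseline raised *by* a factor of 1.8).
The displacement and growth-rate coefficients are fixed quadratics in pulse
length: `a(t) = −5·10⁻⁶ t² + 0.004 t + 2.803`, `b(t) = −7·10⁻⁹ t² +
5·10⁻⁶ t + 0.002`.  The wording "increased by the factor of 1.8" admits two
readings (×1.8 or ×2.8); only ×2.8 is consistent with the tabulated plateau,
and both constructions are unit-tested against the tabulated values.  No
temperature dependence and no within-pulse transient are modelled.

## Field problem and discretization

The quasi-static potential solves `−∇·(σ(|E|)∇φ) = 0` on a 100 × 80 mm
rectangle with two circular electrode cross-sections (1 mm diameter, 10 mm
centre spacing, centred on the domain, axis along x; "needle electrodes seen
in 2-D").  Boundary conditions: `φ = V0` on the anode, `φ = 0` on the
cathode, zero normal current on the outer rectangle.  Pulse count and
frequency do not enter the field problem; they only parameterize survival.

Discretization is linear (P1) finite elements on a Delaunay triangulation of
a deterministic graded point cloud: concentric rings from each electrode
surface (spacing ≈ 0.35 × resolution at the surface, growing geometrically),
a background grid at the target resolution over the treatment region, and
two nested coarser boxes toward the boundary (up to 6 × resolution, capped
at 5 mm).  Interior background points carry a small fixed-seed jitter to
avoid degenerate co-circular Delaunay configurations; meshing is therefore
fully deterministic.  Triangles whose centroid falls inside an electrode
disc are removed, so the hole boundary conforms to the ring nodes placed
exactly on the disc (the inscribed-polygon area defect is < 0.003 % of the
domain).

The nonlinearity is solved by Picard (successive substitution): assemble
with the previous iterate's element conductivities (initially uniform σ0),
factorize with SuperLU, recompute element fields, and stop when the relative
L2 change of `|E|` is below 1e-6 (typically 13–16 iterations for the
protocols studied).  If the residual sequence grows, the conductivity update
is under-relaxed by 0.7.  Nodal fields are recovered by area-weighted
averaging of element gradients.  Discrete current conservation (anode vs
cathode reaction fluxes) holds to machine precision; the discrete maximum
principle `0 ≤ φ ≤ V0` is asserted on every solve.

**Validation oracle.** With constant conductivity the problem has the
closed-form bipolar (two-cylinder) solution.  That form describes free
space, while the simulated domain is a finite insulated box: the two differ
by up to ~4 % of V0 near the outer corners, a physical boundary effect that
does not shrink with mesh refinement.  The solver is therefore validated
against the closed form where it is valid — within 20 mm of the domain
centre (which covers the entire treatment region; ablation contours extend
roughly 9 mm) and at least 2 mm from the electrode surfaces — where the
measured disagreement is below 2 % of V0 on the coarsest mesh used in tests.

## Area integration and mesh convergence

Ablation area is the area with viability ≤ 1 %, the transition zone
1 % < viability < 99 %, and the binary threshold-model area `|E| ≥ EFT`.
All three are integrated by **sub-element linear interpolation** of the
level set: within each triangle the clipping variable is taken linear and
the sub-polygon area computed exactly.  For the viability contours the
clipping variable is log-viability (log of 100 − viability for the upper
bound): viability spans decades across one element near the 1 % contour
while its logarithm is nearly linear in the field, so the log transform
keeps the contour placement second-order accurate.  An element-mean
membership rule (`method="element_mean"`) is provided for comparison but is
not the default: whole-element membership quantizes the area by
O(h × contour length), which would make the 0.1 % refinement criterion
below unreachable at any practical mesh size.

Mesh convergence follows the study's criterion: refine (resolution × 1/√2
per step, default start 0.8 mm) until the monitored ablation area changes by
less than 0.1 % between consecutive meshes.  The case-study protocols
converge in 5–6 meshes (≈ 1.3–2.7 × 10⁵ elements); the resulting areas are
grid-converged to ~0.1 % and agree with the published case-study values to
0.02–0.13 %, comfortably inside the ±5 % tolerance that reflects the
unstated electrode cross-section/placement in the source geometry
description.  The reported element counts are properties of this
discretization, not reproduction targets.

## Fitting

`fit_peleg_fermi` is bounded trust-region least squares on replicate-mean
viability (replicate-level weighting available but off by default, matching
how mean ± sd dose–response data are usually fitted), with `E_c` initialized
at the linearly interpolated 50 % crossing and `A` at a quarter of the field
range.  Fewer than three field levels raises an error; data with essentially
no dose response (all ≈ 100 %, all ≈ 0 %, or a total swing under 2
percentage points) raise `UnidentifiableFitError`; data that respond but do
not cross 50 % fit with an `IllPosedFitWarning`, since the returned `E_c` is
then an extrapolation (this is the situation of the one-pulse strata, whose
`E_c` lies far above the largest applied field).

`fit_double_exponential` exploits the model's conditional linearity
(variable projection): the two rates are optimized by bounded least squares
from a deterministic 4 × 4 log-spaced multi-start grid, with the amplitudes
eliminated by linear least squares at every step.  Rates are constrained to
decay by default (`allow_growth` releases them); amplitudes are unconstrained
in sign, as one calibrated family requires a negative amplitude.  Four exact
points are interpolated to machine precision (R² = 1), and noiseless
refits of the packaged families recover the stored coefficients.

## Synthetic data

The generator reproduces the calibration study's design exactly: pulse
lengths {25, 50, 75, 100} µs × pulse counts {1, 10, 30, 60} × fields
{500, 1000, 1500, 2000} V/cm (plus 4500 V/cm for one pulse, i.e. 1800 V
across the 4-mm cuvette), five replicates — 340 treated tests, 85 per pulse
length.  Truth survival comes from the packaged families; replicate noise is
additive Gaussian on the percent scale, clamped to [0, 100], with default
sd 3 % chosen from the order of the replicate standard deviations reported
for this assay (≈ 2.8–4.1 %).  A moment-matched beta alternative is
available for bounded-support realism.  Controls are not simulated
separately; observations are already expressed relative to controls.

What passing recovery tests show: with the design's field grid and 3 %
noise, protocols whose grid brackets `E_c` recover it with ~1 % median
relative error, bias vanishes as noise → 0, and the double-exponential
refit of noiseless `E_c(n)` reaches R² ≥ 0.999.  What they do not show:
robustness to the real assay's error structure (counting error, morphology
artifacts, control drift are not modelled), behaviour outside the factorial
design, or identifiability of the one-pulse strata, which the design's
field range genuinely cannot identify.

## Degenerate inputs and tie-breaks

Survival saturates cleanly to 0 % for exponents beyond float range; area
clipping floors viability at 1e-280 before taking logs; level-set membership
uses `≥` at the threshold (measure-zero ties); `A(x) ≤ 0` in a family raises
`DegenerateSteepnessError` naming the covariate value; duplicate fields in
the double-exponential fit and sub-minimal designs raise
`InsufficientDataError` before any optimization runs.

## Known limitations

* 2-D cross-section only; no 3-D electrode geometry, no insulation sleeves.
* No Joule heating or thermal damage coupling; no within-pulse conductivity
  dynamics; per-pulse quasi-static field only.
* Calibration is in-vitro HeLa suspension data; in-vivo microenvironment
  effects are outside the model.
* The equivalent-threshold closed form is voltage-independent by
  construction; contour-matched thresholds from independent implementations
  can differ by ±1 V/cm from numerical contouring.
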