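# Methods

This note documents the models inside `mlcdose`, the defaults and where
they come from, the numerical choices, and what the synthetic fixtures
do and do not establish about real data.

## Scope and design stance

`mlcdose` is a desk-scale stand-in for a full Monte Carlo linac-head
simulation. The parts that carry the scientific content — the rounded
leaf-end geometry, the collimator transmission model, the
control-point delivery rules, the dose-comparison analytics — are
implemented exactly. The parts that need hundreds of CPU-hours and
proprietary data (electron-beam commissioning against golden beam
data, the target/flattening-filter/ion-chamber stack) are replaced by
a parameterized photon source at the target position. The phase-space
plane just upstream of the MLC is kept as the natural interface:
sources can be sampled onto it, written, read back and replayed with a
reuse factor.

## MLC geometry

The bank is 60 leaf pairs: 10 outer pairs of 10 mm width at isocenter,
40 central pairs of 5 mm, 10 outer pairs of 10 mm (full / half /
outboard types mirrored across banks), 400 mm total Y extent. Leaf
positions are stored in mm at the isocenter plane (DICOM MLCX
convention, bank A on negative X, bank A <= bank B per pair) and
projected to the physical plane by `source_to_mlc / SAD`
(509/1000 by default) — an exact similar-triangles scaling with an
exact inverse.

The tip cross-section is parameterized as: central arc (radius 80 mm,
half-angle 18 deg), tangent flats (6 mm), tangent side arcs (12 mm,
up to 45 deg), closing onto a 67 mm-high body. None of these
dimensions are published for the modeled machine; the values are
vendor-plausible defaults chosen once and exposed in the machine
profile (`src/mlcdose/data/clinac2300ix-6mv.yaml`) so a site can
substitute measured ones. The invariant `tip radius >= height/2`
guarantees the central arc can span the leaf. A pure-circular
degenerate (no flats, no side arcs) exists for oracle testing against
the chord formula. Tungsten path length behind a tip is the analytic
inverse of the boundary curve: monotone, zero at the apex, saturating
at the body height at ~7.3 mm depth for the default tip.

Interleaf leakage and tongue-and-groove are modeled as a band of
reduced tungsten path (default: 0.3 mm physical width per boundary,
path fraction 0.78). The vendor publishes no gap values; the two
numbers reproduce the expected ordering — interleaf transmission a few
times the body transmission, both well below 1% per leaf at 6 MV
effective energies — and are configuration, not constants. Leaf sides
are parallel to the beam axis at the leaf center (no side focusing);
jaw faces are likewise unfocused boxes at their nominal distances
(Y jaws at 319 mm, X jaws at 406 mm, 78 mm tungsten).

## Cross sections

No attenuation library ships in the environment, so the package
carries its own compendium built from standard analytic forms:

* incoherent scattering — exact Klein–Nishina total cross section per
  electron (free-electron approximation; binding effects are
  irrelevant above ~50 keV),
* photoelectric — per-atom `C Z^4.5 / E^3` joining a `1/E` tail above
  0.5 MeV, with `C` pinned to the photoelectric component of lead at
  0.5 MeV,
* pair production — `alpha r_e^2 Z^2 f(E)` with a universal shape
  `f(E)` anchored to water pair attenuation between threshold and
  10 MeV (screening Z-dependence neglected),
* coherent scattering — neglected (standard at megavoltage energies;
  it redirects without transferring energy).

Coefficients are tabulated on a 256-point log grid over 0.01–10 MeV
and log-log interpolated. Water comes out within 1% of standard
reference values at 1 and 2 MeV (asserted in the tests). The energy
transfer fraction per channel (Klein–Nishina mean recoil fraction,
unity for photoelectric, `(E-1.022)/E` for pair) gives the
collision-kerma coefficient used by the ray-trace mode.

## Transport

The source emits photons with uniform energy fluence across a
rectangular window at the isocenter plane (the flattened-beam
idealization) from a Gaussian focal spot (sigma 1.06 mm — the radial
sigma of the tuned electron beam whose published commissioning
parameters the source stores as metadata). The spectrum is a generic
flattening-filtered 6 MV table (mean 2.07 MeV, maximum 6 MeV),
editable data: a real machine's spectrum is implicit in its tuned
electron beam and never printed.

Collimation uses attenuation weighting (the photon survives with its
weight multiplied by the jaw+MLC transmission) — the standard variance
reduction that makes closed-field leakage computable at desk budgets.
In-phantom transport is Woodcock (delta) tracking against a global
majorant, with analog channel selection, Kahn rejection sampling for
the Compton angle, local deposition of recoil/photoelectron/pair
kinetic energy, and two annihilation quanta carried as one photon of
doubled weight (identical in expectation, slightly different variance).
Photons below the 50 keV cutoff deposit locally.

**Electron spread.** Pure collision kerma would make the closed-MLC
abutment ridge as narrow as the transmission spike itself (<1 mm),
because the physical width of such sub-centimetre dose structures is
dominated by secondary-electron transport. The engine therefore
convolves each batch's energy deposition with a Gaussian kernel of
sigma = 0.4 x CSDA range of the spectrum's mean Compton recoil energy
(1.48 mm in water for the default spectrum; the CSDA table is standard
electron range data). The rule was fixed from the range data, not
fitted to any benchmark. It is a deliberate, documented deviation from
strict local deposition; `electron_spread="off"` restores pure kerma
(used by the attenuation-slope tests), and a numeric value overrides
the sigma. The kernel is not density-scaled — acceptable in
near-water phantoms, wrong inside lungs or metal.

`raytrace_primary` mode deposits primary collision kerma exactly along
Siddon-style voxel traversals (exact boundary-to-boundary path
lengths); it is the deterministic cross-check for the analog mode (the
two agree when scatter and pair tracking are disabled).

**Randomness.** All streams are counter-based Philox generators keyed
by (seed, batch, control point, chunk), so a fixed seed reproduces the
dose grid bit for bit regardless of chunk sizes or execution order.
Per-voxel relative 1-sigma uncertainty comes from the variance over
batches (default 10).

## Delivery and absolute dose

Control-point weights: IMRT — first point zero, then cumulative
meterset increments; VMAT — half weight at the arc ends, the average
of current and previous segment weights inside, renormalized to unit
sum because the literal half/average rule sums to less than one (the
pre-normalization sum is logged and recorded). Whether the VMAT "MU
weight" means segment deltas or cumulative values is genuinely
ambiguous in the source procedure; both readings are implemented
behind `vmat_weight_mode`, defaulting to segment deltas. Histories per
control point are integers by largest remainder, summing exactly to
the budget.

The DSF is calibrated on the jaw-only 10x10 cm^2 water field at
SSD 100 cm by matching the maximum of the central-axis depth dose to
1 Gy per 100 MU (the usual clinic calibration; configurable). The
central-axis curve is averaged over a 24 mm central column and
smoothed with a 5-bin moving average before the maximum is taken —
at desk-scale budgets a raw per-voxel argmax would land on a noise
spike. Scaling: `D = raw x DSF x (2e9 / N_used) x (MU / 100)`.

## Materials

HU to material uses an ordered, contiguous 24-bin stoichiometric
table (air, a lung ramp, adipose and soft-tissue bins, a marrow-to-
cortical-bone ladder) covering [-1024, 3500] HU with per-bin linear
density ramps. The table is explicit CSV data and is normalized on
load: stoichiometric calibration is scanner-specific, so the shipped
rendition is a starting point, not a constant. ROI physical-property
overrides (e.g. a 4.5 g/cm^3 fiducial marker) are applied in file
order — later ROIs win on overlap — after an optional BODY mask that
forces everything outside the body contour to air.

## Analytics

DVHs are cumulative with 0.01 Gy default bins; Dx% interpolates
linearly on the cumulative curve (results are reported to one decimal,
so the bin is safely finer). A 1e-9 Gy guard keeps doses sitting
exactly on a bin edge (as produced by RT Dose integer quantization)
counted as >= that edge. Scalar and voxel-wise differences are percent
of prescribed dose; maps resample the coarser grid onto the finer with
trilinear interpolation. Profile FWHM takes its baseline as the median
of the outer 20% of samples because closed-field peaks sit on an
interleaf-leakage pedestal, and locates half-maximum crossings by
linear interpolation walking outward from the peak. Uncertainty
summaries average relative sigma over voxels above 50% (configurable)
of the region maximum. The LP<x mm ratio counts leaf pairs whose tip
gap is below the threshold among pairs "in the jaw-defined field": the
pair's width interval overlaps the jaw Y opening and its gap interval
lies across the jaw X opening, so pairs parked closed under a jaw do
not count.

## Fixtures: what they emulate and what they do not

The generator emits byte-reproducible DICOM-RT sets for a 50-slice
water box (HU 0 inside +-120 mm, air outside) with BODY/PTV/MARKER
structures: a closed-MLC static field (10x10 jaws, 400 MU), an
MLC-defined 10x10 inside 15x15 jaws (out-of-aperture pairs parked
closed under the X1 jaw, as clinics do), a 160-control-point
unidirectional sliding-window IMRT beam (191 MU), and a 160-control-
point 360-degree VMAT arc (312.5 MU, collimator 10 deg). The
"reference TPS dose" shipped with the dynamic fixtures is a synthetic
Gaussian blob — it exercises the comparison pipeline and is not a
planning-system calculation. Passing tests on these fixtures
establishes geometric, statistical and bookkeeping correctness; it
does not establish clinical accuracy against a commissioned TPS,
which needs real beam data.

## Problem sizes

The shipped benchmark and test budgets are chosen for single-CPU,
minutes-scale runs: 1e7 histories for the closed-MLC leakage benchmark
(statistical scatter of the FWHM about +-0.02 cm across seeds), 1e6
for DSF calibration, 1e5–4e5 for property tests. The physical
quantities they estimate are budget-invariant (that invariance is
itself tested); larger budgets only shrink error bars.

## Known limitations

* No electron/positron transport: sub-millimetre buildup detail and
  interface effects are approximated by the spread kernel.
* Photoelectric and pair parameterizations are a few-percent-accurate
  compendium, not evaluated nuclear data; high-Z transmission values
  inherit that.
* MLC scatter, leaf-side focusing, backlash and calibration offsets
  are not modeled; leaf motion within a control-point interval is not
  interpolated (delivery is a sum of static apertures).
* Only axial, identity-orientation CT geometry is supported.
* The default spectrum, leaf-tip dimensions and HU calibration are
  plausible defaults, not measurements of any specific machine.
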