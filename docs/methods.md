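# Methods

## Scope and model

`lutadose` implements three ¹⁷⁷Lu-DOTATATE dosimetry workflows — multi-SPECT/CT,
planar conjugate-view, and hybrid (planar shapes anchored by one SPECT) — on
top of a common kinetic and dosimetric core, together with a digital phantom
generator that provides analytic ground truth for every stage.

The kinetic model is strictly mono-exponential per region,
`A(t) = A₀ exp(−λ_eff t)` with `λ_eff = ln2/T_phys + ln2/T_bio`. Measured
activities are **not** decay-corrected before fitting: the fit absorbs
physical decay into `λ_eff`, and the residence time
`τ = A₀/(λ_eff A_admin)` is the 0→∞ integral of the fitted curve over real
time. Consequences worth knowing:

* the uptake phase before the first time point (4 h) is extrapolated by the
  same exponential — a deliberate simplification of a single-exponential
  clinical toolchain;
* no bi-/tri-exponential option exists, by design; the API offers no model
  selection;
* a fit that converges to a non-decaying curve raises an error carrying the
  fitted values instead of clamping, because a clamped λ would silently
  corrupt τ.

Dosimetry is MIRD-style. The default dose factor table is diagonal
(self-dose only) under local electron deposition with Δₑ = 0.1479 MeV per
decay: ¹⁷⁷Lu β/conversion electrons have sub-millimetre range, so the
absorbed fraction is ≈1 for the ≥3 g objects handled here, and photon
cross-dose is omitted by default. The self term is rescaled by `m_ref/m`
for the individual organ mass (CT-style volumetry × standardised densities:
kidney 1.05, liver/spleen/tumour 1.06, lung 0.26 g/mL). A full
`(target, source)` S-value table can be loaded from CSV to add cross-organ
terms (needed e.g. for a bladder-content → bladder-wall dose, which the
default table intentionally cannot produce); a missing cross term is a
logged zero, a missing diagonal an error. Tumours use the sphere model at
liver density; their measured residence time is divided by a sphere
recovery coefficient before dosing.

## Quantification paths

**Planar.** Geometric-mean images `√(I_a · I_p)` are formed after mirroring
the posterior view left–right into the anterior frame (camera geometry; the
convention is pinned by a test with an off-centre source). Organ ROIs are
the 2D projections of the 3D masks and may overlap. Background correction
subtracts, per organ, `wf · (band counts / band pixels) · organ pixels` with
`wf = 1 − d_organ/d_body`; the band is a 2-pixel-wide strip auto-placed
laterally next to the ROI bounding box, shifted outward until it clears
every organ ROI and the syringe ROI (falling back to the other side if
needed, re-placed per time point). Both extents are *bounding* extents
along the projection axis, the body one restricted to the organ's footprint
— one factor per organ, as when extents are read off a CT scout. For a
uniform background this correction is exact only where the organ thickness
equals its bounding extent; for thickness that varies across the footprint
(lungs, most of all) it under-subtracts — one of the mechanisms that push
planar doses high. Counts floored at zero by the subtraction are flagged,
never dropped. Camera sensitivity (cps/MBq) is measured at every time point
from the co-scanned syringe on the geometric-mean image, decay-correcting
the nominal syringe activity to scan time. No attenuation correction is
applied anywhere in the planar path — faithfully reproducing the method
under study, and the main reason deep isolated organs read low while
overlapped organs read high.

**SPECT.** VOI activity is the masked voxel sum times a calibration factor.
Simulated volumes are already quantitative, so the factor defaults to 1,
but it remains a mandatory code path (it would carry the NEMA-style
sensitivity in a real deployment).

**Hybrid.** 3D VOIs are projected onto the planar grid; pixels claimed by
more than one organ are removed from each claimant, and a measurement on
the residual region is multiplied by `V_total/V_residual` (3D voxel counts
of the VOI, a voxel counting as residual if its projected pixel survives).
This substitution is exact for uniform concentration — proven by a test at
machine precision — and biased when the removed part is hotter or colder
than the rest. A lesion enclosed by its host (tumour in liver) would be
fully occluded under the plain rule, so `(lesion, host)` pairs are exempt:
the lesion keeps its pixels and the host loses them. The per-organ planar
curve (background-corrected, substitution-scaled) is then rescaled so its
value at the reference time equals the SPECT VOI activity; the nominal
24 h frame is matched to the nearest available SPECT/planar frames within
±2 h, otherwise the workflow refuses to run and lists the available times.
Because the rescaling anchors the absolute level, only the *shape* of the
planar curve (and hence residual contamination with a different washout
rate) separates hybrid from multi-SPECT results.

**Partial-volume model.** The recovery coefficient is the fraction of a
uniform sphere's activity found inside its own boundary after isotropic
Gaussian blur, computed semi-analytically (radial erf profile integrated by
quadrature) and cross-checked against brute-force 3D convolution to <2%.
RC(volume) is monotone with RC→1, but slowly — the boundary deficit scales
like σ/R — so even litre-scale volumes sit a few percent below 1 at 10 mm
FWHM. Correction is applied to tumour VOIs only; organ VOIs are left
uncorrected, mirroring the clinical workflow being modelled.

## The phantom generator

The generator produces what the analysis consumes: per-time-point
quantitative SPECT-like volumes (MBq/voxel), anterior/posterior planar count
images, 3D organ masks, density and attenuation volumes, a calibration
record and an analytic truth record (`f`, `λ_eff`, `τ = f/λ_eff`, mass,
local-deposition dose per organ).

Emulated: mono-exponential washout on top of physical decay; parallel-beam
planar projection with exponential attenuation integrated voxel-by-voxel
along the anterior–posterior axis (half self-attenuation in the emitting
voxel, which makes the conjugate-view depth invariance exact on the grid);
isotropic Gaussian system blur (volumes for SPECT, images for planar);
Poisson counting noise on planar images and optional multiplicative
Gaussian noise on SPECT voxels (both off by default); organs disjoint in 3D
but overlapping in projection; a ⁵⁰ mL syringe in air below the feet,
decaying physically from its reference activity.

Not emulated — so passing tests say nothing about these: tomographic
reconstruction and its artefacts, scatter (none was applied in the workflow
being modelled), collimator distance-dependent resolution, dead time,
patient motion and inter-scan registration error, anatomical realism beyond
ellipsoids/boxes, and non-uniform intra-organ uptake (except tumour vs
host).

Geometry conventions: axes `(x, y, z)`, projection along `y`, anterior
detector on the −y side, posterior images stored camera-mirrored in `x`,
voxel `i` centred at `(i+0.5)·voxel_size`, masks boolean on the shared grid.

### Key parameters (defaults)

| parameter | default | rationale |
|---|---|---|
| physical half-life | 159.528 h (6.647 d) | standard ¹⁷⁷Lu decay data; config constant |
| Δₑ | 0.1479 MeV/decay | standard ¹⁷⁷Lu mean electron energy; config constant |
| μ (soft tissue, 208 keV) | 0.137 cm⁻¹ | narrow-beam water-like value at the imaging energy |
| μ (lung) | 0.04 cm⁻¹ | low-density lung |
| time points | 4, 24, 48, 72, 168 h p.i. | five-day clinical protocol |
| administered activity | 7.2 GBq | typical first-cycle administration |
| syringe | 196 MBq, 50 mL | typical calibration standard |
| planar sensitivity / duration | 10 cps/MBq, 120 s | medium-energy collimator at 208 keV, whole-body scan dwell |
| planar / SPECT PSF FWHM | 8 / 10 mm ("paper_like") | system resolution scale; 0 in the null preset |

### Bundled presets

`paper_like` (64×28×96 grid, 4 mm voxels) was *constructed* so the known
failure modes of planar dosimetry are present and act in their documented
directions: a large liver (washout T_bio = 120 h) whose projection covers
roughly half of the right kidney footprint (kidneys f = 0.02 each,
T_bio = 60 h); a uniform soft-tissue background (f = 0.40, T_bio = 70 h)
filling the body ellipsoid; lungs at low density with strongly varying
thickness; a 15 mm tumour inside the liver; ~10 cm body thickness along the
projection axis. The numbers come from a design budget, not from fitting:
with a geometric-mean attenuation factor of ≈0.5 at kidney depth, the liver
column over the overlapped pixels (concentration ≈ 2× kidney) must more
than double the kidney ROI counts for the planar overestimate to dominate,
which the chosen sizes and uptake fractions guarantee; the liver's slower
washout then lifts the late planar tail so the hybrid result stays slightly
above multi-SPECT after rescaling. The resulting kidney ordering
planar > hybrid > multi-SPECT is asserted as a deterministic regression
(noise off). `no_physics` switches off attenuation, blur, noise, background
and projection overlap; on it the three workflows agree to machine
precision, which pins down that every disagreement elsewhere is physics,
not bookkeeping.

Cohorts are generated by seeded jitter of the base phantom (semi-axes
±8% per axis, in-plane centre shifts ≤4 mm so the overlap topology is
preserved, log-normal uptake (σ=0.25) and washout (σ=0.20) jitter,
administered activity N(7.2, 0.4) GBq); geometrically invalid draws are
rejected and redrawn deterministically.

## Inter-observer simulation

Observers are modelled as independent perturbations of the reference kidney
mask (integer shifts up to the magnitude per axis plus a random one-step
dilation/erosion), applied separately to the 3D VOI (counts from SPECT) and
to the projected 2D ROI (counts from the geometric-mean image), over a
cohort of jittered studies. Kendall's W (tie-corrected, with both the
χ² = m(n−1)W approximation and a seeded within-observer permutation
p-value) quantifies concordance per route. A fixed-seed regression asserts
W(3D) ≥ W(2D) for the bundled configuration. This direction is *not* stable
across seeds in this phantom, and the reason is instructive: the liver
column that contaminates the 2D kidney ROI is nearly identical for all
observers, and concordance is blind to shared bias — contamination hurts
accuracy, not agreement. The clinical finding that 2D agreement is lower
therefore likely rests on larger free-hand delineation variability on
planar images than on CT, which an equal-magnitude perturbation model
deliberately does not encode. The package reports both W values rather than
enforcing an ordering.

## Statistics

Per-organ dose-per-activity values are compared across scenarios with the
Friedman test (three paired samples, ≥3 studies) and two-sided Wilcoxon
signed-rank tests against the multi-SPECT reference (exact null for n ≤ 25
without zeros/ties, normal approximation with continuity correction
otherwise). Degenerate inputs (all differences zero) return statistic 0 and
p = 1 instead of erroring. Median-ratio tables are reported at full
precision and rounded to one decimal for report parity. All three test
statistics are pinned against brute-force implementations (rank formula,
full 2ⁿ sign enumeration, definitional rank computation) in the suite.

## Numerical choices

* Fitting: unweighted nonlinear least squares in linear space (counting
  noise is closer to constant-CV than log-additive), log-linear
  initialisation on the positive samples, closed-form-exact for two points;
  optional 1/σ² weighting was considered and rejected for the default to
  keep the estimator simple and test-pinned.
* Gaussian blur uses truncated (zero-padded) convolution; presets keep
  sources ≥3σ from the grid edge so global activity is conserved to <0.1%.
* Attenuation line integrals use cumulative sums with half self-attenuation;
  this makes the anterior+posterior path lengths sum to the constant slab
  thickness exactly, so the conjugate-view invariance holds to machine
  precision on the grid.
* Mask shifts zero-fill at the boundary (voxel count preserved whenever the
  mask does not touch the edge); erosion to an empty mask is an error.
* Seeds: every stochastic element (Poisson sampling, SPECT noise, jitter,
  observer perturbations, permutation tests) draws from
  `numpy.random.default_rng(seed)`; identical spec + seed reproduces a
  study bit for bit.

## Problem sizes

Default test and reproduction runs use the bundled grids (≈250 k voxels),
five time points, cohorts of 6–8 jittered studies, 200 curves for the
noise-recovery property and ≤1000 permutations for Kendall's W — sizes
chosen so the full pipeline remains interactive on a laptop-class machine
while every mechanism (overlap, attenuation, blur, substitution) is well
resolved on the grid.

## Known limitations

* Local deposition ignores photon cross-dose (a few percent for ¹⁷⁷Lu
  organ self-dose; supply an S-value CSV for more).
* The sphere recovery model assumes an isolated uniform sphere; a tumour
  embedded in active liver violates this, and the hybrid/planar tumour
  values inherit host-column contamination — the tumour's hybrid residence
  time is deliberately asserted only as biased low, not exact.
* Bounding-extent thickness factors reproduce, rather than fix, the
  single-wf bias of the modelled workflow.
* Ellipsoid anatomy, pre-aligned frames and uniform uptake per organ mean
  that quantitative disagreement ratios are phantom-specific; only their
  directions and mechanisms transfer to real data.
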