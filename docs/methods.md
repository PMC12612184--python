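# Methods

This note documents the models behind each `curvchip` module, the
parameters that matter, the numerical choices, what the synthetic-data
generators do and do not emulate, and known limitations.

## Dome geometry and keratometry

An inflated well is modelled as a spherical cap over a circular aperture
of radius `a` (default 4 mm). The measured quantity is the *chord angle*
φ between the flat baseline and the rim-to-apex chord; for a spherical
cap `tan φ = h/a = tan(θ/2)`, so the cap half-angle is exactly `θ = 2φ`.
All descriptors follow in closed form: `R = a/sin θ`, `h = R(1−cos θ)`,
`V = (πh/6)(3a² + h²)`, and the keratometric power `D = K/R` with
`K = 1000·(1.3375 − 1) = 337.5 D·mm` — the standard clinical keratometer
calibration. This chord-angle reading of the measured angle is the only
standard interpretation that reproduces all three chip calibration
triplets (11.79° → 33.75 D, 15° → 42.19 D, 20.91° → 56.26 D on a 4 mm
well) simultaneously, which is why the package adopts it.

Choices: the flat well (φ = 0) is a valid degenerate geometry (R = ∞,
D = 0), not an error, because flat controls are a real condition. Angles
are restricted to φ < 45° (caps at most a hemisphere). Displayed
diopters round half-up to two decimals, the clinical printing
convention; internal values keep full precision. The cap volume is the
*per-well displaced* volume; mapping it to injected syringe volume
requires an empirical calibration (manifold dead volume, shared wells)
that is deliberately out of scope.

## Membrane inflation mechanics

The chip membrane is a clamped circular elastomer sheet (radius `a`,
thickness `t`, modulus `E`) inflated by uniform pressure `p`. The
production solver integrates the finite-rotation axisymmetric membrane
ODEs in the undeformed radial coordinate ρ: unknowns are the deformed
radius r(ρ), meridian slope angle, meridional stretch λ₁ and height;
the hoop stretch is λ₂ = r/ρ. Equilibrium along the meridian gives
`dT₁/ds = (T₂−T₁) cos θ / r` and normal to the surface the Laplace
relation `T₁κ₁ + T₂κ₂ = p`, with exact deformed-surface curvatures (no
small-slope approximation). Reported stresses are tensions divided by
the reference thickness, so `σ_m/ρ₁ + σ_h/ρ₂ = p/t` holds pointwise;
the test suite verifies this residual below `10⁻³·p/t` with curvatures
recomputed independently by finite differences of the stored slope.

**Constitutive law.** Default is an incompressible neo-Hookean membrane
(`μ = E/3`), appropriate for PDMS at moderate strain; a small-strain
Hookean membrane (plane-stress, Poisson ratio ν, default 0.49 clamped
to ≤ 0.4999) is available and is the law used for oracle comparisons.
The commercial FEA this solver stands in for does not state its
constitutive model; the qualitative stress structure (apex isotropy,
edge meridional dominance) is insensitive to this choice.

**Solution method.** Shooting on the *apex stretch*: integration starts
at ρ = 10⁻⁸a from the apex series (isotropic stretch λ₀, slope
`θ ≈ pλ₀ρ/2T₀`) and λ₀ is adjusted by monotone bracketing plus Brent's
method until the deformed rim lands on the clamp (`r(a) = a`, i.e. zero
in-plane edge displacement, which pins the edge hoop stretch to 1 and
the edge stress ratio near 1/ν). ODE tolerances are rtol 10⁻¹⁰ /
atol 10⁻¹²; root tolerances 10⁻¹³. Pressure-to-height matching
(`solve_for_apex_height`) wraps this in a second Brent iteration on p,
converging the apex height to 10⁻⁴·a; no arc-length continuation is
needed because height is monotone in pressure over the sub-hemisphere
range the chip uses. Hoop tension crossing zero (wrinkling near the
clamp at extreme loads) is flagged on the profile, not modelled with
tension-field theory.

**Independent oracle.** `hencky_profile` implements the classical
Hencky power-series solution of the pretension-free Föppl–von Kármán
membrane: the dimensionless radial tension solves
`x²s'' + 3xs' + x²/s² = 0`, expanded in even powers with the recursion
`b_n = −c_{n−1}/(4n(n+1))`, the leading coefficient fixed by the
zero-edge-displacement condition `s'(1) = (ν−1)s(1)`, and deflection
`w' = −pr/2N_r` (hence the signature `w₀ ∝ p^{1/3}` scaling, verified
in tests). At apex deflections below 0.05·a the finite-rotation solver
with the linear law agrees with this series to ~0.03 %, well inside the
1 % oracle tolerance.

**Regions.** A1/A2/A3 summaries are area-weighted means over annuli of
the well-plane radius, with default bounds a/3 and 2a/3 (the source
experiments define the regions only pictorially, so bounds are
configurable). The reported ratio is 100 × (mean σ_m)/(mean σ_h) per
annulus — the ratio of means, chosen over the mean of pointwise ratios
for robustness where hoop stress becomes small near the clamp.

**Known discrepancy.** Experimentally reported FEA summaries give a
meridional-to-hoop ratio of a few percent *at the centre region*, which
no axisymmetric membrane can produce: axisymmetry forces σ_m = σ_h
exactly at the apex. The desk solver therefore reports ~100 % at A1
rising monotonically to ~150 % at A3, reproducing the qualitative
centre-to-edge gradient (and the edge magnitude) but not the literal
centre value, whose definition in the original 3-D analysis is
unspecified. Those FEA numbers are treated as context, never as
validation targets.

## Fluorescence quantification (CTCF)

Quarter-well stitched images are tiled into fixed 1024-px squares
(partial edge tiles dropped) and each tile labelled A1/A2/A3 by the
radius of its centre from the well apex corner — centre-based labelling
is deterministic, unlike majority-area rules. Per channel, tiles are
Gaussian-smoothed (σ = 2 px) and background-subtracted with a rolling
ball (radius 15 px, the middle of the conventional 10–20 px range);
the rolling-ball envelope removes constant offsets exactly and
preserves features much narrower than the ball. Foreground masks come
from Otsu's threshold (the source protocol says only "thresholding");
CTCF is then the exact arithmetic identity
`IntDen − Area × MeanBackground`, zero on uniform tiles and invariant
to constant offsets to machine precision. Nuclei are counted by
Gaussian blur → Otsu → Euclidean distance transform → watershed seeded
at distance maxima (minimum seed separation of the order of the nuclear
radius) → connected components with a minimum-area filter. On synthetic
fields of 50–500 nuclei per 2048² px the count is within 5 % of truth;
residual error comes from genuinely merged overlaps.

## Orientation analysis

Gradients are the exact nodal derivatives of the cubic-spline
interpolant (central differences applied to spline *coefficients*),
the structure tensor is Gaussian-smoothed (σ = 2 px), and per-pixel
orientation/coherence/energy follow from its eigenstructure. Angles are
axial (period 180°), degrees in [−90°, 90°), counter-clockwise from the
image x-axis with y up; rotation equivariance within one bin is tested
at 15/30/45°. Histograms use 1° bins and are normalised by their
maximum (peak ≡ 1) so conditions with different total signal are
comparable. Default weighting counts each coherent pixel once (the
white-pixel-frequency convention); energy weighting is available.
Pixels with coherence below 0.05 are excluded as isotropic.

θ_cross is the separation of the two most prominent modes of the 3-bin
circularly smoothed histogram, each mode refined to sub-bin precision
by the axial circular mean of frequencies within ±8° of the peak; the
narrow refinement window keeps the inter-mode "bridge" contributed by
fibre-crossing pixels (which have intermediate orientations but low
coherence) from pulling the modes together. Both the raw separation and
its acute fold (180°−x when x > 90°) are reported. Alignment efficiency
is the fraction of histogram weight within ±10° of a reference axis
(1/9 for a uniform distribution). Per-cell elongation axes come from
second-moment ellipses of a label image; objects with aspect ratio
below 1.05 are flagged axis-undefined, since rasterisation alone
perturbs a circle's moments by ~1 %.

A caveat found during development: *pixel-iid* white noise is not an
isotropic orientation field — lattice effects concentrate
structure-tensor angles near ±45°. Band-limited noise (e.g. Gaussian-
filtered) behaves isotropically and is what the flatness test uses.

## Coverage kinetics

Colony area is pixel count × pixel area, optionally clipped to the well
disc so stray signal outside the 4 mm radius never contributes; areas
are measured on the projected plane (images are acquired after dome
deflation). The coverage rate is the area gained per day between two
imaging days, conventionally D3 → D6; negative rates are returned but
flagged. Fold changes divide by a reference (flat-control) rate with a
configurable positive floor (default 0.1 mm²/day) because flat-control
colonies can be nearly static. Colony masks derived from nuclei images
use Otsu → 30 µm dilation (about one cell-body radius) → largest
connected component → hole filling; the filling step matters, since the
dilated union of randomly placed nuclei at realistic density leaves
~15 % interior gaps that would bias areas low, while a real colony
footprint is simply connected.

## Expression analysis

2^−ΔΔCt follows the Livak procedure with *within-sample pairing*: ΔCt
is computed per sample against that sample's housekeeping Ct before
averaging (the alternative, ΔCt of condition means, differs only in
noise weighting; within-sample pairing is the standard). ΔΔCt
references the mean ΔCt of the flat condition, making the reference
fold exactly 1 by construction; error bars are the s.d. of per-sample
folds `2^−(ΔCt_i − mean ΔCt_ref)`. Validation rejects tables with
missing housekeeping or reference strata (listing them) and warns on
Ct values outside 10–40 cycles.

Group statistics: one-way ANOVA (cross-checked against
`scipy.stats.f_oneway`) followed by Scheffé's post-hoc test — the
pairwise statistic `(x̄_i−x̄_j)²/(MSE(1/n_i+1/n_j))` scaled by 1/(k−1)
and referred to F(k−1, N−k). Scheffé controls the family-wise error
over all contrasts, is never less conservative than the unadjusted
pairwise test, and coincides with the omnibus ANOVA for k = 2 (both
properties are tested). Significance tiers are 0.05/0.01/0.001.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic functions of (recipe, seed) — one RNG
stream per call, byte-identical reruns — and every generator emits a
truth table, enabling closed-loop recovery tests.

* **Images**: nuclei are isotropic Gaussian blobs (radius ~6 px with
  lognormal jitter, optional minimum-separation placement); fibrous
  cells are Gaussian-profile ribbons with axial orientations from
  uniform, von Mises (κ default 4; the doubled angle is von Mises
  distributed) or two-family mixture models; backgrounds are constant
  plus a random-direction linear gradient; noise is Gaussian (optional
  Poisson). The orthogonal-lamellae fixtures use κ = 100 (family spread
  ~3°), matching the tight near-perpendicular organisation such layers
  show. Not emulated: realistic cell texture, dome projection
  distortion (images are taken deflated), optical PSF, stitching seams.
  Passing recovery tests therefore demonstrates correctness of the
  *measurement pipeline*, not robustness to every real-microscopy
  artefact.
* **Growth series**: colonies are discs expanding at a constant
  programmed radial speed from a 1 mm droplet (default 0.35 mm/day,
  giving D3→D6 rates of a few mm²/day), clipped at the 4 mm rim with
  truth area π·min(r(t), a)²; nuclei fields are Poisson-placed at
  500 cells/mm², a confluent-culture density. Front roughness and
  density gradients at the colony edge are not simulated.
* **Ct tables**: target Ct = baseline − log₂(fold) + N(0, σ) with
  σ = 0.2 cycles and n = 3 replicates by default; housekeeping Ct is
  drawn per sample. Reference strata (fold 1) are added automatically.
  Note that at these settings a single experiment's recovered fold has
  a log₂ s.d. of ≈ 0.23, so individual seeds legitimately land outside
  [8, 12.5] for a true 10-fold change; the stable guarantee (and the
  tested one) is on the median across seeds.

## Problem sizes used in tests

Synthetic fields are 512–2048 px, nucleus-recovery runs use ten seeds
spanning 50–500 nuclei, coverage recovery ten seeds, fold-change
recovery twenty seeds, and the ANOVA null simulation 10⁴ replicates —
sizes at which every stochastic tolerance above is comfortably resolved
while the whole suite runs in a few minutes on one core.

## Known limitations

* The mechanics solver is axisymmetric and bending-free: no 3-D well
  cross-talk, no viscoelastic relaxation of the dome over days, no
  tension-field treatment of wrinkling (flag only).
* Region boundaries (a/3, 2a/3) are a convention, not a measurement;
  analyses that compare regions should state the bounds used.
* Nucleus counting undercounts heavily overlapped clusters (≳3 merged
  nuclei) by design of the watershed split.
* The qPCR module implements the Livak method only; amplification-
  efficiency-corrected (Pfaffl) quantification is out of scope.
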