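# curvchip

Quantitative analysis toolkit for hydraulically actuated **curvature
organ-chip** experiments on corneal stromal cells.

Corneal ectatic diseases (keratoconus, keratoglobus, cornea plana) deform
the cornea across a ~33–56 diopter range, and the mechanical consequences
of that curvature — not just its biochemical context — reshape the behaviour
of the stromal cells living in it. A curvature array chip reproduces these
geometries by inflating thin PDMS membranes over circular wells with
hydraulic pressure, then reads out cell proliferation, phenotype markers,
cytoskeletal alignment and gene expression per curvature level. `curvchip`
implements the complete quantitative machinery of such an experiment as a
tested Python library, together with synthetic-data generators that provide
programmed ground truth for every analysis.

## What it computes

| module | core quantity |
|---|---|
| `curvchip.geometry` | spherical-cap dome state from the measured chord angle φ: half-angle θ = 2φ, radius R = a/sin θ, apex height h = R(1−cos θ), cap volume, keratometric power **D = 337.5 / R** |
| `curvchip.mechanics` | meridional/hoop stress profiles σ_m(r), σ_h(r) of the clamped inflated membrane from the finite-rotation axisymmetric membrane ODEs, satisfying **σ_m/ρ₁ + σ_h/ρ₂ = p/t** pointwise, with centre/slope/edge (A1/A2/A3) area-weighted summaries and an independent Hencky (Föppl–von Kármán) series oracle |
| `curvchip.imaging` | 1024-px tiling of quarter-well images, rolling-ball background removal, and **CTCF = IntDen − Area × MeanBackground** per tile, normalised to watershed-counted nuclei |
| `curvchip.orientation` | structure-tensor orientation fields (cubic-spline gradients), max-normalised angular histograms over −90°…90°, crossing angle **θ_cross** between dominant fibre families, ±10° alignment efficiency, per-cell elongation axes |
| `curvchip.coverage` | colony area (mm²) per imaging day, coverage rate (A(D6)−A(D3))/3 in mm²/day, fold change vs the flat control |
| `curvchip.expression` | Livak **2^−ΔΔCt** fold changes (housekeeping-referenced, flat-normalised) and one-way ANOVA with Scheffé's post-hoc test |
| `curvchip.synthdata` | seeded generators for all of the above: oriented-fibre/nuclei images (von Mises and two-family orientation models), radially expanding colonies, Ct tables — each with machine-readable truth |

## Worked example

Dome geometry of the three chip curvature levels on a 4 mm well
(`python examples/dome_geometry.py`):

```
 phi (deg)   R (mm)  D (diopters)   h (mm)   V (uL)
      0.00      inf          0.00    0.000     0.00   (flat)
     11.79    9.999         33.75    0.835    21.29   (low)
     15.00    8.000         42.19    1.072    27.58   (medium)
     20.91    5.999         56.26    1.528    40.28   (high)

Healthy cornea, R = 7.8 mm: 43.27 D (~43 D)
```

Each row converts one measured chord angle to the full cap state; the
diopter column is the clinical keratometric power of that dome, spanning
the cornea-plana–to–keratoglobus range around the ~43 D healthy cornea.

Membrane stress at the medium dome (`python examples/membrane_stress.py`):

```
target apex height : 1.0718 mm (15-degree dome)
matched pressure   : 0.9787 kPa
apex stress        : 43.12 kPa (isotropic)
equilibrium residual: 4.58e-06 of p/t

 region  sigma_m (kPa)  sigma_h (kPa)  m/h ratio (%)
     A1          42.73          41.95          101.9
     A2          41.14          36.96          111.3
     A3          37.76          25.29          149.3
```

The solver finds the pressure that lifts the 530 kPa / 100 µm membrane to
the dome's apex height, then reports region-averaged principal stresses:
isotropic at the apex, with the meridional-to-hoop ratio climbing to ~150 %
at the clamped edge — the spatial stress gradient cells respond to.

The other `examples/` scripts cover fluorescence quantification, fibre
orientation, colony coverage and qPCR fold changes, each printing what it
computes and what the numbers mean.

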