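# Methods

## Model and estimator chain

The package estimates unbound blood–brain-barrier (BBB) drug transport from
paired steady-state imaging experiments.  Its core identity is that tissue
binding, summarised by the unbound volume of distribution
`V_u (mL g⁻¹)`, is a property of the tissue and therefore common to the
in vivo brain and the incubated brain slice.  Writing the in vivo regional
total concentration as `C_tot,ROI = K_p,uu,ROI · V_u,ROI · C_u,plasma` and
the slice concentration as `C_slice,ROI = V_u,ROI · C_u,buffer`, the ratio

```
K_p,uu,ROI = CF · C_tot,ROI / C_slice,ROI ,   CF = C_u,buffer / C_u,plasma
```

is free of `V_u`.  The classical combinatory mapping form
`K_p / (V_u · f_u,plasma)` is algebraically the same quantity for
consistent bulk inputs; both are implemented and cross-checked in tests.
Assumptions inherited from the experimental design: steady state in both
settings; only unbound drug in the (virtually protein-free) ISF;
negligible brain metabolism and bulk flow; concentration-independent
transport over the range of interest (this is what licenses a constant CF).

For slices measured with their adherent buffer film, the corrected form
`V_u = (A − V_i·C_buf)/(C_buf·(1 − V_i))` is provided with the
inulin-calibrated film volume `V_i = 0.094 mL g⁻¹`; the plain ratio
`C_tot,slice/C_u,buffer` is the default because sectioning for imaging
removes the film.  It is also the `V_i → 0` limit, which a property test
asserts.

## Quantitation

* **IS normalization.**  Pixelwise analyte / deuterated-IS ratio.  Both
  channels share any multiplicative spatial gain (matrix crystallisation,
  spray), so the ratio cancels it exactly; this is asserted to 1e-12 on
  synthetic data.  Pixels with IS below 1% of the median tissue IS are
  excluded from means (ratio against vanishing denominator); the 1%
  floor is configurable.
* **Tissue-equivalent calibration.**  A spotted standard of concentration
  `c` (ng mL⁻¹) and volume `v` (nL) on a dried spot of area `a` (mm²)
  corresponds to `c·v / (a · thickness · density)` ng per g tissue.  The
  default spot geometry is a 1.0-mm disc (0.785 mm²), which maps the
  25 ng mL⁻¹ × 40 nL standard to ≈103 ng g⁻¹.  Spot areas are
  configurable per spot, since dried-droplet footprints vary with matrix
  and solvent.
* **Curve fitting.**  Straight line by OLS (statsmodels), optionally
  1/x²-weighted WLS for wide dilution series; acceptance requires
  regression F-test p < 0.05, positive slope, and R² ≥ 0.99 in weighted
  mode.  LOD = 3.3·σ/S with σ the intercept standard error; LLOQ = the
  lowest nonzero standard.  A perfect fit (zero residuals) is treated as
  F-p = 0, LOD = 0.
* **Region read-out.**  The ROI *mean* normalized intensity is pushed
  through the curve (not per-pixel quantitation then averaging);
  per-pixel maps are for visualisation only.  Sub-LLOQ means are reported
  with a flag rather than censored, because downstream ratios need a
  value; the flag propagates through any ratio ("unreliable").
  Negative predictions clip to 0 and flag.
* **Whole-section values** use the tissue mask minus (dilated)
  calibration spots, and equal the pixel-count-weighted mean of regions
  plus unannotated tissue (conservation property, tested).

## K_p,uu map assembly

Animals are not paired with slices: each of the n in vivo sections (one
per animal) is divided by the mean slice concentration over the slice
replicates, region by region; the reported K_p,uu,ROI is the mean ± sd of
those n ratios, times CF.  CF defaults to 1 — studies are designed with
the buffer matched to the unbound plasma level — and is applied only when
both bulk concentrations are supplied.  Transport is classified from the
95% t-interval of the n ratios: efflux if entirely below 1, uptake if
entirely above, passive if it straddles 1; without an interval, a ±0.1
band around the point estimate is declared indeterminate.  Heat-map
scaling runs from the minimum to the maximum regional mean.

## Statistics

Shapiro–Wilk gates parametric analysis (n 3–50); one-way ANOVA with
Dunnett's many-to-one adjustment compares regional values against the
whole-section reference (scipy's multivariate-t implementation; an
independent 2000-rep Monte-Carlo null simulation in the test suite
confirms family-wise error ≈ α).  Two-tailed pooled-variance t-tests
serve two-group comparisons, with the conventions t = 0, p = 1 for
identical degenerate samples.  Outlier flagging uses robust z-scores
(median / 1.4826·MAD) with Benjamini–Hochberg control at Q = 1% — a
transparent replacement for regression-based outlier detection available
only in proprietary software, applied to scalar replicate sets only.
Default α is 0.01 for map-level significance reporting and 0.05
elsewhere.

## Synthetic data

The generator emulates: regional ground-truth concentration structure on
an 80×100-pixel (100-µm raster, 12-µm thick) elliptical coronal section
with an 11-region atlas (white matter cc/ec/aca, cortical subregions
CgCx/MCx/SCx/InCx/Pir, subcortical CPu/NAc/LS); a smooth multiplicative
gain field (random quadratic, amplitude 0.2) shared between channels;
mean-one lognormal per-pixel detection noise (CV 0.15, plus 0.05 extra IS
spray heterogeneity); optional additive background; six calibration spots
(25–1000 ng mL⁻¹, 40 nL) in a ventral region-free band; lognormal bulk
replicates (CV 0.10).  Identical seeds give bit-identical sections; seeds
are split per channel/section via `SeedSequence`.

Profile construction: per-region multipliers for slice concentration
(σ, equivalently `V_u,ROI`) and for the transport ratio (κ) are fixed
relative to each drug's whole-section values, with the printed anchors
pinned exactly (motor cortex 0.08 and piriform 0.12 for risperidone;
insular in vivo excess 1.3/1.2/1.5-fold; white matter lowest in the
corpus callosum).  The unannotated-parenchyma multipliers are then solved
against the atlas pixel weights so the pixel-weighted whole-section
truths equal 0.10/0.31/0.82 exactly.  Regional values beyond the printed
anchors are constructed, plausible rather than measured.  Steady-state
bulk defaults (unbound plasma = buffer at 240/130/150 ng mL⁻¹, f_u,plasma
0.10/0.05/0.23, mean V_u 12.5/15/20 mL g⁻¹) were chosen once so that
whole-section in vivo concentrations fall inside each drug's
quality-control range (≈103–411, 115–1147, 1144–4579 ng g⁻¹); V_u
cancels in K_p,uu, so these are free parameters of the simulation.

What the generator does **not** emulate: real mass spectra (isotope
patterns, interferences, centroiding), chemical background structure,
section-to-section morphology differences, registration error between
sections, ion suppression that differs between analyte and its deuterated
standard, or saturable (concentration-dependent) transport.  Passing
recovery tests therefore demonstrates the estimator chain is correct and
unbiased under the stated noise model — not that any real acquisition
meets that model.

## Problem sizes and numerics

Recovery runs use 6 in vivo + 3 slice sections of 80×100 pixels; at
pixel CV 0.15 a ~100–250-pixel region mean carries ≈1–1.5% noise, so the
15% recovery tolerance is dominated by between-section variation, not
grid size.  The Dunnett Monte-Carlo check uses 2000 replicates (3 groups
vs reference, n = 6).  Zero-noise end-to-end identity holds to ~1e-12
relative (tested at 1e-6).  Calibration fits are cross-checked against
closed-form normal equations at 1e-10.

## Design choices and limitations

* Internal dataset format is a directory of `.npy` arrays plus a JSON
  manifest — bit-exact round trips; imzML is read-only ingestion with
  per-channel m/z windows (1 mDa analyte, 1.5 mDa IS defaults).
* Coordinates are 0-based row-major; imzML 1-based (x, y) maps to
  (row = y−1, col = x−1).
* Atlas regions must be mutually disjoint and inside tissue; overlapping
  anatomical labels are not supported.
* The gain field is shared between channels of a section generated in one
  process; after a save/load round trip a calibration added to a control
  section rebuilds its own field from the given seed instead (the bias
  from a mismatched field averages out at the default amplitude).
* Bulk (plasma/buffer) samples enter as tabular concentrations; dried-
  spot AUC extraction and LC–MS/MS chromatography are out of scope, as
  are spectral preprocessing, 3-D reconstruction and saturable-transport
  modelling.
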