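# kpuumap

Quantitative MALDI mass-spectrometry-imaging (qMSI) neuropharmacokinetics:
regional mapping of unbound drug transport across the blood–brain barrier
(BBB) and of unbound intrabrain distribution, for neuroPK scientists who
want absolute, region-annotated answers from imaged coronal sections rather
than homogenate averages.

## The science

For a drug at steady state, the pharmacologically meaningful measure of BBB
transport is the unbound partition coefficient

```
K_p,uu,brain = C_u,brain,ISF / C_u,plasma    (<1 efflux, ≈1 passive, >1 uptake)
```

Direct ISF sampling in small brain regions is impractical.  The package
therefore combines two experiments that are each measurable by imaging:

* an **in vivo** study giving regional total brain concentrations
  `C_tot,brain,ROI` at steady state, and
* an **in vitro brain-slice** assay, where slices equilibrate in buffer so
  that `V_u,brain = C_tot,slice / C_u,buffer` (mL g⁻¹) captures all tissue
  binding.  (If the adherent buffer film is not removed, the corrected form
  `(A − V_i·C_buf)/(C_buf·(1 − V_i))` with `V_i = 0.094 mL g⁻¹` applies.)

Because tissue binding is identical in vivo and in vitro, it cancels in the
ratio, giving the imaging estimator

```
K_p,uu,ROI = CF · C_tot,brainROI / C_tot,sliceROI ,   CF = C_u,buffer / C_u,plasma
```

which agrees identically with the classical combinatory mapping approach
`K_p,uu = K_p / (V_u · f_u,plasma)` for consistent inputs.  Applied per
atlas-annotated region of a coronal section, this yields a transport map.

Concentrations come from qMSI: each analyte image is normalized pixelwise
to a uniformly sprayed deuterated internal standard (cancelling matrix and
spray heterogeneity), and calibrated against standards spotted on control
tissue, converted to tissue-equivalent units by
`(conc × volume) / (area × thickness × density)` — e.g. 40 nL of a
25 ng mL⁻¹ standard on a 1.0-mm spot of a 12-µm section (density
1.027 g cm⁻³) ≡ 103 ng g⁻¹, the method's LLOQ.  LOD is `3.3·σ/S` from the
calibration fit.

A synthetic-section generator forward-models all of this (regional ground
truths, shared multiplicative gain fields, lognormal detection noise,
calibration spots, bulk tables), so the entire chain is testable without
instrument data.  The three packaged profiles encode whole-section
K_p,uu,brain of 0.10 (risperidone), 0.31 (clozapine) and 0.82 (olanzapine),
with regional structure (risperidone motor cortex 0.08, piriform 0.12;
insular-cortex concentration excesses of 1.3/1.2/1.5-fold; reduced
white-matter exposure).

## Worked example

```
$ python examples/02_kpuu_mapping.py

=== risperidone: whole-section Kp,uu = 0.098 (ground truth 0.10) ===
  MCx    Kp,uu = 0.078 ± 0.001  [efflux]
  CgCx   Kp,uu = 0.096 ± 0.001  [efflux]
  ...
  Pir    Kp,uu = 0.120 ± 0.002  [efflux]
```

Each line is one brain region's unbound transport ratio (mean ± sd over the
6 simulated animals, each divided by the mean of 3 slice replicates) with
its classification: risperidone is a strong efflux substrate everywhere,
most strongly in the motor cortex (0.078 vs the 0.08 truth), least in the
piriform cortex (0.120 vs 0.12).

Other examples: `01_quantify_section.py` (calibration + regional
concentrations), `03_pk_calculator.py` (the bulk PK relations),
`04_method_validation.py` (linearity / LOD / accuracy / precision report).

A thin CLI wraps the same pipeline:

```
kpuumap simulate --drug risperidone --out study/ --seed 5
kpuumap quantify --data study/ --out quant/
kpuumap neuropk  --quant quant/ --out pk/
```

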