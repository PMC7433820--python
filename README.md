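# qusrad

Quantitative ultrasound (QUS) spectroscopy radiomics for predicting tumor
response to neoadjuvant chemotherapy, built around raw radiofrequency (RF)
ultrasound data rather than B-mode pixels.

## Who this is for

Researchers in ultrasound tissue characterization who want a tested, fully
synthetic-data-driven implementation of the standard pretreatment QUS
radiomics pipeline: RF spectral parameter estimation with reference-phantom
normalization, parametric-map texture analysis, cohort statistics, and
machine-learning response classification. Because clinical RF data of this
kind are rarely shareable, the package includes an RF simulator with known
scatterer ground truth, so every estimator is verifiable end to end.

## The method

RF echo frames retain the frequency-dependent scattering information that
B-mode conversion discards. Inside a contoured tumor ROI, a 2 mm × 2 mm
window slides with 92 % overlap; per window, a Hann-tapered,
line-averaged power spectrum is computed and normalized to a
tissue-mimicking reference phantom at the same depth:

&nbsp;&nbsp;&nbsp;&nbsp;S(f) = 10·log₁₀ ( S_tissue(f) / S_phantom(f) )  [dB]

Within a −6 dB analysis band, seven spectral parameters are estimated per
window (the first three from an OLS line fit S(f) ≈ SS·f + SI):

| parameter | meaning | units |
|---|---|---|
| SS, SI | spectral slope and 0-MHz intercept | dB/MHz, dB |
| MBF | midband fit, SS·f_mid + SI | dB |
| ASD | average scatterer diameter, from a Gaussian form-factor fit (exp(−0.827·k²a²) in power) | µm |
| AAC | average acoustic concentration (fit intercept) | dB/cm³ |
| SAS | scatterer spacing, c/(2·Δf) from spectral-ripple autocorrelation | mm |
| ACE | attenuation coefficient estimate, reference-phantom spectral-difference method (per ROI) | dB/cm/MHz |

Six parametric maps (no map for the scalar ACE) are each quantized to 16
gray levels and summarized by four GLCM texture features (contrast,
correlation, energy, homogeneity) averaged over 0°/45°/90°/135°, giving
24 texture + 7 spectral = **31 features per patient** (averaged over 3–5
tumor slices). Group differences (responder R vs nonresponder NR) use
Shapiro-Wilk-gated Welch-t / Mann-Whitney tests; classification uses K-NN,
SVM-RBF and Fisher's linear discriminant with sequential forward selection
(≤ 4 features) under leave-one-out cross-validation, reported as
sensitivity/specificity/accuracy/F1 and trapezoid ROC AUC.

## Worked example

```python
from pathlib import Path
from qusrad.pipeline import PipelineConfig, run_simulate, run_extract, run_analyze

cfg = PipelineConfig(seed=7, window_overlap=0.5, n_responders=4,
                     n_nonresponders=4, slices_per_patient=3,
                     extent_axial_mm=14.0, extent_lateral_mm=8.0)
out = Path("demo")
sim = run_simulate(cfg, out)                                  # RF container + manifest
df = run_extract(sim["container"], cfg, out / "features.csv") # 31 features/patient
ana = run_analyze(out / "features.csv", cfg, out / "ana")     # stats + classifiers
print(ana["report"])
```

The simulated responders carry smaller scatterers at higher acoustic
concentration than nonresponders, and the extracted features recover that
ground truth — first patients of the feature table:

```
patient_id response    MBF    SS    ASD    AAC  ACE  SAS
     NR001       NR -25.51 -3.45 133.24 -13.90 0.63 0.48
     R001        R  -17.27 -2.27  89.65  -8.13 0.76 0.55
```

(NR diameters were drawn near 130 µm vs 100 µm for R, and R concentration
6 dB higher — visible directly in ASD and AAC; ACE fluctuates around the
shared true 0.7 dB/cm/MHz.) The group comparison flags MBF, SS, SI and AAC
as significantly different, and at this deliberately large synthetic effect
size all three classifiers separate the groups perfectly:

```
classifier  Sn_pct  Sp_pct  AUC  Acc_pct  F1 features
       KNN   100.0   100.0  1.0    100.0 1.0      MBF
   SVM-RBF   100.0   100.0  1.0    100.0 1.0      MBF
       FLD   100.0   100.0  1.0    100.0 1.0      MBF
```

The same stages are available from the shell:

```bash
qusrad simulate --seed 7 --out demo
qusrad extract demo/cohort.h5 --seed 7 --out demo
qusrad analyze demo/features.csv --seed 7 --out demo/ana
qusrad report demo/ana
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at the given seed — simulating an
RF cohort, extracting the 31-feature table, and running the statistics and
three-classifier analysis — and writes the results manifest.

## Layout

- `qusrad.rf_core` — RF frame/ROI types, HDF5 container, B-mode QC
- `qusrad.synthetic_rf` — point-scatterer RF simulator, reference phantom, cohort feature generator
- `qusrad.spectral_qus` — window grid, spectra, normalization, the seven estimators, parametric maps
- `qusrad.glcm_texture` — masked GLCM and texture features
- `qusrad.cohort_stats` — patient-vector assembly, group comparisons
- `qusrad.nac_classifier` — classifiers, forward selection, LOO CV, ROC/AUC
- `qusrad.pipeline` / `qusrad.cli` — orchestration, config, provenance, CLI
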