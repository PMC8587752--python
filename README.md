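# ftirage

**ATR-FTIR aging fingerprints of striated muscle: preprocessing,
chemometrics and band-ratio biomarkers.**

Mid-infrared (4000–600 cm⁻¹) attenuated-total-reflectance FTIR spectra of
tissue read out the bulk composition of a specimen — lipids (3050–2800
cm⁻¹ C–H stretches), proteins (the 1800–1500 cm⁻¹ carbonyl/Amide
envelope) and carbohydrates/nucleic acids (the 1200–900 cm⁻¹ fingerprint
region) — in a single non-destructive measurement.  `ftirage` implements
the complete analysis workflow used to ask whether cardiac and skeletal
muscle of aging mice (6, 12, 17 and 24 months; 10 animals per group,
3 technical replicates each) carry an age-specific spectral signature:

- **Preprocessing** — region cutting, rubber-band (lower convex hull) or
  endpoint-chord baseline correction, area normalization
  (∫A dν = 1, removing sample-amount effects), and Savitzky–Golay second
  differentiation d²A/dν² to resolve overlapping bands.
- **Chemometrics, written from first principles** — mean-centered SVD
  PCA with Q-residual (SPE) outlier screening; single-response PLS by
  the kernel algorithm (NIPALS kept as an internal cross-check) with
  seeded, animal-grouped K-fold cross-validation, parsimonious factor
  selection, and score-plot discrimination of young (6 M) vs old (24 M)
  samples reported as sensitivity/specificity.
- **Nine band-intensity biomarkers** read off inverted second-derivative
  spectra (peak height of a Gaussian band ∝ amplitude/σ²):
  acyl chain length (I₂₈₅₁₊₂₉₂₂/I₂₉₅₉₊₂₈₇₁), lipid unsaturation
  (I₃₀₁₃/I₂₈₅₁₊₂₉₂₂), triglycerides (I₁₇₄₁), antiparallel and
  intermolecular β-sheet shares (I₁₆₉₃ and I₁₆₂₈ over I₁₆₉₃₊₁₆₈₂₊₁₆₂₈),
  cholesterol esters (I₁₁₆₉) and glucose (I₁₀₄₅), plus total protein
  (I_AmideI + I_AmideII) and fibril formation (I_AmideII/I_AmideI) from
  non-derived normalized spectra.
- **Inference** — ordinary two-way ANOVA (tissue × age, technical
  replicates averaged per animal) with Šidák-adjusted
  cardiac-vs-skeletal contrasts at each age.
- **A seeded synthetic cohort generator** that emulates the full study
  design (Gaussian bands with age slopes and tissue offsets, quadratic
  baseline drift, lognormal sample-amount scatter, per-animal amplitude
  effects, white noise), so every stage can be validated against exact
  ground truth.

The intended users are spectroscopists and analysts who want a tested,
scriptable version of this workflow instead of point-and-click
chemometrics software.

## Worked example

```bash
ftirage simulate --seed 17 --out cohort.csv       # 240 synthetic spectra + ground truth
ftirage analyze --in cohort.csv --out run --seed 17
cat run/summary.txt
```

which prints (numbers from this exact invocation):

```
ftirage study report (config 872855cb4bd0, seed 17)
input spectra: 240; after QC: 233 (7 outliers removed)

PLS of age on second-derivative spectra:
  cardiac   lipid        R=+0.701 (2 factors); young-vs-old factor 2: sens 69.0% / spec 76.7%
  cardiac   amide        R=+0.972 (3 factors); young-vs-old factor 3: sens 100.0% / spec 100.0%
  ...
  skeletal  amide        R=+0.955 (2 factors); young-vs-old factor 2: sens 100.0% / spec 100.0%

Tissue separation by PC1 (pooled spectra):
  amide        sens 98.3% / spec 99.1% (PC1 22.4% var)
  ...

Sidak-significant cardiac-vs-skeletal contrasts:
  lipid_unsaturation: 6M ****, 12M ****, 17M ****, 24M ****
  intermolecular_beta_fraction: 6M **, 12M ****, 17M ****, 24M ****
  ...
```

Reading this: the Amide region carries the strongest age signal in both
tissues (PLS correlation of predicted vs true age R ≈ 0.95–0.97, and
cross-validated score discrimination separates 6 M from 24 M animals
perfectly), PC1 of the pooled Amide spectra almost perfectly separates
the two tissues, and the simulated tissue contrasts (higher cardiac
lipid unsaturation, lower cardiac intermolecular β-sheet share) are
recovered as Šidák-significant at essentially every age.  `run/`
additionally contains `report.json` (every number the pipeline
computed), `panel.csv` / `panel_summary.csv` (per-animal biomarker
values and group mean ± SD), and per-region preprocessed spectra for
audit.

The same workflow is available as a library:

```python
from ftirage import CohortConfig, PipelineConfig, generate_cohort, run_pipeline

report = run_pipeline(generate_cohort(CohortConfig(seed=17)),
                      PipelineConfig(), seed=17)
report["pls"]["cardiac"]["amide"]["pearson_r"]   # 0.972
```

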