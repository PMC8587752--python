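# Methods

This note documents the models, numerical choices and limitations behind
`ftirage`, in the spirit of a software methods section.

## Data model

A `Spectrum` is an absorbance trace on a strictly increasing wavenumber
grid (cm⁻¹) with cohort metadata (tissue ∈ {cardiac, skeletal},
age ∈ {6, 12, 17, 24} months, biological and technical replicate
indices).  Wavenumbers are stored ascending internally; FTIR convention
plots them descending, which is purely presentational.  The canonical
interchange format is a long CSV (one row per spectral point) because it
carries metadata without side files; a read-only JCAMP-DX importer
covers the `(X++(Y..Y))` dialect.  Interpolation onto a shared grid is
linear and never extrapolates — at 8 cm⁻¹ instrument resolution bands
are much broader than the grid spacing, so linear interpolation is
accurate and introduces no ringing.

## Synthetic cohorts

The generator emulates the study design that motivates the package:
2 tissues × 4 ages × 10 animals × 3 technical replicates.  Each
spectrum is

    scale · ( Σ_bands amplitude(tissue, age, animal) · exp(−(ν−c)²/2σ²)
              + b₀ + b₁t + b₂t² ) + ε,

with band centers at standard muscle mid-IR assignments (olefinic 3013;
CH₃ 2959/2871; CH₂ 2922/2851; ester carbonyl 1741; Amide I sub-bands
1693 antiparallel β, 1682 β, 1662 β-turn, 1651 α-helix, 1628
intermolecular β; Amide II 1554/1540/1512; cholesterol esters 1169,
glycogen 1155, nucleic-acid phosphate 1081, glucose 1045 cm⁻¹).
Gaussian (not Voigt) line shapes are used deliberately: every
downstream operator only needs smooth peaked bands, and the Gaussian
second derivative has a closed form (−a/σ² at center) that serves as an
exact oracle in the tests.

Noiseless band amplitudes are linear in age,
`base + slope[tissue]·age + offset[tissue]`, and are the ground truth
exposed by `ground_truth()`.  Randomness, all drawn from one seed:

- `scale` — lognormal per spectrum (log-SD 0.15), the sample-amount
  scatter that area normalization must remove exactly;
- baseline — a random quadratic per spectrum in the normalized grid
  coordinate (coefficient SDs 0.02), exercising baseline correction;
- a lognormal per-animal amplitude factor (log-SD 0.05) shared by all
  bands and technical replicates of that animal — an animal-level
  tissue amount/composition effect.  Because it is shared across bands
  it cancels from band ratios; animal-to-animal ratio variation beyond
  this is not modelled;
- iid Gaussian noise, SD 0.025 = 5 % of the largest band amplitude
  (Amide I, 0.5).

Default aging effects encode the qualitative signature reported for
aging striated muscle: the antiparallel β-sheet band falls with age in
both tissues, the aggregation-prone intermolecular β-sheet band rises
with age in cardiac muscle only (and falls in skeletal), carbonyl and
glucose rise in both, and cardiac muscle carries less total protein,
less intermolecular β-sheet and more lipid unsaturation than skeletal
muscle.  Effect magnitudes are the package's design choice, sized by a
power analysis: the group-mean noise floor of the derivative-peak
fractions under the default noise was measured on zero-effect cohorts
(≈0.010–0.015 in fraction units at n = 10 animals), and per-age-step
effects were set to ≥2.5–3 of that floor so the monotone signature is
reliably recoverable under the stated design.  The resulting β-share
swings (≈0.10–0.17 over 6→24 months) correspond to a deep, but not
implausible, remodelling of protein secondary structure.

What the generator does **not** emulate: Voigt/ATR dispersion line
shapes, band-center drift between tissues, water-vapor lines, Mie
scatter, detector drift, or band-limited (correlated) noise.  Passing
tests therefore demonstrate correctness of the *procedure* under a
known, idealized data-generating process — not performance on real
instrument data.

## Preprocessing

Stages are pure per-spectrum functions applied in the fixed order
cut → baseline → area-normalize → second derivative.

- **Baseline.**  Default is the rubber band: the lower convex hull of
  (ν, A), computed by Andrew's monotone chain and evaluated piecewise
  linearly; the corrected trace is ≥ 0 and touches 0 at hull contacts.
  This is the common choice for ATR tissue spectra; an endpoint-chord
  variant is provided for cross-checking.
- **Area normalization** divides by the trapezoidal integral, making
  all indices exactly invariant to positive scaling of the raw input.
- **Second derivative.**  Savitzky–Golay with quadratic fit,
  `scipy.signal.savgol_filter(deriv=2, delta=step, mode="interp")`, so
  boundary points are handled by refitting the polynomial at the edge
  windows and region lengths are stable across stages.  Output keeps
  physical units (the raw convolution divided by step²), which makes
  the Gaussian closed-form oracle and cross-implementation comparisons
  well defined.  The *operation* default is the minimal 3-point window
  (the classic central second difference — exact for quadratics, ~1 %
  curvature error on a σ = 10 cm⁻¹ band at 2 cm⁻¹ steps).  The
  *pipeline* default is an 11-point window: differentiation amplifies
  white noise by √6/h² at window 3, and the 11-point quadratic window
  suppresses it by ~36× while still resolving Amide I sub-bands
  11 cm⁻¹ apart.  The window is a logged config key; results should
  always be reported with the window used.

## Chemometrics

- **PCA** is the SVD of the mean-centered matrix; explained variances
  are σᵢ²/(n−1); at most 7 components by convention.
- **Q-residuals (SPE)** are squared distances from the model plane.
  Outlier screening fits the PCA per tissue on raw full-range spectra
  and keeps only *strong structural* components (explained-variance
  ratio ≥ 10 %, capped at 7) before flagging
  q > median + 3.5·1.4826·MAD.  The rank restriction matters: with too
  many components any single-sample artifact becomes its own component
  and its Q-residual collapses to zero.  Q screening therefore targets
  modest off-model artifacts; gross corruption is assumed to be caught
  at acquisition (visual inspection), as is routine.
- **PLS1** uses the improved kernel algorithm (cross-product kernels
  XᵀX, Xᵀy; no X deflation), with classic NIPALS retained as an
  internal oracle — the two agree on predictions to 1e−8, and with as
  many factors as the rank PLS reproduces least squares.  Factor count
  is chosen by seeded random K-fold cross-validation (K = 10) with a
  one-sided 2 % parsimony band: the smallest count whose CV RMSE is
  within 1.02 of the minimum.  When technical replicates enter as rows,
  CV folds are grouped by animal — splitting replicates of one animal
  across train and test leaks replicate correlation and inflates CV
  skill.
- **Score discrimination** classifies by score sign against the
  score-plot origin (threshold 0, no ROC optimization).  For latent
  scores, whose sign is arbitrary, the axis is auto-oriented so the
  positive group has the larger mean.  The pipeline's young-vs-old
  readout instead uses *out-of-fold predicted age* at the selected
  factor count with a fixed orientation: training scores of a PLS
  factor separate the age groups even on pure noise (the factor is
  built from Xᵀy), while cross-validated scores stay calibrated — on
  zero-effect cohorts sensitivity + specificity averages ≈100 %.
  A fit is flagged non-informative when the CV correlation with age
  falls below 0.3.

## Band indices

Sharp-band intensities are the maximum of the −1 × second-derivative
trace within ±4 cm⁻¹ of the nominal center.  The window absorbs the few
cm⁻¹ of center drift seen between tissues while keeping the 1693 and
1682 cm⁻¹ Amide I sub-bands (11 cm⁻¹ apart) out of each other's search
windows — with a wider window, the 1693 read-out saturates on the 1682
shoulder once the antiparallel band weakens with age.  Amide I and
Amide II are raw-spectrum maxima in 1700–1600 and 1560–1480 cm⁻¹.
Total protein is implemented as the *sum* I_AmideI + I_AmideII and
fibril formation as the *ratio* I_AmideII/I_AmideI; both are emitted so
either convention can be compared.  Peak extraction always operates on
animal-mean spectra (technical replicates averaged first): averaging
before the nonlinear windowed maximum reduces both noise and the
maximum's upward extreme-value bias.  When a band has effectively
vanished, the inverted-derivative read-out near it can be slightly
negative (it sits on a neighbor's positive side-lobe); β-shares are
therefore guaranteed to lie in [0, 1] only when all three β intensities
are nonnegative, and the three shares always sum to 1 by construction.

## Statistics

Ordinary (not repeated-measures) two-way ANOVA of each index on
tissue × age, with technical replicates averaged per animal
(n = animals) to avoid pseudoreplication.  Balanced designs use the
classical cell-mean partition (also fast enough for 1000-replicate
calibration runs); unbalanced designs — normal after outlier removal —
use Type II sums of squares from an effect-coded linear model
(statsmodels `anova_lm`), chosen because no a-priori interaction
emphasis is warranted.  The two paths agree exactly on balanced data.
Pairwise cardiac-vs-skeletal contrasts at each age use the pooled
residual mean square and residual df, two-sided p, Šidák-adjusted over
the family of four ages (p′ = 1−(1−p)⁴); star codes at
0.05/0.01/0.001/0.0001.  Under a zero-effect simulation the tissue
main effect rejects at 0.05 within [0.035, 0.065] (1000 replicates).

## Pipeline and problem sizes

`run_pipeline` executes: per-tissue Q-residual screening on raw
spectra → per-region preprocessing → per-tissue-per-region PLS →
pooled-tissue PCA per region → biomarker panel → ANOVA/contrasts →
JSON + text report with the config hash and seed.  All randomness flows
from one seed; reports are byte-identical across reruns.  The default
validation cohort is the full study design (240 spectra of 1549
points); a pipeline run takes ~1 s, the complete test suite ~15 s, and
the acceptance script ~10 s, so all checks run at the study's native
size rather than a reduced one.

## Known limitations

- The generator's idealizations listed above; in particular iid white
  noise at 2 cm⁻¹ spacing is *rougher* than real interferometer noise
  at 8 cm⁻¹ resolution, making the derivative stage conservative.
- Q-residual screening cannot flag artifacts large enough to claim a
  structural component (by design; a Hotelling T² complement is out of
  scope).
- Band centers are fixed per band; center jitter between tissues is
  not simulated, although the peak-search window would absorb it.
- Amide I envelope deconvolution (curve fitting) is intentionally not
  implemented; all protein-structure read-outs are point intensities.
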