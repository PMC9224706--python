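# Methods

This note records the models, conventions and numerical choices behind
`evir`, and what the synthetic generators do and do not emulate.

## Spectral representation and preprocessing

Spectra are absorbance vs wavenumber on a strictly ascending axis in cm⁻¹;
files stored descending (the common 4000 → 650 export convention) are
reversed on ingestion, and mixed grids are aligned by linear interpolation
onto the intersection range (no smoothing is ever applied at ingestion).
Diagnostic windows are closed intervals: a grid point belongs to
`[lo, hi]` iff `lo ≤ ν ≤ hi`, which makes point counts reproducible (e.g.
1470–1700 cm⁻¹ on a 2 cm⁻¹ grid holds exactly 116 points).

**Linear baseline.** Within a window the straight line through the two
edge anchors is subtracted. By default the anchors are the single grid
points nearest `lo` and `hi`, so corrected absorbance is exactly zero
there; `anchor_k > 1` instead averages the k edge-most points per side
(anchor placed at their mean wavenumber), which trades the exact edge
zeros for robustness to noise at the anchors. Either variant is
idempotent. More elaborate baselines (rubberband, asymmetric least
squares) are deliberately out of scope: the analysis chain is defined
around the linear correction.

**Normalization.** `area` (default): trapezoid integral of |A| equals 1;
`vector`: ΣA² = 1; `max`: max A = 1. The chain uses two scopes: one
full-spectrum baseline + area normalization over the 900–3050 cm⁻¹
working range to put subjects on a common scale, and a per-band
re-application before any shape analysis so that only line shape within
the window carries information. Band *areas* are computed on
baseline-corrected but **not** per-band re-normalized spectra —
re-normalizing each band to unit area would erase the quantity being
measured. Negative corrected absorbance is integrated as-is (clipping
would bias weak bands upward); `clip_negative=True` exists for
sensitivity analysis.

**C=O window.** All quantitative work uses 1720–1760 cm⁻¹ for the
lipid-ester band; the narrower 1720–1740 cm⁻¹ display variant is
available as `CANONICAL_BANDS["ester_co_narrow"]`.

**Replicates.** The pipeline assumes one spectrum per subject;
`average_replicates` provides a pointwise-mean utility when an instrument
session yields several.

## PCA-LDA band-shape scoring

Within a band (baseline-corrected, area-normalized), subjects × wavenumber
matrices are reduced by PCA — eigendecomposition of the sample covariance
of mean-centered rows (ddof = 1), components ordered by decreasing
eigenvalue. The default of 2 retained components keeps the within-class
scatter well conditioned at cohort sizes near 39 and matches how such
scores are usually visualized in the PC1–PC2 plane; it is configurable.

The two-class Fisher discriminant in PC-score space maximizes
J(w) = (wᵀS_Bw)/(wᵀS_Ww); the fitted direction is the closed form
w ∝ S_W⁻¹(μ_case − μ_control), normalized to unit length. When S_W is
numerically rank-deficient (condition number above 1e12) a ridge
ε = 1e-8·trace(S_W)/k is added. Identical class means raise a
"no separation" error rather than returning an arbitrary direction.

Conventions: LD1 is oriented so the case group has the higher mean, and
reported scores are standardized to zero pooled mean and unit pooled
variance (ddof = 1) so scores are comparable across bands; the published
per-group LD1 summaries sit on this scale.

**LOOCV.** Classification is validated leave-one-out: for each of the n
subjects the *entire* chain — centering, PCA, LDA, and the decision
threshold at the midpoint of the two training class-mean LD1 scores (the
equal-prior Gaussian boundary) — is refit on the other n−1 subjects. A
variant that fits PCA once on all data exists behind `refit_pca=False`
purely as a leakage comparator; the test suite demonstrates the two
disagree when an outlier subject dominates the variance.

## Univariate and multivariate evaluation

**Wilcoxon rank-sum**, two-sided: exact null distribution when
n₁+n₂ ≤ 20 and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections (scipy's
`mannwhitneyu` backs both branches; the exact branch is verified against
exhaustive permutation enumeration). Raw p-values are reported;
a Benjamini–Hochberg column is available but off by default, matching the
single-cohort screening setting.

**ROC/AUC.** The empirical ROC is the step curve over all unique score
thresholds (predict case when score ≥ t); AUC is computed by the
Mann–Whitney rank identity U/(n₁n₀) with ties counted half. 95% CIs use
DeLong's placement-value variance by default (deterministic; validated
against the pROC reference implementation) or a 2000-replicate stratified
bootstrap. Markers in which controls score higher (the amide and
carbohydrate/nucleic-acid areas) can be negated up front (`orient=True`)
so reported AUCs are ≥ 0.5 with the direction recorded.

**Operating points.** Youden maximizes sens + spec − 1; closest-top-left
minimizes (1−sens)² + (1−spec)². Numeric ties (within 1e-12) are broken
toward higher sensitivity in both.

**Logistic combination.** Maximum likelihood via Newton iterations
(statsmodels), max 100 iterations, tolerance 1e-8; constant and exactly
duplicated columns are dropped before fitting. Complete or
quasi-complete separation is flagged when any coefficient exceeds 15 in
absolute value on the within-sample standardized scale, in which case the
fit is marked non-converged; a Firth (Jeffreys-prior) penalized fit is
available as a finite-estimate alternative. Stepwise selection is
bidirectional, starts from the full model, minimizes AIC, and is
deterministic given column order (ties resolved toward the smaller
model); the selection trace is recorded and strictly decreases AIC.
AIC was chosen over p-value thresholds because it is deterministic,
standard, and consistent with "most informative subset" selection.

## Synthetic cohorts

Defaults describe a two-group cohort of 19 controls and 20 cases on the
650–4000 cm⁻¹ instrument grid at 2 cm⁻¹ (1676 points).

**Spectral generator.** Each subject's spectrum is a sum of nine Gaussian
peaks (carbohydrate/nucleic 1045/1080/1160, amide II/I 1545/1652,
lipid-ester 1735, CH stretches 2852/2922/2960 cm⁻¹; widths 6–15 cm⁻¹),
plus a random linear baseline drift and additive white Gaussian noise.
Subject-level variance is carried by a per-band lognormal amplitude
factor (mean 1, CV 0.25 by default — matching the ≈25–30% coefficients of
variation of the published band areas) and a per-peak center jitter
(sd 1 cm⁻¹). Peak amplitudes are calibrated by fixed-point iteration so
the *extracted* band areas (closed window, in-window linear baseline) hit
the published control-group means exactly on a noiseless spectrum; the
analytic starting point is area = a·σ·√(2π) per peak. Case effects enter
as per-band amplitude ratios equal to the published case/control mean
ratios (0.81 amide, 0.80 carbohydrate/nucleic, 1.30 CH stretch, 1.42
ester) and small center shifts (amide I +3, CH₂ +1.5, ester +2 cm⁻¹) that
plant the band-shape differences; the carbohydrate/nucleic band gets no
shape effect, mirroring the observation that only its intensity differed.
Measurement noise defaults to 1e-6 absorbance, small relative to the
weakest (ester) band — necessary because the published area scales span
four orders of magnitude, so a noise level realistic for the amide band
would obliterate the ester band entirely. `planted_cohort_spec(effect_d,
...)` converts a desired standardized effect size d into the amplitude
ratio s via d = (s−1)/(cv·√((1+s²)/2)).

Band areas extracted from these spectra are *not* re-scaled by the
full-spectrum normalization stage: the generator already emits subjects
on a common scale, and the published area magnitudes are only consistent
with an unnormalized extraction (a unit-area-normalized spectrum cannot
contain a sub-band of area 12).

**Feature-level generator.** Independent Gaussian draws per marker per
subject with the published group means/SDs for the four areas, three LD1
scores, and the AFP / PIVKA-II analogues. Two documented gaps between
this model and real cohorts: between-marker correlations are not modelled
(so combined-marker performance is a property-based target, not a
value-matched one), and the clinical markers AFP and PIVKA-II are heavily
right-skewed in reality — a Gaussian with their printed mean/SD
understates their rank separation, which is why the generator reproduces
the published per-marker AUCs for the spectral markers (binormal identity
Φ(Δμ/√(σ₀²+σ₁²)) within ±0.03 for most) but not for AFP/PIVKA-II, nor
for LD1(2800–3000) where the two groups' printed SDs differ most.

Both generators are deterministic given a seed (numpy `default_rng`
Philox/PCG stream); the analysis pipeline itself contains no randomness
except the optional bootstrap CI.

## Problem sizes used in checks

The validation suite averages 1000 feature cohorts for the AUC
reproduction check, 500 effect-free spectral cohorts (pooling the four
independent area markers) for null calibration of the Wilcoxon/AUC chain,
150 cohorts for null LOOCV accuracy, 100 cohorts for planted-effect
recovery, and 200 replicates for stepwise selection consistency. The
acceptance script uses 800/300/200/30-replicate averages for the
corresponding quantities. These sizes put Monte-Carlo standard errors
well below the tolerances being checked.

## Known limitations

- No physical ATR modelling (penetration depth, wavelength-dependent
  effective path), no water-vapor/CO₂ lines, no Mie scattering: the
  generator is statistical, not radiometric. Passing tests demonstrate
  the *analysis chain* is correct and calibrated, not that it would reach
  the same performance on raw instrument data.
- JCAMP-DX support is the minimal `##XYDATA=(X++(Y..Y))` dialect,
  read-only; vendor binary formats are out of scope.
- Stepwise in-sample AUCs at n ≈ 39 are optimistic (the example in the
  README reaches 1.0); LOOCV and replicate-averaged figures are the
  honest performance estimates.
- Multiclass LDA and alternative classifiers (PLS-DA, SVM, forests) are
  out of scope.
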