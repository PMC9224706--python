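# evir

Chemometrics for mid-infrared liquid biopsy: spectral preprocessing, band
quantification, PCA-LDA shape scoring and ROC-based biomarker evaluation
for ATR-FTIR spectra of serum extracellular-vesicle (EV) preparations.

## The problem

EVs circulating in serum carry proteins, lipids and nucleic acids from
their cells of origin, and their bulk composition shifts in disease —
notably in hepatocellular carcinoma (HCC). A dried film of an EV-enriched
suspension measured by ATR-FTIR gives a molecular fingerprint in the mid-IR
(650–4000 cm⁻¹) whose major bands report on molecular classes:

| band (cm⁻¹)   | assignment                       |
|---------------|----------------------------------|
| 1000–1200     | carbohydrates and nucleic acids  |
| 1470–1700     | protein amide I and II           |
| 1720–1760     | lipid-ester C=O stretch          |
| 2800–3000     | lipid CH₂/CH₃ stretches          |

`evir` implements the full analysis chain that turns a labelled cohort of
such spectra (e.g. 19 controls vs 20 HCC patients) into candidate
diagnostic markers:

1. **Preprocessing** — linear baseline subtraction and area/vector/max
   normalization, at full-spectrum and per-band scope.
2. **Intensity markers** — trapezoid band areas plus the lipid-to-protein
   ratio LPR = A(2800–3000)/A(1470–1700) and lipid-to-nucleic-acid ratio
   LNR = A(2800–3000)/A(1000–1200).
3. **Shape markers** — per band, PCA (default 2 components) followed by a
   two-class Fisher discriminant; the LD1 score
   (w ∝ S_W⁻¹(μ₁−μ₀) in PC space) summarizes band shape in one scalar,
   validated by leave-one-out cross-validation with the whole chain refit
   in every fold.
4. **Evaluation** — two-sided Wilcoxon rank-sum tests (exact for small
   tie-free samples), empirical ROC curves with AUC = U/(n₁n₀) and DeLong
   or bootstrap 95% CIs, Youden and closest-top-left operating points, and
   marker combination by logistic regression with bidirectional
   stepwise-AIC selection.
5. **Synthetic cohorts** — a spectral generator (Gaussian peaks,
   per-band subject variability, baseline drift, white noise) and a
   feature-level Gaussian generator, both parameterized by the published
   cohort summary, so every stage is testable without patient data.

## Worked example

```python
import numpy as np
from evir import synthetic_data as sd
from evir.band_features import build_feature_table
from evir.biomarker_stats import (roc_auc, wilcoxon_rank_sum, stepwise_select,
                                  combined_marker_roc, youden_threshold)
from evir.chemometrics import pca_lda_scores, loocv_classify
from evir.preprocess import CANONICAL_BANDS

ds = sd.generate_cohort(sd.default_cohort_spec(seed=7))   # 19 controls, 20 cases
table = build_feature_table(ds)                            # areas + LPR + LNR
labels = ds.labels
table["ld1_1720_1760"] = pca_lda_scores(ds, CANONICAL_BANDS["ester_co"])

for m in ("area_2800_3000", "lpr", "ld1_1720_1760"):
    vals = table[m].to_numpy()
    p = wilcoxon_rank_sum(vals[labels == 0], vals[labels == 1]).p_value
    r = roc_auc(vals, labels, orient=True)
    print(f"{m}: AUC {r.auc:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f}), p={p:.4f}")

rep = loocv_classify(ds, CANONICAL_BANDS["ester_co"])
print(f"LOOCV (1720-1760): sens {rep.sensitivity:.2f} spec {rep.specificity:.2f} "
      f"acc {rep.accuracy:.2f}")

model = stepwise_select(table, labels)
roc = combined_marker_roc(model, table, labels)
op = youden_threshold(roc)
print("stepwise keeps:", model.markers)
print(f"combined AUC {roc.auc:.3f}, Youden sens {op.sensitivity:.2f} "
      f"spec {op.specificity:.2f}")
```

prints

```
area_2800_3000: AUC 0.842 (95% CI 0.701-0.984), p=0.0003
lpr: AUC 0.939 (95% CI 0.873-1.000), p=0.0000
ld1_1720_1760: AUC 0.966 (95% CI 0.910-1.000), p=0.0000
LOOCV (1720-1760): sens 0.90 spec 0.95 acc 0.92
stepwise keeps: ['lpr', 'ld1_1720_1760']
combined AUC 1.000, Youden sens 1.00 spec 1.00
```

i.e. on this synthetic cohort the CH-stretch area separates cases from
controls with AUC 0.84, the derived LPR ratio and the ester-band shape
score do better still, the cross-validated shape classifier is 92%
accurate, and stepwise selection combines the LPR with the ester-band
shape score into a panel that separates the two groups completely
in-sample (an optimistic in-sample figure at n = 39 — the LOOCV numbers
are the honest ones).

A command-line interface mirrors the stages:

```sh
evir simulate --preset spectral-default --seed 7 --out cohort.csv --manifest labels.csv
evir features --spectra cohort.csv --manifest labels.csv --out features.csv
evir pcalda   --spectra cohort.csv --manifest labels.csv --band ester_co --loocv
evir evaluate --features features.csv --stepwise --ci delong
evir run      --seed 7 --out report/
```

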