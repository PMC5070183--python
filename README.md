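# ki67prog

Automated KI67 scoring of breast-cancer tissue-microarray (TMA) cores and
10-year breast-cancer-specific survival (BCSS) modelling, as one tested,
reusable pipeline.

KI67 (stained by the MIB-1 antibody) marks proliferating cells; the KI67
score of a tumour is the percentage of malignant nuclei staining positive.
Centralised automated scoring promises reproducibility and throughput that
visual scoring by pathologists cannot match, but it has to be validated end
to end: image analysis, quality control, cut-off derivation and survival
modelling. `ki67prog` implements each stage and — because consortium imaging
and clinical data are never public — ships a first-class synthetic-data
module so the whole chain runs against known ground truth.

## What it does

1. **Image scoring** (`ki67prog.image_scoring`). H-DAB colour deconvolution
   (optical densities `OD = −log10(I/255)` inverted against a stain basis),
   Otsu-initialised nuclear segmentation with a distance-transform watershed,
   per-nucleus shape features in microns (spot width, width, roundness
   `4πA/P²`, compactness `P²/4πA`, axis ratio), shape-window malignant
   classification and DAB-based positivity. A computer-assisted-visual (CAV)
   emulator counts nuclei in 250 µm grid tiles without double counting.
2. **QC and aggregation** (`ki67prog.qc_aggregation`). Cores pass QC iff the
   malignant nuclei count is > 50 and < 15,000 and the score is not a
   saturated 100 %; a patient's KI67 is the unweighted mean over valid
   cores; patients with no valid core or missing follow-up are excluded
   under exactly one primary reason, with a conserving exclusion ledger.
3. **Cut-offs and agreement** (`ki67prog.threshold_agreement`). Prognostic
   cut-off = the upper-quartile boundary of the score distribution (high =
   strictly above); a visual cut-off is extrapolated by OLS of visual on
   automated scores and rounded up to the next multiple of 5; Cohen's kappa,
   sensitivity/specificity, and Mann–Whitney ROC AUC with Hanley–McNeil CIs.
4. **Survival models** (`ki67prog.survival_models`). Kaplan–Meier and
   log-rank with delayed entry (time at risk left-truncated at study entry),
   Cox regression with Efron ties, and a time-varying extension in which the
   KI67 hazard ratio varies as an exponential function of time,

   `HR(t) = HR₀ · T^t`,  `T = exp(θ)`,

   so `T < 1` means the effect wanes over follow-up. AIC/BIC comparison,
   Cochran-Q subgroup heterogeneity and fixed-effect inverse-variance
   meta-analysis across study groups with `I² = max(0, (Q − df)/Q)`.
5. **Missing data** (`ki67prog.missing_data`). MI+ chained-equations
   imputation — every imputation model includes the event indicator and the
   Nelson–Aalen cumulative hazard — with predictive-mean matching and
   logistic draws, and Rubin's-rules pooling (Barnard–Rubin df), 20
   imputations by default.
6. **Synthetic data** (`ki67prog.synthetic_data`). Beer–Lambert rendering of
   core images with per-nucleus ground truth, and a 10-study cohort
   simulator with left-truncated entry, per-year baseline hazards, missing
   covariates and a time-varying KI67 effect sampled exactly by inversion on
   a 0.1-year hazard grid.

## Worked example

```python
import numpy as np
from ki67prog import synthetic_data as sd, image_scoring as sc, survival_models as sm

# render a core with known truth and score it
truth = sd.random_core_truth(500, frac_positive=0.30, seed=7)
img, truth = sd.generate_core_image(truth, seed=7)
score = sc.score_core(img)
print(f"true KI67 = {truth.true_ki67_pct:.1f} %   scored KI67 = {score.ki67_pct:.1f} %")

# simulate a 10-study cohort and fit the time-varying Cox model
cfg = sd.SimCohortConfig(patients_per_study=(400,) * 10, seed=7)
coh = sd.simulate_cohort(cfg)
coh["ki67_high"] = coh["true_ki67_high"]
fit = sm.cox_tvc_fit(coh, ["ki67_high", "age", "study_id"], tvc_vars="ki67_high")
print(fit.hr_baseline("ki67_high"), fit.T("ki67_high"))
```

prints

```
true KI67 = 29.9 %   scored KI67 = 29.9 % (112/375 malignant nuclei)
HR at baseline = 2.94 (95% CI 2.36-3.66)
T = 0.914 (95% CI 0.874-0.956), P = 0.0001
```

The scored fraction recovers the rendered ground truth; the fitted baseline
hazard ratio exceeds the generator's conditional effect because the partial
adjustment (age + study) leaves the grade–KI67 confounding in place, and
`T < 1` correctly reports the waning of the KI67 effect over follow-up that
the generator builds in.

The same flow is available from the shell:

```bash
ki67prog simulate-images --n-cores 5 --out cores/
ki67prog score --manifest cores/truth_manifest.csv --out scores.csv
ki67prog run-all --seed 1 --out run/        # full synthetic pipeline
```

## Layout

```
src/ki67prog/
  synthetic_data.py      images + cohorts with ground truth
  image_scoring.py       deconvolution, segmentation, classification, CAV
  qc_aggregation.py      QC cascade, patient aggregation, descriptives
  threshold_agreement.py cut-offs, kappa/AUC/sensitivity/specificity
  survival_models.py     KM, log-rank, Cox (+ time-varying T), meta-analysis
  missing_data.py        MI+ chained equations, Rubin's rules
  pipeline.py / cli.py   orchestration and the `ki67prog` command
docs/methods.md          model and design notes
```

See `docs/methods.md` for assumptions, parameter defaults and limitations.
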