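# choromvq

Contrast-free **quantitative high-definition microvessel imaging (qHDMI)** of
choroidal tumors, end to end and fully in silico: simulate ultrafast power-Doppler
acquisitions over synthetic vascular trees, reconstruct microvessel images,
extract twelve vessel-morphology biomarkers, and run the group statistics used
to separate malignant choroidal melanomas from benign nevi.

## The problem

Early choroidal melanoma and benign choroidal nevus look alike, and biopsy is
rarely an option in the eye. Malignancy, however, remodels the tumor
microvasculature: vessels grow denser, wider, more tortuous, and branch more
irregularly. qHDMI images those microvessels without contrast agents —
ultrafast plane-wave ultrasound (effective 1000 Hz frame rate, 16.5 MHz center
frequency) produces a slow-time ensemble of complex IQ data whose
high-amplitude, slowly varying tissue clutter is rejected by singular-value
decomposition of the Casorati (pixels × frames) matrix; the power-Doppler
image of the residual blood signal is then enhanced with morphological
filtering and multiscale Hessian tubularity.

From the binarized, skeletonized vessel network the package measures, per
participant:

| biomarker | meaning |
|---|---|
| VD | vessel area / ROI area |
| NV, NB | number of vessel segments and branch points |
| D(mean/max) | vessel diameter (µm) from the distance transform |
| τ(mean/max) | tortuosity: path length / endpoint chord (≥ 1) |
| MD(mean/max) | deviation from Murray's law \|d_p³ − Σ d_i³\| / d_p³ |
| mvFD | box-counting fractal dimension of the skeleton |
| BA(mean/max) | angle between daughter vessels at a bifurcation (°) |

MD and BA are *structurally missing* whenever a lesion has no branch point
(NB = 0). The statistics module therefore pairs Wilcoxon rank-sum tests and
Mann–Whitney AUCs (with stratified bootstrap CIs) for the always-measurable
biomarkers with Firth (Jeffreys-penalized) logistic regression for the
branching ones, using the linear predictor β₀ + β₁X₁ + β₂X₁X₂ (X₁ =
measurability indicator, X₂ = biomarker value) and a 2-df likelihood-ratio
test — finite estimates even under complete separation, and the value term
vanishes exactly where the value is unobservable.

Because the underlying patient data are restricted, the package ships a
first-class synthetic-data module: Murray-law-exact branching trees with
controllable tortuosity, rasterized lumen/velocity maps, a tissue + blood +
noise IQ ensemble model, and moment-matched biomarker cohorts with the
observed missingness pattern.

## Worked example

Simulate a 21-malignant / 15-benign cohort at the study group moments and run
the full analysis:

```python
from choromvq.synth import generate_cohort, study_cohort_spec
from choromvq.stats import run_group_analysis

cohort = generate_cohort(study_cohort_spec(seed=7))
ga = run_group_analysis(cohort, thickness_cutoff_mm=2.5, seed=7, bootstrap_B=2000)
print(ga.comparison[["biomarker", "malignant_mean", "benign_mean",
                     "p_value", "auc", "auc_ci_low", "auc_ci_high"]].round(3))
```

```
biomarker  malignant_mean  benign_mean  p_value   auc  auc_ci_low  auc_ci_high
       VD           0.188        0.126    0.047 0.698       0.514        0.854
    Dmean         404.386      317.122    0.116 0.657       0.463        0.829
     Dmax         903.532      730.372    0.132 0.651       0.454        0.822
       NV          18.476        6.600    0.000 0.876       0.743        0.971
     mvFD           1.302        1.139    0.000 0.876       0.743        0.978
       NB           8.762        3.333    0.000 0.857       0.725        0.956
 tau_mean           1.182        1.060    0.078 0.676       0.495        0.841
  tau_max           1.645        1.120    0.001 0.838       0.683        0.956
```

Vessel count, fractal dimension, branch count and maximum tortuosity separate
the groups sharply (p < 0.002, AUC ≈ 0.84–0.88); mean diameter and mean
tortuosity do not — the same significance split the clinical study reports.
The branching biomarkers, analyzed with the missingness-aware Firth LRT
(8 of 15 benign lesions measurable), all reach p ≈ 0.001–0.002:

```
biomarker  n_measurable_malignant  n_measurable_benign  p_value
   MDmean                      21                    8   0.0008
    MDmax                      21                    8   0.0017
   BAmean                      21                    8   0.0021
    BAmax                      21                    8   0.0015
```

A full physics-level in-silico study (phantom trees → IQ ensembles → image
reconstruction → morphometry → statistics) is one call or one command:

```bash
choromvq run-all --seed 7 --out results/
```

which writes `cohort.csv`, the comparison tables, the correlation matrix and a
reproducibility manifest. The individual stages are available as `choromvq
simulate | reconstruct | quantify | cohort-stats`.

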