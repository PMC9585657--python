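# gliotex

MRI texture radiomics for classifying high-grade glioma into IDH-mutant and
IDH-wild-type subgroups — and a synthetic textured-phantom cohort generator
that makes the whole pipeline testable without access to clinical imaging.

Non-invasive prediction of IDH mutation status from routine MR imaging is a
standard radiomics problem: tumors of the two molecular subgroups differ in
image *texture* — the spatial arrangement and histogram shape of intensities
inside the tumor — even when they look similar to the eye. `gliotex`
implements the classic slice-based pipeline end to end:

* multi-scale **Laplacian-of-Gaussian (LoG)** band-pass filtering at spatial
  scale filter (SSF) levels 0 (unfiltered) and 2–6 mm;
* an 82-feature vector per MR sequence per tumor slice: 36 first-order
  statistics (6 statistics x 6 SSF levels), 20 **gray-level co-occurrence
  matrix (GLCM)** features at pixel distance 1 and 20 at distance 4, and 6
  shape features — 164 features when the T1C and T2 sequences are combined;
* two dataset modes: *single-slice multiple sampling* (every tumor-bearing
  slice is a sample) and *multislice* (per-patient averaging);
* **LASSO** logistic feature selection (penalty at minimum cross-validated
  binomial deviance, non-zero coefficients retained);
* polynomial-kernel **SVM** classification (linear / quadratic / cubic)
  evaluated by stratified, patient-grouped 10-fold cross-validation or
  hold-out splits, reporting rank-based AUC per class, and a confusion
  matrix with sensitivity, specificity, PPV, NPV, FNR and accuracy.

Inputs are NIfTI volumes with co-registered binary ROI masks listed in a
CSV manifest, or phantom cohorts generated in memory. The phantom generator
produces two-channel tumor volumes whose classes differ in Gaussian-random-
field correlation length, amplitude and histogram skew, with the study-like
83:17 class imbalance — see `docs/methods.md` for the model and every
documented convention.

## Worked example

```python
import gliotex as g
from gliotex.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(
    phantom={},               # default cohort: 100 patients, 17 positive
    modes=("multislice",),
    sequences=("T1C+T2",),
    kernels=("quadratic",),
    validation=("cv10",),
    seed=7,
    outdir="out",
))
cell = report["cells"]["multislice|T1C+T2|quadratic|cv10"]
print(round(cell["auc_positive"], 2), round(100 * cell["accuracy"], 1))
```

prints

```
1.0 99.0
```

— on the default phantom conditions (wild-type texture correlation length
1 mm vs mutant 4 mm at equal amplitude) the texture classes are cleanly
separable: the pooled 10-fold cross-validated AUC of the combined-sequence
quadratic-kernel model is 1.0 and 99 of the 100 patients fall on the
correct side of the decision-score sign threshold. `out/` then contains the slice-level and per-patient feature
tables (164 feature columns), the grid report CSV, pooled out-of-fold ROC
points per grid cell, and a JSON report recording the seed, the retained
feature names per fold and every convention the run used. Shrinking the
between-class texture difference moves the AUC continuously toward the 0.5
of identical classes.

The same run from the shell:

```bash
radiomics-pipeline run --config cfg.json --seed 7
phantom --n 100 --n-pos 17 --seed 7 --outdir cohort/   # write NIfTI + manifest
radiomics-pipeline extract --manifest cohort/manifest.csv --outdir feats/
```

Confusion-matrix arithmetic is exposed directly, e.g. for a pooled CV
result with 80 true positives, 9 true negatives, 8 false positives and 3
false negatives out of 100 cases:

```python
from gliotex import ConfusionMatrix, confusion_metrics
m = confusion_metrics(ConfusionMatrix(tp=80, tn=9, fp=8, fn=3))
# accuracy 0.89, sensitivity 0.964, specificity 0.529, PPV 0.909, NPV 0.75
```

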