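# oralcyto

Automated risk stratification for brush-biopsy oral cytology.

Screening for oral squamous cell carcinoma (OSCC) and its precursor lesions
in low-resource settings relies on brush cytology digitised by portable
slide-scanning microscopes. `oralcyto` implements the complete automated
analysis chain such a platform needs, for engineers and methodologists
building or evaluating cytology screening pipelines:

1. **Segmentation** — estimate the circular field of view (FOV) from three
   boundary pixels and their circumcircle, trim to it, threshold the green
   channel (best stain contrast) by Otsu's method, clear background, split
   touching cells by distance-transform watershed, and emit per-cell ROIs.
2. **Quality control** — a four-check cascade (size/aspect, shadow-artifact
   red/green ratio, hematoxylin-stained area, nucleus presence) removes
   clumps, shadows, unstained debris and anucleate fragments.
3. **Atypia scoring** — every surviving cell receives a score *s* ∈ [0, 1]
   (cells with *s* > 0.5 are atypical).  The scorer is pluggable; a trainable
   morphometric reference scorer (regularised logistic model on nucleus/cell
   geometry and stain features) is included.
4. **Patient aggregation** — three features per patient:

   - percentage of atypical cells: 100 · |{s : s > 0.5}| / n
   - mean score of atypical cells: Σ s_atypical / n_atypical
   - mean score of all cells: Σ s / n

5. **Cascade risk stratification** — Test 1, a linear SVM on
   (mean score of all cells, % atypical cells) trained on a random half of
   the cohort, flags OSCC risk; Test-1 negatives go to Test 2, an ROC-derived
   Youden cutoff on the mean atypical-cell score, separating HGD risk from
   LGD/benign.
6. **Diagnostic statistics** — sensitivity/specificity/accuracy/PPV/NPV with
   half-up percent rounding, Cohen's kappa, McNemar's paired test, empirical
   ROC/AUC, Kruskal–Wallis group tests, and the seven-feature manual cytology
   score (positive when > 3).

No clinical images ship with the package: a seeded synthetic generator
renders circular-FOV fields with stained cells (atypia drawn as enlarged,
irregular nuclei), clumps and shadow artifacts together with pixel-exact
ground truth, and simulates per-cell score cohorts matching published
class-conditional distributions — so the full chain is testable offline.

## Worked example

```python
import oralcyto as oc
from oralcyto.cascade import CascadeRiskModel

records = oc.generate_score_cohort(oc.CohortSpec(seed=7))   # 60 patients
res = CascadeRiskModel.from_records(records).fit(seed=7)
print(res.summary())
```

```
Cascade risk stratification results
===================================
cohort: 60 patients (train 30, test 30), seed 7

Test 1: linear SVM on (mean_all, pct_atypical), positive = OSCC risk
  weights: mean_all +1.8819, pct_atypical +0.2113, intercept -0.1450
Test 2: cutoff on mean atypical score (Youden J = 0.000)
  cutoff: 0.6857  [non-informative]

held-out diagnostics (percent):
  test1    sens   93.3 spec   93.3 acc   93.3 (n=30)
  test2    sens   90.9 spec    0.0 acc   71.4 (n=14)
  overall  sens   96.3 spec    0.0 acc   86.7 (n=30)

held-out strata: OSCC_risk=15, HGD_risk=14, LGD_or_benign=1
```

Test 1 recovers the OSCC patients at 93% held-out sensitivity.  Test 2 is
flagged *non-informative* here because under the published class parameters
the LGD mean atypical score (0.78) sits **above** the OSCC mean (0.71), so no
"≥ cutoff → positive" rule can separate them — see `docs/methods.md` for why
the generator defaults reproduce this ambiguity and how to override it
(`ClassScoreSpec.mean_atypical`).  `res.compare_learners()` fits the five
reference learners (SVM, random forest, logistic regression, LDA, KNN) on the
same split; `res.plot_features()` / `res.plot_roc()` draw the decision plane
and the Test-2 ROC.

The image path is exercised the same way:

```python
img, truth = oc.generate_field_image(oc.SceneSpec(seed=1))  # 2592x1936 field
rois = oc.segment_field(img)          # 25 ROIs, centroids within 5 px of truth
passing, tally = oc.apply_qc(rois)    # {'passed': 25}
```

A `click` CLI wraps the stages (`oralcyto simulate | segment | qc | score |
aggregate | stratify | evaluate | run`); `oralcyto run --config cfg.yaml
--out rundir` chains everything and writes deterministic per-stage artifacts
plus a run manifest.

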