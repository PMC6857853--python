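# Methods

This note documents the models, the synthetic data the package is validated
on, the numeric choices behind every stage, and the known limitations.

## The stratification model

Patients carry per-cell atypia scores in [0, 1]; a cell is *atypical* when
its score is strictly above 0.5.  Three aggregates summarise a patient:
percentage of atypical cells, mean score of all cells, mean score of
atypical cells (undefined when the patient has no atypical cell).  The
cascade stratifies sequentially:

* **Test 1** — linear-kernel SVM (C = 1, features standardised to zero
  mean/unit variance on the training half) on (mean score of all cells,
  % atypical).  Positive → OSCC risk.  The split is a seeded 50/50 holdout,
  stratified by class (stratification is switchable; a class with fewer than
  two members cannot be stratified and raises).
* **Test 2** — applied only to Test-1 negatives.  A scalar cutoff on the
  mean atypical-cell score, derived by empirical ROC of OSCC vs LGD
  training patients and the Youden criterion J = sens + spec − 1; candidate
  cutoffs are midpoints between adjacent sorted unique training scores, ties
  break toward the lower cutoff (higher sensitivity).  Decision rule:
  score ≥ cutoff → HGD risk, else LGD/benign.  A patient with no atypical
  cells is an automatic negative — zero atypical cells is incompatible with
  high-grade disease under this scoring scheme.

Assumptions worth stating: the two Test-1 features are treated as exchangeable
across sites and scanners (no batch correction); Test 2 assumes the atypical
score of HGD patients is *larger* than that of LGD patients.  The published
class statistics the generator defaults to actually invert that ordering
(LGD 0.78 vs HGD 0.76 vs OSCC 0.71), so on default simulations the Test-2
derivation reports Youden J ≈ 0 and flags the cutoff *non-informative* rather
than pretending to discriminate.  `ClassScoreSpec.mean_atypical` is
per-class overridable, and the recovery tests use separated means
(LGD 0.62 / HGD 0.76, ≥ 2 SD apart) to show the cutoff lands between the two
class means when a direction exists.

## Segmentation

Stages and their numeric choices (all in `SegmentationParams`, all
overridable):

* **FOV estimation.**  Rays are cast inward from the border along six
  equally spaced directions; the first pixel whose luminance exceeds the
  Otsu split of the whole frame is an edge candidate, and the triple of
  candidates maximising the minimum pairwise angular separation is kept.
  The circle through them is the closed-form circumcircle.  A frame whose
  1–99 percentile luminance spread is below `min_contrast` (30 grey levels)
  has no FOV: dark frames raise, uniformly bright frames return border
  points flagged low-confidence.
* **Trim.**  Pixels outside the circle are zeroed and the frame is cropped
  to the circle's bounding box; ROI coordinates are mapped back through the
  recorded crop origin.  Thresholding afterwards ignores a 4 px guard band
  inside the fitted circle (`fov_margin_px`) — the vignette transition is
  blurred, and without the guard a one-pixel dark ring at the boundary
  thresholds into a spurious giant component.
* **Cell-mass threshold.**  Otsu on the green channel over in-FOV pixels,
  inverted (stained = dark = foreground).  Green is used because the
  stain gives it the strongest cell/background contrast.  A flat FOV
  (spread < 30) yields an empty mask with a warning instead of thresholding
  noise.
* **Background clearing.**  Components below `speck_area_px` (25 px²) are
  debris and removed; the image is blacked out outside the surviving mass.
* **Clump splitting.**  Watershed on the negated Euclidean distance
  transform.  Markers are distance-transform maxima at least 10 µm apart
  (`marker_min_separation_um` × pixel scale); every input component is
  guaranteed one marker, so the component count never decreases and no
  foreground is created outside the input.  Watershed lines (1 px) separate
  the pieces.
* **ROI extraction.**  One ROI per connected component with area (px² and
  µm² at 1.9 px/µm), aspect ratio from fitted-ellipse axes, per-channel
  means over the mask, half-open bounding box, ids ordered by (y0, x0).

Coordinates are 0-based, x = column, y = row.

## Quality control

Four checks in fixed order with short-circuiting: size/aspect → shadow →
hematoxylin area → nucleus.  None of the thresholds is dictated by the
hardware; defaults come from typical squamous-cell dimensions (20–70 µm
diameter) at 1.9 px/µm and are all in `QCCriteria`:

| check | rule | default |
|---|---|---|
| size_aspect | area ∈ [min, max] µm², aspect ≤ max (inclusive) | 150–4000 µm², 3.0 |
| shadow | mean_red / mean_green ≤ threshold (inclusive; 0 green fails) | 1.15 |
| hematoxylin_area | fraction of mask pixels that are blue-dominant (B ≥ R) and below the ROI's Otsu luminance split ≥ min (inclusive) | 0.05 |
| nucleus | Otsu on the ROI's red channel; ≥ 1 particle ≥ min area; largest stored as nucleus mask | 10 µm² |

The hematoxylin and nucleus checks treat an ROI whose relevant channel has
less than 30 grey levels of 1–99 percentile spread as flat (unstained or
anucleate) — without this, Otsu on pure sensor noise splits the noise in
half and fabricates structure.

## Atypia scoring

The scoring contract (one monotone score per cell in [0, 1]) is what
deployed CNN scorers provide; their training settings (Inception V3 transfer
learning, 4000 epochs, learning rate 0.01, 90/10 train/validation split) are
carried as provenance metadata only.  The included reference scorer is a
StandardScaler + L2 logistic regression (C = 1) on seven features: cell area
(µm²), aspect ratio, nucleus/cell area ratio, nucleus boundary irregularity
(perimeter²/4π·area), and the three channel means.  It is deterministic
given its seed, reports stratified 90/10 validation accuracy, and
serialises to JSON (coefficients + standardisation constants).  Scores are
binned for reporting at [0, 0.3), [0.3, 0.5), [0.5, 0.7), [0.7, 0.9),
[0.9, 1] — half-open, closed on the left, top bin closed.

## Diagnostic statistics

* Percent metrics keep the raw fraction and round half-up (integer and
  one-decimal styles both exposed).  Note 13/15 rounds to 87, not 88.
  Zero-denominator metrics are `None`, never silently 0.
* Cohen's kappa is unweighted, accepts rating vectors or a k×k table, and
  flags pe = 1 (both raters constant and equal) as undefined.
* McNemar uses the exact two-sided binomial for b + c < 25 and the
  continuity-corrected chi-square above; the method is tagged in the result.
  The 25 switch point is a package convention.
* ROC: decision rule score ≥ t → positive; thresholds are midpoints between
  adjacent unique scores plus sentinels; AUC by trapezoid (ties in FPR
  ordered by TPR); Youden ties break toward the lower cutoff.  J = 0 flags a
  non-informative cutoff.
* Group comparisons: Kruskal–Wallis across classes, Lilliefors-corrected
  Kolmogorov–Smirnov normality per group (≥ 4 values required), Pearson r
  between feature vectors.
* Manual cytology score: sum of seven binary features (multi-nucleation,
  mitotic figures, prominent nucleoli, altered N:C ratio, hyperchromatic
  nucleus, irregular nuclear membrane, abnormal cell shape); positive when
  strictly above 3.  Classic sheets list six features; abnormal shape ranks
  among the most informative, so seven is the default and `n_features=6` is
  supported.

## Synthetic data

**Field images** (`SceneSpec`): 2592 × 1936 px, 8-bit RGB, 1.9 px/µm, bright
circular FOV (default radius 900 px, centred) on a near-black vignette.
Cells are hard-rasterised ellipses (diameter 25–55 µm, aspect 1–1.6) with a
darker nucleus, anti-aliased by a σ = 0.8 px Gaussian blur, plus σ = 5/255
Gaussian pixel noise.  The palette mimics a Papanicolaou-type stain:
blue-violet cytoplasm (green darkest of the three channels, red/green ≈ 1.08),
dark hematoxylin nucleus (blue-dominant, red ≈ 70), and red-dominant shadow
artifacts (red/green ≈ 1.45) so they fail the shadow check.  A single
brightness draw is shared across channels per object — stain density varies
far more than hue — keeping channel ratios stable.  Atypia is rendered
morphologically: nucleus area fraction 0.35–0.60 (vs 0.08–0.18 normal) with
a 25% sinusoidal boundary perturbation, which is exactly the signal the
morphometric scorer uses.  Clumps are pairs of touching ellipses; default
scenes contain 25 non-overlapping single cells and no clumps or artifacts
(tests opt in via `n_clumps` / `n_shadow_artifacts`).  Per-field seeds
derive from the master seed as `SeedSequence((seed, index))`; identical
specs are byte-identical.

**Score cohorts** (`CohortSpec`): per-cell scores follow a two-component
truncated-normal mixture — normal cells on (0, 0.5], atypical on (0.5, 1] —
with the truncation *mean-corrected* (the location parameter is solved so
the truncated mean equals the requested component mean; naive truncation
biases component means toward the interval centre).  Patient heterogeneity:
atypical fraction, atypical-component mean and normal-component mean are
drawn per patient around the class values; cell count is Poisson (mean 200).
Default class parameters follow the published statistics: atypical fractions
0.39/0.16/0.14 (OSCC/HGD/LGD, SDs 0.11/0.09/0.09), mean atypical scores
0.71 ± 0.02 / 0.76 ± 0.03 / 0.78 ± 0.03, mean all-cell scores 0.40/0.21/0.17.
The benign class has no published distribution of its own and defaults to
the LGD parameters.  Cohort composition (60 = 30 OSCC + 24 HGD + 4 LGD +
2 BNG) is reconstructed from the published holdout denominators.

One published inconsistency forces a design choice: the per-class SDs above
imply a pooled correlation of only ≈ 0.90 between mean all-cell score and
atypical fraction, while the published correlation is r = 0.992.  Both
cannot hold.  The generator pins the fraction-*independent* share of
Var(mean_all) to (1 − r²)·sd_all² with r = 0.992
(`ClassScoreSpec.feature_correlation`), which reproduces the strong
correlation; the realised SD of the OSCC all-cell mean then comes out ≈ 0.06
rather than the printed 0.08.

**What the generator does not emulate** — and hence what passing tests do
not show about clinical data: focus gradients and chromatic aberration,
stain batch variation and slide-to-slide colour shifts, keratinised
anucleate squames in large sheets, mucus/bacterial background, true optical
overlap of cells in thick smears, and any correlation between cell
morphology and its position in the field.  Segmentation recall of ~100% on
synthetic fields is an upper bound that real smears will not reach; the
value of the synthetic path is exactness of the ground truth, not realism of
the difficulty.

## Problem sizes

Test-suite and acceptance-script simulations are sized for single-CPU desk
runs: 50 acquisition-scale fields for the segmentation oracle, 8 small
fields for QC discrimination, 20 seeded 60-patient cohort replicates for
cascade recovery, 200 replicates for the Kruskal–Wallis type-I-error check,
and 1000 random circles for circumcircle recovery.

## Known limitations

* The reference scorer is morphometric; it scores the synthetic generator's
  notion of atypia and is a stand-in for image-level CNN scorers, not a
  clinical classifier.
* Overlapping-cell resolution beyond marker-based watershed is out of scope;
  heavily clumped smears will under-segment.
* The cascade supports exactly the published two-feature Test 1 and scalar
  Test 2; no probability calibration, nonlinear kernels, or cross-validation
  beyond the single holdout.
* Wilson intervals on proportions are available as an extra but no other
  confidence intervals are provided.
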