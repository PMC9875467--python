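# Methods

## The screening problem

Pediatric anemia (hemoglobin < 11 g/dL in children 6–59 months) reduces
blood redness and therefore skin redness wherever perfusion is visible.
In the CIELAB opponent color space, redness is the positive direction of
the a\* channel, so the mean a\* of a palm region is a one-number pallor
summary. Literature thresholds, expressed in the offset encoding
a\*+128, place anemic palms below 142 and non-anemic palms above 160.
`palmscreen` builds the full pipeline around that signal and benchmarks
five classifiers on top of it.

## Synthetic cohort: what the generator emulates

There is no retrievable public palm dataset for this task, so the
package generates one with the structure the analysis assumes:

- **Labels.** Anemic iff Hb < 11 g/dL, exactly. Anemic Hb is drawn
  Uniform(6.0, 10.9), non-anemic Uniform(11.0, 14.0) — the cutoff is
  authoritative; the within-class distribution is a stipulation, since
  only the cutoff and a handful of example values are constrained.
  Default class sizes 304/223 (58% prevalence); sex is drawn from
  class-conditional marginals (59.2% / 52.9% female) and age uniformly
  on 0–5 years.
- **Images.** A parametric hand silhouette (palm ellipse + five finger
  lobes) on a dark gray background (gray level 40), at 96×96 by default.
  The silhouette is deterministic given the raster size, which makes the
  exact foreground recoverable as ground truth in tests.
- **Color model.** Each subject has a target a\* equal to its class mean
  (134 anemic / 168 non-anemic, offset encoding), optionally plus a
  between-subject random effect of sd `subject_sd` (default 0). Each
  foreground pixel then draws a\* ~ Normal(target, `a_sd` = 4)
  independently, at fixed L\* = 65 and b\* = 152 (offset; skin is
  yellowish), is converted CIELAB → sRGB, and receives additive Gaussian
  channel noise of sd `noise_sd` = 3. Out-of-gamut pixels (a rare tail of
  the non-anemic a\* draw) are clamped to the sRGB boundary and logged.

Because pixel-level a\* draws are i.i.d., the per-image mean a\*
concentrates on the subject target: with `subject_sd` = 0 the two class
distributions of image means are separated by over 30 sigma of the mean,
and every well-segmented image classifies correctly by the thresholds
alone. This is a *stated world*, not an empirical fit — no real-cohort
a\* distributions were available to calibrate against. Consequently a
green classifier test establishes that the pipeline preserves and
recovers the planted signal, not that real palms are this separable.
What the generator does **not** emulate: illumination/camera variation,
pose, skin-tone diversity, specular highlights, anatomical shape
variation.

`subject_sd` exists precisely because the default world is too clean to
study protocol artifacts: the leakage experiment (below) uses class
means 147/155 with `subject_sd` = 6, giving heavily overlapping
image-level distributions.

## Segmentation

Grayscale is BT.601 luma, rounded. The triangle threshold is Zack's
geometric construction: take the chord from the histogram peak (first
argmax on ties) to the farthest occupied bin, score every level between
them by perpendicular point-to-line distance, return the argmax, with
ties broken toward the peak-distal side. Degenerate histograms (single
occupied bin, flat geometry) return the distal candidate with a logged
warning. The implementation is checked against an exhaustive
256-candidate scan on random bimodal histograms, and against
scikit-image's independent implementation (±2 bins) on a smooth case.

Foreground polarity is auto-detected: the threshold class holding the
majority of the 1-pixel image border is background. (Stated readings of
"compare the mean gray of the two classes" are circular — the
above-threshold class is brighter by construction — so border occupancy
is the package's choice; it also survives inverted lighting.) After
thresholding, only the largest connected component is kept and its holes
are filled (`cleanup=True`, toggleable) so background speckle cannot
contaminate mean color features. Empty foregrounds raise a
`SegmentationError` naming the image.

## Features

sRGB ↔ CIELAB uses the standard sRGB companding / D65 white point
(scikit-image). The pixel filter retains pixels with
minL < L\* < maxL **and** every channel of (R, G, B) strictly inside
(min, max); defaults minL=10, maxL=96, min=10, max=245 — the bound
values are stipulated (only the rule's form is externally fixed) and
config-overridable. The literal reading "R = G = B" would retain only
gray pixels and destroy the a\* signal, so "each channel in the band" is
used. G is taken after filtering, over the same retained set as a\* and
b\*, for internal consistency. Features are means over retained mask
pixels only — perturbing any background pixel leaves the vector
bit-identical (tested). `mean_a`/`mean_b` are stored in the offset
encoding so they compare directly against 142/160; helpers convert to
native signed units. `std_a` is computed and reported but the default
classifier feature set is (mean a\*, mean b\*, mean G), which is the
configuration reported to discriminate best; `include_std_a` adds it.

## Augmentation

Five views per original: rot90, rot270, flip_h, flip_v, translate — and
the untransformed original is *not* a pool member, which is the only
arithmetic consistent with 527 originals → 2635 pool entries (5×).
Rotations and flips are exact pixel permutations, so any
multiset-statistic (all mean features) is bit-identical on full-frame
ROIs. Translation defaults to a single combined (dx, dy) = (8, 8) shift;
`wrap` edge policy is an exact permutation (channel sums conserved
exactly), the default `reflect` changes mean a\* by < 1 CIELAB unit at
default offsets (tested empirically). Cropping and noise injection are
excluded by design because they alter mean intensity; the module rejects
unknown transform names. Offsets are bounded by min(H, W)/4. The
transform list is applied deterministically; probabilistic
per-transform application is deliberately not implemented.

## Classifiers

Classical models are scikit-learn estimators behind this module's
surface; hyperparameter defaults are fixed in `ClassifierConfig`:

- Naive Bayes: Gaussian class-conditionals, log-domain Bayes rule.
- k-NN: k = 100 (clamped to n_train with a warning when larger),
  Euclidean, uniform weights; score = anemic fraction among neighbors.
- Decision tree: CART/Gini, `min_samples_leaf=10`, `min_samples_split=5`;
  leaf score = anemic fraction. A statement that "100 trees" were
  configured contradicts a single-tree method description; a single tree
  is the implementation and `tree_bagged=True` provides a 100-tree
  bagged variant for fidelity experiments.
- SVM: sigmoid kernel tanh(γ⟨x,y⟩ + r) with γ = 1/(n_features·var)
  ("scale") and r = 0 (neither is externally specified), C = 100,
  tolerance 0.1, iteration cap 100. Hitting the cap sets
  `converged=False` rather than raising. Score is a logistic link on the
  decision value (no Platt refit, keeping scores deterministic).
  `svm_epsilon=1.10` is stored for configuration fidelity only — it is a
  regression parameter with no role in classification.
- CNN: the environment has no deep-learning framework, so the miniature
  convnet is implemented in numpy (`palmscreen._cnn`): two blocks of
  3×3 conv + ReLU + 2×2 max-pool (8 then 16 channels), dense softmax
  head, He init, mini-batch SGD (batch 32, lr 0.01 — stipulated), L2
  1e-4, 10 epochs, fully seeded. It is a stated-hyperparameter
  miniature, not a large pretrained architecture; pooled-gradient ties
  share gradient equally.

Features are z-scored inside the SVM and k-NN models by default
(`standardize=False` for strict raw-scale behavior): CIELAB and 8-bit
channel scales otherwise distort Euclidean distances. Scores tie-break
toward anemic at 0.5 — the conservative direction for a screen.

## Evaluation

Split sizes: n_val = ⌊0.1·N⌋ and n_test = ⌊0.2·N⌋ with the remainder to
train, which reproduces 1845/263/527 at N = 2635 and 7/1/2 at N = 10.
(Half-to-even rounding of 263.5 would give 264 and break the published
accounting — the floor rule is the deliberate choice.) Pooled mode
permutes pool entries; grouped mode assigns whole subjects atomically in
shuffled order until each partition's target is met, logging any drift.

"10% validation by tenfold cross-validation" is ambiguous; the
implementation runs stratified tenfold CV on the *training* partition
(the conventional placement) and scores the 10% validation partition
once as an extra holdout — both numbers appear in the report. CV folds
whose training part is single-class are skipped with a warning. CNN CV
is off by default (`cv_include_cnn`) because it multiplies training cost
tenfold without changing any conclusion on the synthetic world.

Metrics follow the standard confusion-matrix definitions with anemic
positive; zero-denominator ratios are reported as 0 and flagged. Three
AUC-family numbers are reported side by side: the verbatim formulation
(TPR−TNR)/2 — which is 0 for a perfect classifier and is reproduced
only so reports remain comparable with the source's tables — balanced
accuracy (TPR+TNR)/2, and a trapezoidal ROC AUC over a score threshold
sweep. Cumulative gains sort by descending score with tied scores
sharing one rank block; lift = gains(f)/f with the undefined f = 0 point
omitted. Reports print percentages to two decimals.

## Leakage demonstration

`compare_split_modes` trains the same model on the same features under
pooled and grouped splitting across seeded replicate cohorts
(default: 40+30 subjects, class means 147/155, `subject_sd` = 6, k-NN,
20 seeds). Because rotations and flips leave features bit-identical,
pooled splitting places exact copies of test items in the training set;
on overlapping cohorts this inflates test accuracy relative to the
grouped protocol (measured gap ≈ 4–6 accuracy points). This is the
mechanistic account of why augment-before-split evaluation protocols
report near-perfect figures: they partly measure subject memorization.

## Numerical choices and limitations

- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); identical configs produce byte-identical
  cohorts and identical reports.
- The triangle threshold uses exact float equality for tie detection;
  distances are computed once and shared by the argmax.
- The CIELAB round trip is exact to ≤1 channel step on a strided 8-bit
  grid; out-of-gamut conversions clamp to the boundary (detected by a
  round-trip discrepancy > 0.5 CIELAB units).
- Accuracies near 100% on the default synthetic world say nothing about
  clinical performance: the world is constructed to be separable, and
  published near-perfect accuracies on pooled protocols are consistent
  with the leakage mechanism above. Realistic difficulty requires
  `subject_sd` > 0 and, ultimately, real photographs.
- k-NN distance ties follow the underlying estimator's stable neighbor
  ordering; the documented "training-set order" rule is only observable
  on constructed ties.
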