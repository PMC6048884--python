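# Methods

## Problem and scope

Automated lung-nodule detection pipelines screen CT volumes for candidate
lesions with permissive intensity/morphology thresholds, then reclassify the
candidates to suppress false positives. This package implements the second
stage for the hardest size class — micro-nodules, solid lesions under 3 mm
in diameter — as a binary image-patch classification problem: label 1 for a
micro-nodule, label 0 for a non-nodule. It covers the full desk-scale
pipeline: parsing reader annotations in the LIDC XML dialect, extracting
intensity patches from DICOM CT series around each mark, training three
small convolutional networks of increasing depth, and evaluating them under
fivefold cross-validation.

## Annotation model

Each scan carries up to four reading sessions (one per expert). Lesions are
typed by how they are marked:

* a **nodule** (3–30 mm) has per-slice closed edge maps (≥ 3 vertices);
* a **micro-nodule** (< 3 mm) has no contour — only its 3-D
  centre-of-mass point, encoded as a nodule element whose region of
  interest reduces to a single distinct point;
* a **non-nodule** is a single point inside a `locus` element, a keyword
  unique to that category.

Marks from different readers are kept separate and each yields its own
patch: agreement between readers is deliberately not collapsed, so a lesion
seen by all four readers contributes four patches. Contoured nodules are
parsed (so the parser is total over real annotation files) but produce no
patches. Duplicate scans are detected by a fingerprint — the SHA-256 of the
sorted set of slice SOP UIDs referenced in the document (falling back to the
series UID when no SOP UIDs appear) — and collapsed to the scan with the
lexicographically smallest `patient_id + fingerprint` key. The archive is
known to contain duplicated patients but not which ones, so fingerprint
equality is the only scan-intrinsic criterion available.

## Patch extraction

Slices are stacked in ascending z and converted to Hounsfield units (HU)
with each slice's rescale slope/intercept. Annotation x/y are treated as
0-based column/row indices (recorded in the manifest so a ±1 audit remains
possible). A mark's slice resolves by exact SOP-UID match first, then by
nearest z within half the median slice spacing; marks that resolve nowhere
are skipped with a logged reason rather than silently dropped.

Patches use the half-open centring convention `[c − s/2, c + s/2)` for the
even sizes 16, 32 and 64, so the mark sits at pixel index `s/2`. Windows
that extend past the image are padded with −1000 HU (air) instead of being
shifted, which would de-centre the lesion. This convention makes the three
sizes nest exactly: the central 32×32 of a 64×64 patch is bit-identical to
the 32×32 patch. Intensities are clipped to the standard lung window
[−1000, 400] HU and mapped affinely to [0, 1]; the source protocol does not
state a preprocessing step, so the window is a package choice and is kept
out of the raw HU store.

## Architectures

Three models, differing only in convolutional depth, all ending in a 2-unit
dense layer with softmax:

| model | layers |
|---|---|
| M1 | conv(32 @ 3×3) → maxpool → dense(256) → dropout(0.5) → dense(2) → softmax |
| M2 | conv(64 @ 7×7) → ReLU → maxpool → conv(128 @ 2×2) → dropout(0.5) → dense(256) → dense(2) → softmax |
| M3 | [conv(3×3, same) → maxpool] ×3 (32/64/128 filters) → conv(256 @ 3×3, same) → dropout(0.5) → dense(256) → dense(2) → softmax |

Fixed by the published design: M2's kernel complement (64 @ 7×7 then
128 @ 2×2 — the small second-layer kernels target sub-3 mm detail), M1's
3×3 kernel, and the 1/2/4 depth progression. Package choices, surfaced as
keyword arguments: M1's 32 filters, M3's 32/64/128/256 filter ramp, the
256-unit dense width, dropout 0.5, 2×2/stride-2 pooling. M1 and M2 use
valid (no) padding — which reproduces the expected M2 shape chain
26×26×64 → 13×13×64 → 12×12×128 at 32×32 input — while M3's convolutions
are 'same'-padded: with three stacked poolings, valid 3×3 convolutions
would collapse 16×16 and 32×32 inputs to non-positive sizes before the
fourth convolution, so valid padding cannot realise M3 at all three sizes.

Shape propagation follows `floor((n + 2p − k)/s) + 1`; parameter counts are
`kh·kw·c_in·c_out + c_out` per convolution and `n_in·n_out + n_out` per
dense layer. Specifications serialise to JSON so experiments are
declarative.

## Training

The layers (im2col convolution, ReLU, 2×2 max pooling with
first-maximum gradient routing, dense, inverted dropout) and the optimizer
are implemented in numpy; analytic gradients are verified against central
finite differences in the test suite. Training uses SGD with classic
momentum (`v ← μv − η∇; w ← w + v`), two-class cross-entropy on the softmax
output, learning rate 1e-4, momentum 0.9 and batch size 128 by default,
with 50 epochs as the baseline schedule and 120 as the published optimum
for M2 at archive scale. Weights are initialised variance-scaling uniform
(limit √(6/fan_in)) from a seed, so a run is reproducible bit-for-bit.

Inputs are zero-centred and scaled to unit variance with statistics
computed on the training fold (stored on the estimator and re-applied at
prediction). Lung-window CT intensities occupy a narrow band of [0, 1]
(background ≈ 0.1, s.d. ≈ 0.04), and without centring the gradient
magnitudes are too small for the fixed 1e-4 learning rate to converge in
tens of epochs; zero-centring the input is also the default behaviour of
the image input layer in the mainstream deep-learning toolboxes this design
originates from.

## Cross-validation

Fivefold, stratified, at patch level. Within each class the shuffled
indices are dealt to folds cyclically with the deal pointer carried across
classes, so overall fold sizes differ by at most one **and** per-class
counts per fold differ by at most one (a stock stratified splitter only
bounds the overall spread by the number of classes). Each fold is scored by
the model trained on the other four; every patch is scored exactly once.
Fold metrics are aggregated by unweighted mean, with pooled
out-of-fold-prediction metrics also emitted for audit. Patch-level
splitting means patches of one patient can occur on both sides of a split;
results on real archives should be read with that leakage caveat.

## Metrics

With class 1 (micro-nodule) positive: accuracy (TP+TN)/n, sensitivity
TP/(TP+FN), and the average F-score Σ_C P_C·R_C/(P_C+R_C) over both
classes — algebraically the two-class macro-F1, since each class term is
half that class's F1. A zero denominator contributes 0 (not NaN) so the
score is total over degenerate folds. The decision threshold is 0.5 with
ties predicted positive. The ROC sweeps distinct score thresholds
descending with tied scores advanced jointly; the trapezoidal area then
equals the Mann–Whitney probability that a random positive outscores a
random negative, with half-credit for ties (verified to 1e-12 in the
tests). Metrics are fractions in [0, 1]; result tables print ×100 in the
columns F-score (%), Accuracy (%), Sensitivity (%), AUC (%).

## Synthetic data

Two generators stand in for the archive at desk scale.

**Scan fixtures** write a miniature DICOM series (default 64×64×3,
0.7 mm pixels, 2.5 mm slices) plus a matching annotation XML from a planted
mark list, painting a bright blob at every planted coordinate so extraction
can be checked against image content. Micro-nodules are emitted as
single-edge-point nodule elements, non-nodules as `locus` elements, and
contoured nodules as 4-point square edge maps — covering every parser
branch.

**Patch datasets** emulate the classification task directly. The background
is smoothed white noise (σ = 1.5 px Gaussian kernel, renormalised to
60 HU s.d.) around −850 HU, i.e. aerated parenchyma with correlated
texture. Label-1 patches add a Gaussian blob at the patch centre with
diameter drawn uniformly in [1, 2.9] mm at 0.7 mm/px — honouring the < 3 mm
micro-nodule definition; label-0 patches add, with probability ½, a
vessel-like ridge whose axis is offset 4+ px from the centre, else plain
texture. Contrast is `separation × noise_sd` HU for both lesion types, so
at separation 0 the class-conditional distributions are identical by
construction (a built-in permutation null), while separation 5 gives a
centre-pixel effect size above 3 pooled standard deviations. This generator
verifies the pipeline and the learnability of a planted signal; it does not
model scanner physics, dose, reconstruction kernels or real parenchymal
texture, so passing tests demonstrate mechanism correctness, not clinical
performance.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full protocol at desk
scale: metric oracles over 1000 random confusion tables and 1000 random
score sets; the architecture audit over all nine model × size cells; the
extraction round trip on a 64×64×3 fixture with 5 planted micro-nodules,
3 non-nodules and 1 contoured nodule; and M2 learnability on 2000
synthetic 32×32 patches (1600 train / 400 held out, 20 epochs) plus the
same training on label-shuffled data as a negative control. Archive-scale
numbers (nine cells × fivefold × 50–120 epochs on 34,494 patches) are
reachable through the same CLI but are not part of the shipped checks.

## Known limitations

* Patch-level (not patient-level) CV splits; see above.
* The numpy engine is single-threaded apart from BLAS; it is sized for the
  three small models, not a general training framework.
* Micro-nodule identification relies on the single-point-ROI rule; an
  archive variant that contours sub-3 mm lesions would be classified as
  nodules and excluded.
* The synthetic generator's vessel/texture negatives are a two-mode
  caricature of the non-nodule class.
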