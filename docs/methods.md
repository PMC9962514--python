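# Methods

`papkit` implements a fully automatic pipeline from cardiac-CT substructure
label maps to pulmonary-artery-pressure (PAP) estimates, together with the
agreement-statistics battery used to evaluate such pipelines, and a
synthetic thoracic phantom cohort that makes every stage testable without
patient data. This note documents the models, the conventions chosen where
the problem was genuinely open, and what the synthetic experiments do and
do not demonstrate.

## The phantom cohort

Real CTPA/RHC cohorts for pulmonary hypertension (PH) are small and
private, so the package ships a generator that emulates the *statistical
structure* such a cohort presents to the pipeline, not its anatomy.

**Hemodynamics.** A latent severity `s ~ N(0,1)` drives everything.
mPAP = `mu + sigma·s`, clipped at the PH diagnostic floor of 25 mmHg;
`(mu, sigma)` are calibrated in closed form (clipped-normal moment
equations, solved at run time) so the *clipped* distribution has mean
42.82 and SD 12.74 mmHg — the cohort moments the generator targets.
Clipping rather than resampling-truncation is used because resampling at
−1.4 SD would shift the mean by ≈ 2 mmHg, off the target moments.
sPAP is regressed on mPAP with slope 1.4 (marginal moments 68.35 ± 20.62
mmHg; the residual SD follows from the variance identity), floored at
mPAP + 2. dPAP derives from the classical identity mPAP = (sPAP + 2·dPAP)/3
plus N(0, 3) noise, clipped into (0, mPAP]; the ordering dPAP ≤ mPAP ≤ sPAP
holds for every record by construction. The reported dPAP SD of 42.53 mmHg
is not emulated: it would admit negative diastolic pressures. CO is
lognormal around 4.64 L/min (log-SD 0.35); TPR = 80·mPAP/CO and
PVR = 80·(mPAP − PCWP)/CO (Wood-to-metric factor 80; total pulmonary
resistance does not subtract wedge pressure, pulmonary vascular resistance
does). At n = 55 an optional missingness pattern reproduces the per-column
n bookkeeping of a real table (1/55 of sPAP/dPAP cells, 7/55 of TPR).

**Geometry.** Each patient's heart is four axis-aligned ellipsoid chambers
(LV, RV, LA, RA) and four vertical cylinders (MPA, AA, LPA, RPA), placed on
a fixed non-overlapping layout in a 144 mm cube. Each structure's linear
scale is `1 + slope·tanh(z/1.2)` times multiplicative noise
`1 + N(0, 0.06)`, where `z` is standardized severity. The tanh link is
smooth, bounded and strictly monotone, so the zero-noise configuration has
|Spearman r| = 1 by construction. Slopes carry the sign structure the
pipeline must recover: the left atrium and ventricle shrink with severity
(LA −0.15, LV −0.10), the right heart and pulmonary trunk grow (RA/RV
+0.12, MPA +0.08, LPA/RPA +0.05, AA 0). The noise level 0.06 makes the
feature–pressure correlations strong but imperfect; it is a single
documented constant, chosen once as a realistic measurement-plus-biology
scatter for geometric CT features.

**Rendering.** Blood pools are painted at 350 HU (contrast-enhanced), the
LV myocardium shell at 100 HU, lungs at −800 HU, soft tissue at 40 HU and
air at −1024 HU; Gaussian blur (default 1.5 mm, emulating reconstruction
point spread) and Gaussian noise (default 10 HU) are applied to the image
only — label maps stay exact. The default grid is 96³ voxels at 1.5 mm
(a 144 mm cube); the full 512 × 512 × 480 standardized shape is supported
but not the default, so the experiments run at desk scale.

What the phantoms do **not** emulate: real anatomy and its partial-volume
ambiguities, cardiac motion, contrast-bolus timing variation, inter-patient
field-of-view differences, and segmentation failure modes such as a
structure vanishing on one slice or splitting in two. Passing the phantom
suites therefore demonstrates that the pipeline's machinery is correct and
recovers planted signal under CT-like degradation — not that a clinically
trained segmenter/regressor would reach the same accuracy on patients.

## Mask refinement

A candidate segmentation mask is scored by a small classifier. The mask is
dilated and eroded by a 1-voxel ball to form a (contracted, current,
expanded) variant triple; each variant's interior boundary (mask voxels
with a six-connected non-mask neighbour; the grid border does not count as
outside) is traversed slice by slice, ordered by angle about the in-slice
boundary centroid, and the image intensities along it are flattened into a
vector zero-padded/truncated to L = 2048. The three vectors are tokens to
a single-head self-attention layer (learned 2048→64 embedding, 64-dim
queries/keys/values) followed by a 64→32→1 MLP with sigmoid output. The
idea: a well-placed contour samples the partial-volume edge (intermediate
HU), an undersized one samples pure blood pool, an oversized one samples
the surroundings, and attention across the three variants gives the
classifier the local intensity context to tell these apart.

Training is full-batch gradient descent with momentum (lr 0.1, momentum
0.9, 400 iterations) on binary cross-entropy, with hand-written
backpropagation in numpy; given a seed the run is bit-for-bit reproducible.
At initialization the output layer is near zero, so the loss starts at
≈ ln 2 on balanced classes.

Refinement: if the candidate scores ≥ 0.5 it is returned unchanged.
Otherwise each iteration scores the 1-voxel-dilated and 1-voxel-eroded
candidates (each with its *own* variant triple) and keeps the better one,
stopping at acceptance or after 10 iterations, returning the best-scoring
mask seen (the input included) — so refinement can never return a mask the
classifier likes less than the input. The step size, the iteration bound,
L, the embedding sizes and the 0.5 threshold are package conventions; none
is externally fixed.

## Morphometry

All 16 features are measured on transversal (axial) slices of the label
map, the plane of the first two axes. Per slice, a structure's area is the
pixel count of its largest 4-connected in-plane component times the pixel
area (largest component only, for robustness to speckle labels); the
structure's area feature is the maximum over slices. Diameters are taken
on the maximal-area slice: vessels (MPA, RPA, LPA, AA) as the
equivalent-circle diameter `2·sqrt(area/pi)`; chambers (LV, RV, LA, RA) as
the maximum Feret (caliper) diameter. Feret is computed over pixel
*corners* (the caliper of the union of pixel squares), which is exact for
axis-aligned rectangles and keeps voxelized primitives within one voxel of
their analytic diameters; the convex hull of pixel centers prunes the
candidate set exactly (Minkowski-sum argument). Ratios (MPAd/AAd,
RPAd/LPAd, RVd/LVd, RAd/LAd) are plain quotients, missing if either
component is missing; an absent structure yields a missing value, never an
exception. Cardiac phase ("in diastole") is ignored: phantoms are static
and multi-phase data are out of scope.

These conventions are reproducible and oracle-testable but are not the
radiologist's caliper placement; systematic offsets against manual
measurements are expected, which is exactly what the paired-t /
Bland–Altman battery is for.

## Feature selection

Against a chosen target (default mPAP): (1) Spearman screen, keeping
features with two-sided p < 0.05 (average ranks for ties; p by the
t-approximation `r·sqrt((n−2)/(1−r²))`, exact permutation for n ≤ 9;
pairwise-complete rows); (2) collinearity prune — feature pairs visited in
descending |pairwise Pearson r|, and when |r| > 0.9 with both alive, the
one with the smaller |Pearson r to target| is dropped (lexicographic
tie-break), leaving all pairwise |r| ≤ 0.9; (3) standardization to mean 0 /
variance 1 (population divisor n; a zero-variance column is an error
naming the column); (4) PCA keeping the smallest m with cumulative
explained variance ≥ 0.95, with a deterministic sign convention (each
loading's largest-magnitude entry positive) and listwise-complete rows.
The 0.05 level, the greedy order with its tie-break, and the 0.95 variance
fraction are package conventions; the 0.9 prune threshold is the method's
stated rule. Inside cross-validation the whole chain is re-fit on each
training fold; if no feature passes the screen (a permuted-label null run,
for instance), the single best-|r| feature is kept so the downstream fit
stays defined — the report records the fallback.

## PAP models and cross-validation

Regression (mPAP, sPAP, dPAP, TPR) and severity classification (mPAP ≥ 40
mmHg, sPAP ≥ 55 mmHg; the boundary value counts as severe) use
gradient-boosted trees of maximum depth 3. The remaining hyperparameters —
200 trees, learning rate 0.1, subsample 1.0, single-threaded for
determinism — are package defaults recorded in every report. Repeated
k-fold cross-validation (defaults 10 folds; the study protocol's 20
repeats) stratifies classification folds by class and regression folds by
target-quartile bin; repeat r uses seed `seed + r`; a repeat whose dealing
would leave a training fold single-class is re-dealt and logged;
`folds = n` degenerates to leave-one-out. Reports store every out-of-fold
prediction and fold assignment, so all aggregate metrics (MSE over all
out-of-fold predictions; consistency ICC between truth and the per-case
mean prediction; AUC/sensitivity/specificity at score 0.5 on the per-case
mean score) are recomputable from the stored arrays.

## Agreement statistics

Paired t with 95% CI of the mean difference; reconstruction of t from a
printed mean and CI (`SE = width / (2·t₀.₉₇₅,ₙ₋₁)`); Bland–Altman bias and
95% limits of agreement `bias ± 1.96·SD(d)`, also reconstructible from a
printed mean and t (`SD = |mean/t|·sqrt(n)`); Spearman/Pearson correlation
with the p-value conventions above; the two-way mixed *consistency* ICC
(subjects random, measures fixed) from the interaction-free two-way ANOVA —
ICC_single = (MSR−MSE)/(MSR+(k−1)·MSE), ICC_average = 1 − 1/F with
F = MSR/MSE on (n−1, (n−1)(k−1)) df, CIs by the standard F-bound
construction — and the Spearman–Brown step-up relating the two; ROC AUC as
the tie-aware rank-sum statistic with a normal-approximation p against
AUC = 0.5; Dice overlap with the two-empty-masks case defined as 1.0
(agreement on absence). Cross-structure Dice summaries use the population
SD (divisor N), the convention that reproduces published ±SD values of
this kind. The ICC implementation is cross-checked in the test suite
against an independent reference (pingouin's ICC(C,1)/ICC(C,k)).

## Problem sizes and numerical choices

The shipped experiments use a 96³/1.5 mm grid; the refinement experiment
trains on 10 phantoms (10 positives, 20 negatives at ±2-voxel degradation)
and refines 20 fresh degraded cases; the recovery experiment uses a
200-patient measured cohort with 5 CV repeats and a 2-run permutation
null. These sizes were chosen as the smallest at which the planted effects
are comfortably detectable; all are parameters, and the full 20-repeat
protocol is the library default. Degenerate inputs are handled explicitly:
contraction of a thin mask falls back to the current mask (flagged),
refinement prunes emptied candidates, constant columns and single-class
inputs raise, absent structures propagate as missing.

## Known limitations

The segmentation backbone itself (a 3D U-Net ensemble in the original
setting) is out of scope: the package assumes candidate masks exist and
refines them; phantom ground truth stands in for the backbone. The phantom
geometry is axis-aligned and static, so measured diameters are exactly the
planted parameters up to voxelization — real-data effects such as oblique
vessel courses are not represented. Published real-data performance
numbers (Dice on patient CTPA, clinical ICC/MSE/AUC) are not reproducible
here because the underlying cohort is private; the package instead
reconstructs every published quantity that is a deterministic function of
other published numbers, and demonstrates the pipeline's properties on the
phantom cohort.
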