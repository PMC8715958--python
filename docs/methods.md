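# Methods

## Problem

Memory impairment in the Alzheimer's disease spectrum is screened with
neuropsychological tests, three of which measure memory directly: the MMSE
delayed word recall (0–3 words), the ADAS-Cog delayed word recall (0–30
words; in this package's convention the number of words recalled, higher =
better), and the CDR memory box (0, 0.5, 1, 2, 3). The three tests often
disagree within a subject. A concordance rule declares a sample

- **certain impaired** iff MMSE-Recall ≤ 1 *and* ADAS-Cog-Recall < 12 *and*
  CDR-Memory ≥ 1;
- **certain healthy** iff MMSE-Recall > 1 *and* ADAS-Cog-Recall > 23 *and*
  CDR-Memory = 0;
- **uncertain** otherwise.

The ADAS cut points 12/23 equal mean ∓ one sample SD of the ADAS recall
over a reference cohort (`triage.compute_adas_thresholds` re-derives them);
the inequalities are applied exactly as written, so boundary scores fall to
uncertain, and CDR 0.5 can never be certain. Roughly 73% of samples in a
memory-clinic cohort are uncertain under this rule.

The package trains a compact 3-D convolutional classifier on the FDG-PET
volumes of the *certain* cases (impaired = 1, healthy = 0) and applies it
to the uncertain cases, then validates those diagnoses by (a) longitudinal
memory decline, (b) voxel/ROI group metabolism statistics, and (c)
mental-state (GDS) item statistics.

## Synthetic cohort and phantoms

No clinical data ship with the package; `synthetic` generates cohorts with
the statistical structure the analysis assumes. Defaults are the study
conditions:

- group proportions (312, 333, 1741)/2386;
- per-group score and demographic means/SDs from the published demographic
  table (e.g. MMSE-Recall 0.19 (0.39) / 2.87 (0.33) / 2.02 (1.09));
- CDR-Memory monthly slopes drawn uniformly from the published 95% CI
  ranges: impaired 0.0046–0.0076, healthy 0.0011–0.0020 per month;
- GDS-energy "yes" proportions 0.8027 / 0.7644 / 0.6955.

Scores are discrete, so generation is draw-from-normal → round/clip →
resample (≤ 1000 draws) until the triage rule reproduces the intended
certainty label. The table moments are therefore *targets*: the rejection
step truncates the score normals (for example the certain-impaired ADAS
mean shifts by about −0.5 because draws ≥ 12 are rejected). Uncertain
samples receive a latent state via u ~ Uniform(0,1), impaired iff
u > 0.5. MMSE/ADAS trajectories decline proportionally to the drawn CDR
slope (3 and 20 score units per unit CDR slope — chosen so a typical
impaired trajectory loses ~1.7 MMSE words and ~12 ADAS words over 96
months); visit noise SDs (0.3 / 1.5 / 0.15) are inflated ×1.5 for
non-energetic subjects, reproducing the observed instability of repeated
testing in non-energetic subjects.

Phantom volumes live on a geometric atlas: 13 ROI spheres (radius 0.055 of
the grid edge) inside an ellipsoidal "cerebrum", with the pons below it,
outside the brain mask. Voxel values follow

    v = baseline · (1 − δ_AD · severity · [AD ROI])
                 · (1 − δ_dep · [non-energetic] · [depression ROI]) + ε

with severity 1 for certain-impaired, 0 for healthy, and the latent draw
u ∈ (0.5, 1) for impaired uncertain samples (their impairment is mild and
*varied*; samples built without a draw fall back to a fixed mild fraction,
default 0.5); ε ~ N(0, 0.05), baseline 1.3, pons 1.0, δ_AD = 0.15,
δ_dep = 0.08. The AD pattern covers precuneus, inferior temporal,
posterior/middle cingulate, hippocampus, parahippocampus, angular and
frontal ROIs; the depression pattern covers medial orbitofrontal, anterior
cingulate, insula, hippocampus and parahippocampus (the overlap is
deliberate — depression-related hypometabolism partially mimics the AD
pattern). δ_dep = 0.08 was chosen once as roughly half the AD effect,
matching the qualitative finding that the depression pattern is detectable
but weaker. The generator does **not** emulate anatomy, scanner/site
effects, attenuation or reconstruction; passing tests show the *pipeline*
recovers planted effects of realistic magnitude, not that it would perform
identically on clinical data.

## Preprocessing

Volumes are assumed template-aligned (spatial normalisation is out of
scope). `petprep` implements pons-referenced SUVr (output pons mean exactly
1, hence idempotent and scale-invariant), separable Gaussian smoothing with
σ = FWHM/(2√(2 ln 2))/voxel_mm and reflect boundaries (default FWHM 8 mm;
smoothing precedes masking), and brain-mask vectorisation in a fixed
ascending (z, y, x) scan order with an exact inverse.

## Classifier

Architecture (per the printed design): n_blocks × [3×3×3 conv, stride 1,
same padding → batch norm → ReLU] → 2×2×2 max pool, filters doubling
16 → 128; then a 1×1×1 convolution (64 channels) → ReLU → flatten → one
sigmoid unit. The 1×1×1 head replaces stacked dense layers and keeps the
closed-form parameter count (asserted against the model handle) in the
10⁵–10⁶ range at 96³ input. Training: Adam, lr 0.001, batch 4, binary
cross-entropy, early stopping on the *training* loss (no improvement
≥ 0.01 for 10 consecutive epochs); a validation split may be monitored but
never drives stopping. All randomness derives from one seed.

The engine is written directly on numpy: convolutions are im2col + BLAS
matrix products with the column tensor laid out (N, C·27, P); the input
gradient is computed as a transposed-kernel convolution of the output
gradient, which keeps every product fat enough for BLAS; max-pool
gradients use an equality mask (exact ties occur only at ReLU zeros, whose
gradient the upstream ReLU mask removes). The backward pass is verified
against float64 finite differences.

**Input normalisation.** Before entering the network each volume is
z-scored (which exactly cancels the multiplicative jitter the pons
reference leaves behind), then centred on the *training-set mean volume*
and rescaled by the residual SD — classical mean-image subtraction, stored
with the model like batch-norm statistics. This step matters: volumes of
one template share almost all of their structure, and without removing it
the between-sample signal is orders of magnitude below the shared
component, leaving the per-batch gradient dominated by common-mode noise
(empirically, training never left chance level while a linear model on raw
voxels was perfectly accurate).

Decision rule: impaired iff p ≥ 0.5 (the ≥ convention at the sigmoid
midpoint). Baseline comparators (3-layer MLP, C-/Nu-SVM with linear/RBF
kernels, linear and logistic regression) are fitted on masked-voxel
vectors via scikit-learn.

## Evaluation

Five-fold cross-validation with 60/20/20 splits: subject-level folds
(repeated scans of one subject never straddle the train/test boundary);
rotation i uses fold i as test and fold i+1 (mod 5) as validation.
Metrics (accuracy, precision, sensitivity = recall of the impaired class,
specificity, F1, all in percent) report undefined ratios as absent rather
than zero; AUC is the pairwise concordance probability. Flatten-layer
features can be embedded in 2-D by PCA or seeded t-SNE.

## Validation statistics

- **Longitudinal**: visits binned to the nearest multiple of 6 months in
  6–96 (ties to the lower bin — the binning convention is this package's
  choice); Welch t-tests per bin, Bonferroni-corrected across the evaluated
  bins of each score (Welch everywhere because equal variances are not
  assumed); OLS trends with t-based 95% CIs; within-subject SD of repeated
  scores compared between energetic and non-energetic subjects.
- **Voxelwise/ROI**: per-voxel least-squares GLM of intensity on
  [intercept, group, age, sex, education, ApoE4] (rank-deficient designs
  are rejected naming the collinear columns); with no covariates the t-map
  equals the pooled two-sample t exactly. FWE = Bonferroni α/V (not
  random-field theory — exact and conservative without smoothness
  estimation); FDR = Benjamini–Hochberg; cluster filter keeps components
  with extent strictly > 5 under 18-connectivity (the neighbourhood
  convention of standard neuroimaging packages).
- **Mental state**: per-item 2×2 chi-squared without continuity correction
  (large-sample convention), family-wise threshold 0.05/16 ≈ 0.0031;
  GDS total by Welch t and by a balanced two-way ANOVA
  (certainty × impairment, closed-form sums of squares) on random balanced
  subsamples — each repeat draws every cell down to the recomputed smallest
  cell size — reporting mean p over repeats. Zero within-cell variance
  yields absent (NaN) p-values rather than a fabricated F.

## Problem sizes and numerical choices

End-to-end runs use 32³ phantom grids, 100 + 100 certain and 300 uncertain
samples, five folds and up to three training seeds, with max_epochs 40
(training converges within a handful of epochs at the default effect
sizes; early stopping ends runs around epoch 12). Calibration suites use
200 null simulations (family-wise error of the binned tests; type-I rate
of the subsampled ANOVA with one fresh cohort and one subsample per
repeat, which makes the null p exactly uniform) and 500 replicates for
trend-CI coverage. Degenerate inputs are contracts, not crashes: empty
pons or mask, single-class training sets, sub-16 atlas grids, < 3-visit
trend fits and empty ANOVA cells all raise typed errors.

## Known limitations

- Phantoms are geometric; no anatomy, registration error, site or scanner
  effects, so real-data performance is not implied.
- The GDS-memory item is tied to the latent state, which makes its
  certainty-factor association structurally weak in the generator even
  though its impairment association is strong.
- Impaired uncertain phantoms with latent severity just above 0.5 sit close
  to the trained decision boundary; their occasional misdiagnosis (~15% at
  the default 0.5 threshold) slightly lifts the mean fitted decline of the
  diagnosed-healthy group above the healthy generator range, even though
  the group separation itself is overwhelming (p ~ 1e-40).
- FWE is Bonferroni, stricter than random-field-theory corrections on
  smooth maps.
- FLOP accounting and exact reproduction of the published parameter totals
  are out of scope (the layer multiplicity of the published figure is not
  fully recoverable from text); the closed-form count is asserted against
  the implementation instead.
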