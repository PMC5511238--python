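# Methods

`dlradiomics` implements a deep-learning radiomics (DLR) pipeline for
predicting a binary molecular phenotype (IDH1-like mutation status) from
multi-modal brain MR volumes. The pipeline has four stages: patch-based CNN
tumor segmentation, multi-scale pooling of deep filter responses over tumor
ROIs, Fisher-vector encoding against a shared Gaussian mixture, and
filtered/ranked linear-SVM classification. Because no suitable labeled
cohort is publicly deposited, the package ships a phantom generator that
creates cohorts with a controllable phenotype signal, and every experiment
in the test suite and acceptance script runs on those phantoms.

## Phantom model

A phantom is a `(channel, z, y, x)` volume containing one axis-aligned
ellipsoidal "tumor" on a flat background:

* voxel intensity = `background_level` (+ `tumor_contrast` inside the mask)
  + intratumoral texture + white Gaussian noise (`noise_sd`, everywhere);
* the intratumoral texture is white Gaussian noise convolved with an
  isotropic Gaussian kernel of width `texture_corr_length[class]`, rescaled
  to unit variance and multiplied by `texture_sd`. Class 0 uses a longer
  correlation length (smoother) than class 1, mirroring the observation
  that wild-type tumors look internally more complicated than mutants on
  FLAIR. This single scalar knob is the phenotype signal;
* the mask is exactly the ellipsoid; the in-plane semi-axis is drawn
  uniformly from `tumor_radius_range` and the center placed so the tumor
  keeps at least one patch half-width (16 voxels) from the in-plane border,
  so every tumor voxel is a legal patch center.

Defaults: `volume_shape=(8, 64, 64)` (eight axial slices), 2 channels,
radius 8–12 voxels, contrast 4 over background 1, texture SD 1,
noise SD 0.3, correlation lengths (3.0, 1.0) voxels. These were chosen once
as a high-contrast, clearly separated operating point: the tumor is obvious
(contrast-to-noise ≈ 13) and the texture classes are far apart. What the
phantoms deliberately lack: brain anatomy, bias fields, registration error,
skull, multi-compartment tumors, class overlap in texture, inter-scanner
variation. A passing suite therefore demonstrates that the machinery is
correct and can recover a texture-coded phenotype, not that the method
reaches any particular accuracy on clinical data.

`generate_cohort` alternates labels, assigns unique case ids, and sets
`diagnosis_time` to the case index so the chronological train/test split is
deterministic. Per-case seeds are spawned from one base seed
(`numpy.random.SeedSequence`), making whole cohorts bit-reproducible.

## Patch sampling and normalization

Training patches are 33×33 axial windows labeled by the class of their
center voxel. Sampling is deliberately unbalanced — by default 40% of
patches have tumor centers — because tumor occupies a small fraction of the
volume. Within each class, centers are drawn uniformly without replacement
from all voxels whose full patch support fits in the slice, stratified
across cases proportionally to eligible-voxel counts (largest-remainder
rounding). Each patch is standardized per channel to zero mean and unit
variance; constant patches are dropped with a warning. Normalization
statistics are per patch, not per volume — the narrower reading of
"the patches in one channel were normalized" — and this choice is flagged
here because the alternative (volume-level statistics) is also defensible.

## Network

The classifier is a stack of 3×3 valid convolutions with ReLU, 2×2
max-pooling after every second convolution while the spatial extent stays
≥ 8, then two fully connected layers with ReLU and dropout (rate 0.5), and
a 2-way softmax. The default configuration has 6 convolutional layers with
widths (64, 64, 128, 128, 128, 128) — the last width is F = 128, the deep
filters used by the radiomics stage — and 4096-neuron fc layers; a shallow
variant (1 conv, fc 256) is the ablation baseline. The per-layer widths and
pooling placement are package defaults, exposed in `NetworkSpec`, since
only the depth, the last width and the fc size are fixed by the design;
the builder verifies the conv stack's receptive field does not exceed the
33-voxel patch.

The implementation is plain NumPy (im2col + BLAS matmuls, float32 weights).
Fully connected layers are stored as convolutions whose kernel covers the
whole remaining spatial extent, so the same weights run in two modes:
patch mode for training, and fully convolutional mode for test-time dense
inference on whole padded slices. Gradients are exact (verified against
numerical differentiation); training is minibatch SGD with momentum
(defaults: learning rate 0.005, momentum 0.9, batch 128, 30 epochs; the
optimizer is part of the design, its hyperparameters are package choices,
logged and configurable). Training is bit-deterministic for a fixed seed.

Dense inference standardizes each slice per channel, zero-pads by 16, and
produces a logit map subsampled by 2^(number of pools); the class-1
probability map is upsampled to voxel resolution with bicubic interpolation
and clipped to [0, 1]. Post-processing keeps the largest 4-connected
component per axial slice of `{p >= 0.5}`, then smooths the binary stack
with a 3×3×3 box kernel and re-thresholds at 0.5 (an isolated voxel
smooths to 1/27 and disappears). The 0.5 thresholds and 4-connectivity are
package choices. Segmentation is scored by DSC, PPV and sensitivity; empty
denominators return 0 with a warning.

## Deep features and Fisher encoding

For each axial slice intersecting the tumor mask, the mask bounding box is
cropped, standardized per channel over in-mask pixels, out-of-mask pixels
are zeroed (isolating the tumor signal), and the crop is resampled at 10
ratios spanning 0.5–2. The ratios are geometrically spaced with both
endpoints included — multiplicative spacing is the natural choice for scale
— which means ratio 1.0 is not among the 10 (`scale_ratios` is
configurable if exact-native sampling is wanted). Either the ground-truth
mask or the predicted mask can drive the ROI (flag `roi_mask`), supporting
a fully automatic mode.

Each scaled ROI runs through the convolutional stack only; the post-ReLU
feature map of each of the F last-layer filters is flattened row-major and
concatenated across ROIs (slice-major, then scale), giving per case an
(F, T) response set with a common length T. Permuting ROI order permutes
responses but cannot change the encoding (the Fisher vector is a set
statistic), and post-ReLU responses are nonnegative.

A single K = 64 component univariate Gaussian mixture is fitted by EM
(scikit-learn, k-means++ initialization, tolerance 1e-6, ≤ 500 iterations,
variance floor 1e-6 × pool variance) on responses pooled over all filters
from an encoder-fit subset — by default the first 30 cases, fitted once
per cohort; a per-fold refit is available but not default, since one shared
dictionary is the stated design. The pool is subsampled to a bounded size
(default 2×10^5) before EM. One global mixture across filters keeps the
dictionary shared, exactly one "visual vocabulary" per cohort.

Encoding follows the standard improved-Fisher-vector form. For filter f
with responses x_1..x_T and responsibilities γ_k(x):

    G_{f,k} = 1/(T√w_k)    Σ_t γ_k(x_t) (x_t − μ_k)/σ_k
    H_{f,k} = 1/(T√(2w_k)) Σ_t γ_k(x_t) [((x_t − μ_k)/σ_k)² − 1]

laid out as `index(f, k, order) = f·2K + order·K + k` (layout version
`fko-v1`), length 2·K·F = 16,384 at defaults. "Improved" means element-wise
signed square root followed by global L2 normalization; both are flags, so
the raw gradient vector is available. Responsibilities are computed in
log-space. The encoder is verified against a literal double-loop oracle and
against the consistency property that responses drawn from the fitted
mixture give vanishing raw statistics.

## Selection and classification

Two selection steps run inside every evaluation fold, in this order:

1. unpaired two-sample Student's t-test (pooled variance) per feature,
   keeping p < 0.05. No multiple-testing correction is applied — the plain
   per-feature significance threshold is a deliberate design choice even
   though ~5% of null features survive by chance. The two classes are
   independent patient groups, so the unpaired (not paired) test is the
   correct form. If nothing survives, the fold falls back to F-score
   ranking over all features rather than fitting on an empty set;
2. F-score ranking, F(i) = [(x̄⁺−x̄)² + (x̄⁻−x̄)²] / [s⁺²+s⁻²], keeping the
   top m (default m = 100; m is not fixed by the design and is swept in
   experiments). Ties break toward the lower index.

Features are z-scored with training-fold statistics before the SVM — a
linear SVM at C = 1 is scale-sensitive, and descriptor entries span orders
of magnitude. The classifier is a linear-kernel SVM with box constraint
C = 1 (scikit-learn SVC). Evaluation is leave-one-out cross-validation
(selection redone in every fold; fold isolation is tested bit-exactly) or a
single chronological split on `diagnosis_time`. The metric panel is AUC
(Mann–Whitney rank form, half-credit for ties, verified against exhaustive
pairwise concordance), ACC, SENS, SPEC, PPV, NPV and MCC at the score-0
threshold; undefined ratios return 0 with a warning.

## Experiment problem sizes

The packaged experiments (`dlradiomics.experiments`) run at reduced sizes
chosen so a full run takes minutes on one CPU: a 2-conv network with widths
(8, 16) and fc 64; 8 training phantoms with 5,000 patches and 10 epochs for
the segmentation benchmark (held-out DSC ≈ 0.9 at the defaults); 40-case
cohorts, K = 8 and m = 50 for the LOOCV phenotype benchmark. The
chance-level (null) benchmark — identical texture statistics in both
classes — averages the LOOCV AUC over three independent cohorts at
consecutive seeds: a single leave-one-out AUC under in-fold selection at
n = 40 has a null standard deviation near 0.2 and a mild pessimistic bias
(the LOOCV anti-learning effect: each fold's training set is slightly
class-imbalanced against the held-out case, and selection overfits the
remaining cases), so one draw cannot establish chance-level behavior;
the three-cohort mean can. The reference
operating point (6 conv / fc 4096 / K = 64 / 16,384-dim descriptors) is
exercised end-to-end for dimensional correctness with an untrained
128-filter network. Numbers obtained at these sizes characterize the
implementation on phantoms, not clinical performance.

## Numerical and degenerate-input conventions

* constant patch channels: rejected (`DegeneratePatchError`), sampled
  patches dropped with a warning;
* constant slices at inference: standardized to all-zeros instead of NaN;
* features with zero pooled variance: excluded from the t-test with a
  warning; zero-denominator F-scores score +inf (separated) or 0;
* empty predicted or truth masks: overlap ratios return 0 with a warning;
* GMM fits require ≥ 10·K distinct pooled values; variances are floored;
* all randomness flows from explicit integer seeds; cohort seeds are
  spawned, never reused across cases.

## Known limitations

* Phantom texture is stationary Gaussian; real tumors have structured
  heterogeneity (necrosis, cysts, infiltration) that filters may exploit
  differently.
* The NumPy network is CPU-bound and meant for small studies; the
  architecture family is faithful but per-layer widths beyond the defaults
  were not tuned.
* The encoder-fit subset reuses cohort cases (fit once per cohort by
  default); under LOOCV this means held-out cases can contribute unlabeled
  responses to the dictionary. The label-free nature of the GMM makes this
  mild, and a per-fold refit hook exists for strict isolation.
* The chronological split assumes `diagnosis_time` is informative only as
  an ordering; no drift modeling is attempted.
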