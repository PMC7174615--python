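# Methods

This note documents the models, procedures and design choices behind
`headgrade`, in the order the pipeline runs them.

## Problem setting

The package monitors broccoli heads ("flower balls") in nadir RGB images of
field beds. Three quantities are extracted per image: the set of head
pixels (semantic segmentation), an estimate of fresh weight from the
segmented pixel area, and an ordinal freshness grade from the proportion of
yellowing flower buds. Because top-down pixel area is proportional to
ground-plane area in an orthophoto, pixel counts carry physical meaning.

## Synthetic scenes

Field acquisitions of this kind are not publicly distributable, so the
`synthetic` module renders simplified scenes with pixel-exact ground truth.
A scene consists of:

* a soil background: a brown base color modulated by low-frequency
  luminance noise (feature size ~10 px, amplitude 14 intensity levels);
* one or more elliptical heads (axis ratio 0.75–1, random orientation)
  placed without overlap by bounded rejection sampling; head texture is a
  luminance modulation at the bud-granule scale (default 4 px);
* occluding leaf lobes: darker-green ellipses overdrawing up to
  `leaf_occlusion_fraction` (default 10%) of each head's pixels, which are
  removed from the head mask — emulating the main error source of
  area-based yield estimation;
* yellow bud patches grown by seeded region growing inside the visible
  head until the target pixel count is reached exactly, so the recorded
  yellow fraction is exact to within one pixel;
* fresh-weight ground truth `w = k·area + N(0, sd)` truncated at zero,
  with `k = 0.002` g/px and `sd = 2` g by default.

Class textures modulate luminance only, with a small (sd 1) independent
per-channel jitter on top. This matters for grading: the blue-deficit
discriminant (below) cancels pure luminance changes, so a fully green head
produces a near-constant discriminant channel, exactly the degenerate case
the grading guard is designed for. Real heads carry chromatic texture too;
the generator's separation between green and yellow is therefore cleaner
than reality, and passing grading tests demonstrate correctness of the
thresholding machinery, not field-level accuracy.

Default scene geometry (480×360, one head of radius 50–95 px) emulates a
camera-above-plant crop; the test suite uses 96×96 scenes with radii 22–38
so that training fits desk-scale budgets. Scenes are bit-reproducible from
`(params, seed)`.

Robustness perturbations: additive Gaussian noise (sd = level·255),
salt-and-pepper (each pixel forced to 0/255 with probability level/2 each),
and mean-centered Rayleigh noise (scale = level·255, centered so level→0 is
the identity). Illumination changes are multiplicative brightness factors;
a camera's lux-to-intensity response is device-specific and is not modeled.

## Preprocessing

`robert_edges` computes the Roberts-cross gradient magnitude
`sqrt(d1² + d2²)` with `d1 = I[r,c] − I[r+1,c+1]`, `d2 = I[r,c+1] −
I[r+1,c]`, edge-replicated to input size; it is kept as a diagnostic layer.
`median_filter3` applies a 3×3 median per channel with mirror boundary
handling. The denoising step filters the whole image and returns the edge
map alongside; no edge-gated filtering is attempted, as the gating rule is
underdetermined. Resizing is bilinear for images and nearest-neighbor for
masks (which keeps masks binary).

## Augmentation

Each labeled original is resized to a working resolution (1440×1080 by
default), randomly cropped 3 times (480×360), each crop kept at rotations
0/90/180/270° — the unrotated crop counts toward the factor, which is how
3×4 = 12 outputs per original arise — and every output receives a fancy-PCA
color shift. The FPCA covariance is computed on the [0, 1] scale and the
perturbation is `sum_i p_i·(alpha_i·lambda_i)` with one `alpha_i ~ N(0,
sigma)` draw per image (default sigma 0.1); the same shift applies to every
pixel, so object boundaries are unaffected.

Splitting groups records by source image so crops and rotations of one
photograph never straddle the train/val/test boundary; groups are shuffled
and assigned greedily to the split with the largest remaining deficit
against the 6:1:1 targets, which reaches the exact counts whenever group
sizes allow.

## Segmentation network

The encoder has four residual stages (default widths 8/16/32/64 in the
scaled profile, strides 1/2/2/2). Each residual block computes `y =
ReLU(BN(conv3×3(ReLU(BN(conv3×3(x))))) + skip)` where the skip is the
identity, or a strided 1×1 convolution with BN when shape changes. Batch
normalization is part of the ResNet family this architecture derives from
and proved necessary: without it, dice-loss training from random
initialization collapses for some seeds at any workable learning rate.

Each stage output is brought back to input resolution by its own
transposed convolution with kernel = stride (non-overlapping learned
upsampling; the stride-1 branch reduces to a 1×1 convolution). The four
branch outputs, all with `fusion_channels` channels, are combined as a
softmax-weighted sum with four learned scalars — so the fusion weights are
a proper convex combination and an ablation can force one-hot attention on
a single stage. The fused grid passes through dropout, then three 1×1
convolution layers (N1–N3) with the LReLUSoftplus activation after N1 and
N2 and a logistic unit after N3, yielding per-pixel head probabilities.

LReLUSoftplus is `ln(e^x + 1) − ln 2` for x ≥ 0 (zero at the origin,
asymptotically `x − ln 2`) and `a·x` for x < 0 with a = 0.01; the positive
branch is evaluated as `x + log1p(e^−x) − ln 2` to avoid overflow.

Training minimizes dice loss `1 − (2·Σpt + ε)/(Σp + Σt + ε)` with ε = 1.0
(a common stabilizer; it bounds the loss away from the exact Dice
complement by O(ε/N)), averaged per sample over the batch, using SGD with
momentum 0.9 and a stepped learning rate. The reference full-scale profile steps from
0.001 to 0.0005 at iteration 3000 with batch size 64 over 200 epochs and
dropout 0.8. The scaled test profile uses 0.1 → 0.05, batch 8, dropout 0.1,
and global-norm gradient clipping at 5.0: the reduced model's dice
gradients are orders of magnitude smaller per parameter, and these rates
were chosen for that regime. Everything — initialization (He), shuffling,
dropout — derives from one seed, so runs are bit-reproducible.

Inference thresholds the probability grid at 0.5. Images larger than the
model input are processed as overlapping tiles (stride = half the input
size) with probability averaging; smaller images are reflection-padded.

Open architectural points resolved here: stage outputs (post-block) feed
the deconvolution branches; the "three-layer adaptive network" excludes
the logistic output unit; dropout sits before N1 only. ImageNet
pre-training is out of scope — training always starts from random
initialization.

## Evaluation metrics

Accuracy, precision, recall, IoU and F-measure are computed from the
per-pixel confusion counts. Dataset summaries average per image (means over
test images), with a pixel-pooled alternative behind a flag. Ratios with
zero denominators are reported as NaN, excluded from aggregation, and
counted — never silently coerced to 0.

## Yield estimation

Fresh weight is regressed on head pixel area by ordinary least squares,
`w = slope·area + intercept`, with `R² = 1 − SSE/SST` and `NRMSE =
RMSE/mean(w)` on the fitting set (NRMSE is read as a relative error:
actual values in the numerator differences, their mean in the
denominator). The evaluation protocol sorts samples by weight ascending,
numbers them from 1, and fits on odd ranks while validating on even ranks.
Fits are per variety by default, with a pooled mode available. Predictions
are floored at 0 g.

## Grading

Masked head pixels are mapped to the blue-deficit channel
`g = clip((R + G − 2B + 510)/4, 0, 255)`: yellow buds (high R+G, low B)
score near 255, green buds near 150, neutral gray exactly 128. Plain
luminance cannot separate yellow from green reliably, which motivates this
channel.

The binarization threshold maximizes Otsu's between-class variance
`ω₀ω₁(μ₀−μ₁)²` of the split {≤ t, > t}. Two searches are provided and are
required to agree in fitness: exhaustive traversal over all 256 integer
thresholds (ties broken toward the smallest t), and particle swarm
optimization over [0, 255] (20 particles, inertia 0.7, cognitive = social
= 1.5, 50 iterations, fitness evaluated at round(x), seeded). PSO's
correctness is established by fitness equality with the exhaustive search,
not by tuning.

The yellow fraction is the proportion of masked pixels strictly above the
threshold. A guard precedes thresholding: if the discriminant's standard
deviation is below 2.0 gray levels the head is uniformly green and graded
level 0 — Otsu applied to a near-constant channel would otherwise split
measurement noise into a spurious yellow class.

Two standards map fraction to level. The merged 5-level commercial scale:
0 iff f = 0; 1 iff f < 1%; 2 iff f < 5%; 3 iff 5% ≤ f ≤ 10% (10% belongs
to level 3 because level 4 is "> 10%"); 4 above. The original 0/1/3/5/7/9
sensory scale defines its low levels by bud counts; without bud-instance
detection these are approximated by area fractions with cut points 0,
(0, 1%), [1%, 27.5%), [27.5%, 62.5%), [62.5%, 100%), {100%} — the interior
cuts are midpoints between the scale's named anchors (5%, 50%, 75%) and
are the main arbitrariness in this module.

The population yellowness degree is `Y = Σ(M1·N1) / (M2·N2)` with M1 a
head's level, N1 the count at that level, M2 the standard's highest level
(4 merged, 9 original) and N2 the number of heads; Y ∈ [0, 1]. Populations
graded under different standards cannot be combined — this is rejected.

## Problem sizes used by the test suite

The suite trains the scaled profile (widths 8/16/32/64, 96×96 inputs,
48 training scenes, 10 epochs, batch 8), which reaches IoU ≥ 0.8 on
held-out scenes across seeds; grading is validated on 200 heads at nominal
yellow fractions {0, 0.5%, 3%, 7%, 15%}; yield recovery uses 20 datasets
of 50 scenes with weight noise at 5% of the mean weight; robustness is a
monotonicity check of mean IoU over salt-and-pepper levels
{0, 0.02, 0.05, 0.1} on the fixed trained model.

## Known limitations

* The generator's color separation between classes is cleaner than field
  imagery; no specular highlights, shadows, wilting gradients or
  insect damage are modeled, and heads are strict ellipses.
* No photometric calibration: illumination robustness is exercised through
  multiplicative factors, not physical lux.
* The original sensory standard's bud-count levels are approximated by
  area fractions.
* Training is CPU NumPy; the full-scale profile (widths 64–512, 200
  epochs) is provided but is not exercised by the tests.
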