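# headgrade

Segmentation, yield estimation and freshness grading of broccoli heads
from nadir field RGB images.

Broccoli heads are the crop's harvested organ; monitoring them
non-destructively means answering three questions from a top-down
photograph: *which pixels are head* (semantic segmentation), *how much
does the head weigh* (pixel area is proportional to ground-plane area in
an orthophoto, and fresh weight is close to linear in area), and *how
fresh is it* (the proportion of yellowing flower buds drives commercial
grade). `headgrade` implements the full pipeline for researchers in plant
phenotyping and postharvest quality:

* **Improved-ResNet segmentation** — a four-stage residual encoder whose
  stage outputs are each deconvolved back to input resolution, fused with
  learned softmax weights, and classified per pixel by a three-layer
  1×1-conv head using the LReLUSoftplus activation
  (`f(x) = ln(eˣ+1) − ln 2` for `x ≥ 0`, `0.01·x` below), trained with
  dice loss `1 − (2Σpt + ε)/(Σp + Σt + ε)` and momentum SGD. Implemented
  in NumPy with explicit backpropagation; no GPU required.
* **Yield regression** — `weight = slope·area + intercept` by least
  squares, scored with `R² = 1 − SSE/SST` and `NRMSE = RMSE / mean(w)`,
  with the sort-by-weight odd/even modeling-validation protocol.
* **PSO-Otsu grading** — masked head pixels map to a blue-deficit channel
  `g = (R + G − 2B + 510)/4`; the binarization threshold maximizes Otsu's
  between-class variance `ω₀ω₁(μ₀−μ₁)²`, found both by exhaustive
  traversal and by particle swarm optimization (the two must agree); the
  yellow-area fraction maps to an ordinal level under a 5-level merged
  standard (0, <1%, <5%, 5–10%, >10%) or the 0/1/3/5/7/9 sensory scale,
  and a population summarizes as the yellowness degree
  `Y = ΣM₁N₁ / (M₂N₂)`.
* **Supporting stages** — Labelme-polygon rasterization, Roberts-edge +
  3×3-median preprocessing, 12× augmentation (3 random 480×360 crops ×
  4 right-angle rotations, fancy-PCA color jitter), leakage-safe 6:1:1
  splitting, the five confusion-count metrics (accuracy, precision,
  recall, IoU, F-measure), and a synthetic scene generator with
  pixel-exact ground truth for masks, yellow fractions and weights.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Train the scaled profile on 48 synthetic scenes (96×96, one head each),
then segment, weigh and grade 12 held-out scenes generated with a 7%
yellow-bud fraction:

```python
import numpy as np
from headgrade.synthetic import SceneParams, generate_scene
from headgrade import ImprovedResNetSegmenter, AreaWeightRegressor, HeadGrader
from headgrade.grading import PSOConfig

def scenes(n, seed0, yf=0.0):
    return [generate_scene(SceneParams(height=96, width=96, n_heads=1,
            head_radius_range=(22, 38), yellow_fraction=yf,
            weight_noise_sd=0.25, seed=seed0 + i)) for i in range(n)]

train, test = scenes(48, 100), scenes(12, 900, yf=0.07)
X = np.stack([s.image for s in train]); Y = np.stack([s.head_mask for s in train])
seg = ImprovedResNetSegmenter(epochs=10, batch_size=8, seed=0).fit(X, Y)

Xt = np.stack([s.image for s in test]); Yt = np.stack([s.head_mask for s in test])
print("held-out mean IoU:", round(seg.score(Xt, Yt), 3))

pred = seg.predict(Xt)
areas = pred.sum(axis=(1, 2))
weights = np.array([s.true_weight_g for s in test])
reg = AreaWeightRegressor().fit(areas.reshape(-1, 1), weights)
print("slope (g/px):", round(reg.slope_, 5), " R2:", round(reg.r2_, 3),
      " NRMSE:", round(reg.nrmse_, 3))

grader = HeadGrader("merged", PSOConfig(seed=0))
grades = grader.grade_many(Xt, pred)
print("levels:", [g.level for g in grades])
print("yellowness degree Y:", round(grader.population(grades).yellowness_degree, 3))
```

Output (≈90 s on one CPU core):

```
held-out mean IoU: 0.877
slope (g/px): 0.00189  R2: 0.986  NRMSE: 0.043
levels: [3, 2, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3]
yellowness degree Y: 0.729
```

Reading the numbers: the network recovers head masks at IoU 0.877; the
regression on *predicted* areas recovers a slope near the generator's true
0.002 g/px with a 4% relative error (NRMSE); and 11 of 12 heads grade at
level 3 (5–10% yellow), matching the 7% generation target — one head lands
at level 2 because leaf occlusion pushed its measured fraction just below
5%. Y = 0.729 summarizes the population's senescence on the merged scale.

The same stages are available as a CLI — `headgrade synth | preprocess |
augment | split | train | segment | evaluate | yield-fit | yield-predict |
grade | run`, where `headgrade run --config cfg.yaml` executes the whole
pipeline from a YAML config and writes a consolidated JSON report.

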