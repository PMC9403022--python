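# epistroma

Pixel-level **epithelium / stroma segmentation and quantification for H&E
whole-slide histology images**, with downstream correlation of tissue ratios
against gene expression.

Epithelial and stromal tissues are the two dominant components of the tumour
microenvironment, and the tumour–stroma ratio is a prognostic factor in
breast and other solid cancers. This package provides, end to end:

- a **dilated-convolution encoder–decoder segmentation network** (pure
  NumPy, explicit backpropagation) that labels each pixel background /
  epithelium / stroma. The decoder applies four parallel dilated
  convolutions and restores full resolution by sub-pixel channel-to-space
  rearrangement (each low-resolution pixel's r²·c channels become an r×r
  block), summing the branches pixel by pixel;
- an automatic **slide-processing pipeline**: ×16 thumbnail, CIELAB (a*, b*)
  2-means foreground detection with the unstained-corner rule, largest-
  connected-component ROI extraction, 1128×720 tiling with the >80%-
  background discard rule, per-patch prediction and stitching into a global
  tissue mask;
- **quantification**: `ratio_epi = ΣEᵢ/ΣTᵢ`, `ratio_stro = ΣSᵢ/ΣTᵢ` over
  valid patches, plus the ten standard confusion-matrix metrics (TPR, TNR,
  PPV, NPV, FPR, FDR, FNR, ACC, F1, MCC);
- **genomics**: per-gene Spearman correlation against both ratios, top-1%
  gene selection, hypergeometric over-representation analysis with
  Bonferroni (or BH) adjustment, top-10 term reporting;
- a **synthetic-data module** that generates H&E-like slides with exact
  ground-truth masks and planted tissue fractions, labelled training
  patches, expression matrices with planted ratio-correlated genes
  (Gaussian-copula calibrated to a target Spearman ρ), and GMT gene-set
  collections — so the whole stack is testable without external data.

See `docs/methods.md` for the model, the assumptions, and every numerical
choice.

## Worked example

```python
import numpy as np, pandas as pd
from epistroma.synth import (SlideSpec, generate_slide, ExpressionSpec,
                             generate_expression, generate_annotation)
from epistroma.pipeline import Slide, process_slide, PipelineConfig, GroundTruthSegmenter
from epistroma.metrics import count_patch, compute_ratios
from epistroma.genomics import RatioExpressionAnalysis

# a synthetic slide with a planted 60% epithelial fraction
spec = SlideSpec(width_px=640, height_px=480, epi_fraction_target=0.6, seed=7)
img, mask, achieved = generate_slide(spec)

# run the slide pipeline (ground-truth oracle in place of a trained model)
res = process_slide(Slide(img), GroundTruthSegmenter(mask),
                    PipelineConfig(patch_w=160, patch_h=160, seed=0))
r = compute_ratios([count_patch(res.tissue_mask)])
print(f"ratio_epi = {r.ratio_epi:.4f}, ratio_stro = {r.ratio_stro:.4f}")

# expression with 10 genes planted at Spearman 0.8 vs the epithelial ratio
rng = np.random.default_rng(0)
ratios = rng.uniform(0.1, 0.9, 100)
espec = ExpressionSpec(n_genes=2000, n_samples=100, n_planted_epi=10,
                       n_planted_stro=10, target_rho=0.8, seed=1)
expr, planted = generate_expression(ratios, espec)
rt = pd.DataFrame({"ratio_epi": ratios, "ratio_stro": 1 - ratios}, index=expr.columns)
ann = generate_annotation(list(expr.index), 50, (10, 100), planted["epi"], seed=2)
print(RatioExpressionAnalysis(expr, rt, ann).fit(fraction=0.01).summary(top=3))
```

prints

```
ratio_epi = 0.6105, ratio_stro = 0.3895
[epi] 20 selected genes
  T0000        k=10   K=10    ER=  83.44  p=2.800e-21  p_adj=1.400e-19
  T0045        k=4    K=94    ER=   3.55  p=2.234e-02  p_adj=1.000e+00
  T0008        k=3    K=53    ER=   4.72  p=2.327e-02  p_adj=1.000e+00
[stro] 20 selected genes
  T0009        k=2    K=45    ER=   4.45  p=7.197e-02  p_adj=1.000e+00
  ...
```

The recovered `ratio_epi` (0.6105) matches the planted fraction (0.6000)
up to the tile-discard slack; T0000 — the term holding exactly the ten
planted genes — dominates the epithelial enrichment (k = 10 of K = 10,
Bonferroni p ≈ 1.4e-19) while no term survives adjustment on the stromal
side, where nothing was planted with an annotation.

Training the tiny network preset on synthetic patches:

```python
from epistroma.nn import SegmentationModel, TrainConfig, tiny_config, cross_validate
from epistroma.synth import generate_patch_dataset

ds = generate_patch_dataset(200, 96, 96, (0.2, 0.8), seed=20)
cv = cross_validate(ds, tiny_config(0), TrainConfig(folds=5, crop=96, epochs=12, seed=0))
print(cv.summary())        # mean held-out pixel accuracy well above 0.9
```

A `epistroma` console script exposes the same functionality
(`epistroma synth slide|patches|expression|gmt`, `segment`, `train`,
`eval`, `quantify`, `correlate`); every subcommand takes `--seed`.

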