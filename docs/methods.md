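# Methods

## Problem and model

`epistroma` segments hematoxylin-and-eosin (H&E) stained histology slides
into background, epithelium and stroma at pixel level, quantifies the
epithelial and stromal area ratios of a slide, and relates those ratios to
gene expression. The tumour–stroma ratio is a recognised prognostic factor
in solid tumours, and pixel-level tissue maps make it computable at scale.

### Segmentation network

The network is an encoder–decoder built from dilated (atrous) convolutions.
The 1-D reference form of the dilated convolution is

    y[i] = sum_{k=1..K} x[i + r·k] · w[k]

where `r` is the sampling rate between kernel taps; the network layers use
the standard centred, zero-padded 2-D form of this operation so that spatial
dimensions are preserved (the uncentred, unpadded 1-D form is retained in
`nn.ops.dilated_conv_1d` as the tested reference semantics).

- **Encoder**: a strided convolutional stem (one stride-2 stage per entry of
  `stem_channels`, so output stride `r = 2**len(stem_channels)`), followed
  by dilated residual blocks. Each block contains four ResUnits whose
  dilation rates cycle through `(1, 2, 4, 8)` — a multi-scale schedule in
  the spirit of atrous spatial pyramid pooling. The rates are configurable;
  the published architecture family this follows does not fix them.
- **Decoder**: four parallel dilated convolutions (rates `(1, 2, 4, 8)`,
  Xavier-initialised) each emit `r²·C` channels at the encoder resolution,
  where `C = 3` classes. A pure channel-to-space rearrangement
  (`multichannel_upsample`, i.e. sub-pixel / pixel-shuffle upsampling: the
  channel block `(p, q)` of pixel `(i, j)` moves to output pixel
  `(i·r + p, j·r + q)`) restores full resolution, and the four branch
  outputs are summed pixel by pixel. The rearrangement is a bijection of
  tensor entries and is inverted exactly by `multichannel_downsample`.

Two presets exist. `full` mirrors the production-scale design: stem of three
stages (7×7 stride-2 conv then two projected ResUnits; output stride 8),
six dilated blocks of four ResUnits at 128 channels, decoder rates
`(1, 2, 4, 8)`. `tiny` is the desk-scale variant used by the test suite:
two stem stages of 12 and 16 channels (output stride 4), one dilated block
at 16 channels, same decoder structure (~51k parameters; a 96×96 forward
pass takes a few tens of milliseconds on one CPU core). The first stem
stage is kept slightly wider than strictly necessary: narrower stems were
prone to losing the hue contrast between the tissue classes during
training. An optional hook loads externally supplied pre-trained
encoder weights; nothing in the package requires it.

### Training

Loss is mean per-pixel cross-entropy over the three classes. Activations are
leaky rectifiers (negative slope 0.05): with plain ReLU and no batch
normalisation, narrow presets can lose the hue-discriminating features to
dead units and collapse the two tissue classes into one — the leak removes
that failure mode at no cost. Augmentation is
random crop and random horizontal mirror. Both SGD with momentum and Adam
are implemented; **Adam (lr 5e-3, β₁ 0.9, β₂ 0.999) is the default** because
the network carries no batch normalisation and plain SGD needed fragile
learning-rate tuning to converge at desk scale, while Adam converges within
a handful of epochs on the synthetic task. All randomness (initialisation, shuffling,
augmentation) is driven by explicit seeds; training is bit-reproducible.

A practical note on crops: dilated units with rate 8 span 17 pixels, so
training on crops much smaller than the inference size changes the fraction
of padding the large-rate units see and measurably hurts held-out accuracy.
The desk-scale experiments therefore train on full 96×96 patches
(`crop=96`); the default `crop=600` applies to larger imagery.

Cross-validation partitions the dataset by a seeded permutation into k
disjoint folds (default 5), trains a freshly initialised model per fold and
scores held-out patches with the metric suite below.

## Slide-processing pipeline

1. **Thumbnail**: ×16 block-mean downsample (ceil output dims; partial edge
   blocks average only their real pixels).
2. **Chroma clustering**: convert to CIELAB (sRGB, D65), keep only (a*, b*)
   — L* is brightness and irrelevant to stain colour — and split pixels with
   2-means (k-means++ with 10 restarts, caller-supplied seed). The cluster
   containing the upper-left pixel is declared background, on the assumption
   that slide corners are unstained. This rule fails mechanically when
   tissue touches the upper-left corner; the failure is covered by a test
   and inverts the mask bitwise.
3. **ROI**: bounding box of the largest 8-connected foreground component
   (ties broken by first appearance in row-major scan), mapped to full
   resolution by multiplying offsets by the downsample factor and clamping
   to the slide bounds. Coordinates are row-major, 0-based, half-open.
4. **Tiling**: a non-overlapping grid of width 1128 × height 720 patches
   anchored at the ROI top-left. Edge tiles are conceptually padded with
   background to full size; the background fraction of a tile is measured
   against the k-means mask upsampled to full resolution by nearest
   neighbour, over the full patch_w × patch_h area. Tiles with **strictly
   more than** 80% background are discarded (a tile at exactly 80% is
   retained). The alternative of measuring background with the model's own
   predicted class would couple tiling to the model and is not used.
5. **Prediction and stitching**: retained tiles (padded with white at the
   ROI edge) go through the model; predictions are cropped back and placed
   at their tile offsets; discarded tiles remain background. The stitched
   mask has exactly the ROI's shape, and every ROI pixel belongs to exactly
   one tile.

## Quantification

With per-patch counts E_i (epithelium), S_i (stroma) and T_i = E_i + S_i
over the N valid patches:

    ratio_epi = ΣE_i / ΣT_i        ratio_stro = ΣS_i / ΣT_i

T_i is defined as E_i + S_i — the model-predicted tissue — rather than the
k-means foreground count; this makes the two ratios sum to exactly 1
whenever tissue is present, matching how such ratios are conventionally
reported as complementary percentages. Zero tissue is an explicit error,
not a silent 0.

Evaluation uses the ten standard confusion-matrix metrics (TPR, TNR, PPV,
NPV, FPR, FDR, FNR, ACC, F1, MCC), computed at full precision on the unit
scale; the ×100, two-decimal presentation happens only in reporting
helpers. Per-cohort metrics pool pixel counts across images; a
macro-averaged alternative is provided. Zero denominators yield NaN plus a
warning, never a silent zero. `metrics_from_rates` recovers the full set
from (TPR, TNR, PPV) alone by solving the PPV identity for the class
prevalence — used to check the internal consistency of published tables
that print rates but not counts.

## Genomics

Per gene, Spearman correlation (average ranks, then Pearson; scipy) against
ratio_epi and ratio_stro. Genes constant across samples are flagged
undefined rather than dropped silently. Selection takes the top
`ceil(fraction·G)` genes (default fraction 1%) by **signed** descending
correlation per tissue — positively correlated genes — with ties broken by
gene ID; absolute-value ranking is available as an option.

Over-representation uses the hypergeometric upper tail
p = P[X ≥ k], X ~ Hypergeom(N, K, n), computed by scipy in log space.
The reference universe defaults to genes present in both the expression
matrix and the annotation. Only terms with at least `min_term_size` (=5)
genes in the reference are tested; the Bonferroni factor m is the number of
terms actually tested (Benjamini–Hochberg available as an alternative).
Reporting takes the top 10 terms ordered by (p_adj, p, −enrichment ratio,
term ID). Whether top-gene sets should be unioned across tissues before
enrichment is ambiguous in the source method; this package runs per-tissue.

## Synthetic data: what it emulates, and what it does not

`synth` exists so every stage is testable without external slides or
expression data.

- **Slides**: one dominant tissue component (ellipse or rectangle) inside a
  near-white border (≥5% margin; small Gaussian jitter keeps the a*/b*
  clustering non-degenerate). Within tissue, a smoothed Gaussian random
  field is thresholded at the order statistic matching the requested
  epithelial fraction, giving contiguous nest-like epithelial regions and
  an achieved fraction exact up to 1/n_tissue quantisation (well within the
  ±0.02 contract). Epithelium renders as clustered dark-purple nuclei on a
  lighter purple base; stroma as pink with oriented sinusoidal fibre
  stripes and sparse darker nuclei. The classes are separable by local
  colour/texture statistics by design — texture realism is *not* a goal.
  Consequently, passing tests demonstrate the pipeline's mechanics and the
  network's capacity to learn a colour/texture separation; they say nothing
  about accuracy on real H&E slides, stain variation, scanner artefacts or
  nuclei-level morphology.
- **Expression**: planted genes follow `baseline + f(ratio) + ε` with `f`
  the Blom normal scores of the ratio ranks (strictly increasing), so the
  joint copula with the ratio is exactly Gaussian. The noise scale for a
  target Spearman ρ_s uses the bivariate-normal rank-correlation identity
  ρ_s = (6/π)·asin(ρ_p/2): σ = sqrt(1/ρ_p² − 1) with ρ_p = 2·sin(πρ_s/6).
  This is exact for the population value; the sample Spearman at n = 100
  concentrates around the target (verified across ≥20 seeds). `noise_sd`
  multiplies all noise, so `noise_sd → 0` gives perfectly monotone planted
  genes; calibration is exact at the default `noise_sd = 1`. Null genes are
  i.i.d. Gaussian.
- **Annotation**: one term holds exactly the planted genes (plus optional
  random padding); the rest are random subsets, GMT-round-trippable.

## Numerical and design choices

- Coordinates row-major, 0-based, half-open; patch size is width × height.
- Downsampling is block-mean with ceil dims; mask upsampling is nearest
  neighbour.
- 8-connectivity for "largest connected component"; deterministic
  scan-order tie-break.
- Argmax ties in prediction resolve to the lower class index
  (0 = background, 1 = epithelium, 2 = stroma — fixed mapping).
- Degenerate chroma images (all pixels identical) return an all-background
  mask with a warning instead of failing inside k-means.
- Model serialisation is a zip of config JSON plus parameter arrays in
  traversal order; loading rebuilds the architecture from the embedded
  config.
- A single trained model (not a fold ensemble) is the intended inference
  artefact after cross-validation.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run at desk scale by choice:
tiny preset, 200 synthetic 96×96 patches with epithelial fractions uniform
on [0.2, 0.8], 5-fold CV, 12 epochs, Adam 5e-3 (≈7 min on one CPU core);
20 synthetic 512×384 slides for ROI recovery; 5 synthetic 640×480 slides
with 160×160 tiles for ratio recovery; 2000 genes × 100 samples with 10
planted genes at target ρ = 0.8 and 50-term annotations (20 replicates) for
the genomics chain.

## Known limitations

- The NumPy network trains small models only; there is no GPU path, no
  batch normalisation, and no mixed precision.
- Synthetic slides do not model staining variation, scanner artefacts,
  tissue folds, or instance-level nuclei ground truth; results on them
  upper-bound nothing about real-world accuracy.
- The upper-left-corner background rule inherits its documented failure
  mode when tissue touches that corner.
- The copula calibration targets the population Spearman; very small sample
  sizes will show visible bias.
- Vendor slide dialects (SVS/NDPI metadata), stain normalisation and
  overlapping-tile blending are out of scope.
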