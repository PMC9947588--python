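# Methods

This note documents the models and procedures implemented in `ctcdet`, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer should know about.

## Detection model

The detector is a single-shot multibox (SSD) network: a VGG16-style backbone
(13 convolutions in five blocks, 2-2-3-3-3, each 3×3 with ReLU; 2×2
max-pooling between blocks with ceil-mode padding for odd sizes) followed by
two convolutionalized fully-connected layers and four extra downsampling
stages. Six feature maps feed detection heads: for a 300-px input the grids
are (38, 19, 10, 5, 3, 1); for the 150-px desk profile (19, 10, 5, 3, 2, 1).
Each head is a 3×3 convolution emitting, per anchor, scores for
{background, CTC, WBC} and four box offsets.

**Anchors.** Per feature map l with size list `s`, each grid cell gets a
square anchor of side `s_l`, a square anchor of side `sqrt(s_l * s_{l+1})`,
and aspect-ratio variants {2, 1/2} (plus {3, 1/3} on the 6-anchor maps 2–4);
anchors per location are (4, 6, 6, 6, 4, 4), which gives the closed-form
count Σ a_l g_l² = 8732 at 300 px. The default size list
[21, 45, 99, 153, 207, 261, 315] is tuned toward small objects and scales
linearly with input size (so the desk profile sees [10.5, 22.5, ...]).
Offsets use the standard center/log-size encoding with variances
(0.1, 0.1, 0.2, 0.2).

**Attention.** CBAM is attached to the first four of the six feature maps
(the enumeration that treats the detection pyramid, not the backbone
convolutions, as "layers" — the fusion description below uses the same
enumeration, which is why we read it this way). Channel attention passes
spatial max- and average-pooled descriptors through one shared two-layer
MLP (reduction ratio 8) and gates channels with the sigmoid of their sum;
spatial attention convolves the channel-wise max and mean maps (7×7, pad 3)
and gates positions. With all attention parameters zero the module
multiplies its input by exactly 0.25 (two sigmoid-of-zero gates), a closed
form the tests pin.

**Fusion.** For l in {1, 2, 3} the (attended) map l+1 is upsampled with a
stride-2 transpose convolution whose kernel/padding are solved from the grid
pair (e.g. 19→38 uses k=2, p=0; 10→19 uses k=3, p=1), concatenated with map
l, and projected back to map l's channel count by a 1×1 convolution with
ReLU. Fusion inputs are taken from the attended-but-unfused maps (parallel,
not cascaded) — the wiring of which high level feeds which low level is an
interpretation, documented here as the package's choice. Both attention and
fusion are strictly optional; with both off the forward pass is a plain SSD,
which is what the ablation grid exercises.

## Training

Anchors with best IOU ≥ 0.5 toward any ground-truth box are positive for
their best box; each ground truth additionally forces its single
highest-IOU anchor positive; everything else is negative. The loss is

    L_total = L_reg^pos + L_clas^pos + L_clas^neg

with unit weights: smooth-L1 on encoded offsets over positives,
cross-entropy of positives against their class, and cross-entropy against
background of the ⌊1.2 × #positives⌋ hardest negatives (largest background
cross-entropy; minimum one; mined per image). All terms are normalized by
the positive count; with zero positives the loss degrades to a single mined
negative normalized by one, with a logged warning.

Optimization is Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) at initial learning rate
6e-4 with cosine decay to a 1e-6 floor over the full epoch horizon, and L2
weight decay 5e-4 applied to weight matrices (not biases). The freeze phase
excludes every backbone parameter (`blocks.*`, `fc.*`) from updates
entirely — no gradient step, no decay, no moment update — so frozen
parameters are bitwise unchanged; the full schedule is 50 frozen + 50
unfrozen epochs. Early stopping watches validation loss with patience 10 by
default. Data splits are 0.8/0.1/0.1 by seeded permutation with rounded
sizes. The freeze phase is designed for imported pretrained backbones;
training from scratch (as the desk study does) sets `freeze_epochs=0`,
since freezing a randomly initialized backbone would train heads on noise
features.

## Evaluation

A detection is a true positive only when its IOU with an unmatched truth of
the same class strictly exceeds the threshold (an IOU of exactly 0.5 at
threshold 0.5 counts as a false positive); matching is greedy in score
order. Precision = TP/(TP+FP), recall = TP/(TP+FN); the degenerate 0/0
cases are defined as 1.0 so an empty image handled perfectly is not
penalized. AP integrates the PR curve with all-point interpolation
(monotone precision envelope). Evaluation is per-class with CTC as the
headline class plus a macro average; recall is reported both at the
operating score threshold and implicitly as the endpoint of the PR sweep.

## Interpretation

Grad-CAM weights are spatial means of ∂Y/∂A per channel; Y defaults to the
pre-softmax, pre-NMS class logit of the chosen detection's anchor (a
`score_type="prob"` flag switches to the normalized score). The maps
visualized are the attended multi-level maps *before* fusion — the six
per-layer views the method produces — rather than the fused maps the heads
consume: backpropagating to the pre-fusion maps routes gradient into two
adjacent scales for every detection (each map feeds both its own head and
the fusion block below it), whereas post-fusion maps leave each detection a
single gradient-carrying layer whose spatially averaged channel weights can
turn the whole map negative and rectify to nothing. The weighted
channel sum is rectified — negative evidence zeroed — before min–max
normalization; a flag disables rectification for the literal unrectified
form, but the rectified map is the default because negative evidence would
otherwise corrupt the "hot means contributing" reading of the overlay.
Per-layer maps from the first four levels are bilinearly upsampled to input
resolution and fused as a normalized weighted sum with default weights
(4, 3, 2, 1) — low levels weighted higher because they carry localization
detail; the weight vector's scale is irrelevant by construction.

t-SNE embeds spatial-mean-pooled activations of the third backbone block for
single-cell crops resized to 48 px (the detector's own backbone, not a
separately trained classifier), using scikit-learn's implementation
(perplexity-calibrated Gaussian affinities vs Student-t in 2-D; the final KL
divergence is reported). Perplexity defaults to 20 with at least 3×
perplexity items required.

## Synthetic data

The simulator emulates the statistical structure of bright-field spiked
samples on a bright background (level 0.82 of full scale): cells are
rendered as tilted ellipses, exactly tight in their integer bounding boxes
(via a correlated quadratic form), with a radial center-to-rim intensity
profile, multiplicative speckle, and additive Gaussian noise (σ 0.03).
CTCs are darker with a pronounced dark rim and coarser speckle; WBCs are
smaller, lighter and finer-textured. Diameters are drawn from a truncated
normal centered on each class range midpoint (CTC 10–20 μm, WBC 7–12 μm,
sd = range/6): real cell sizes cluster around a typical value, and the
truncation plus central concentration keeps the class size distributions
nearly disjoint, so a size threshold on truth boxes separates the classes
with ≳98% accuracy — the dataset is learnable by construction. Default
scale is 0.62 μm/px (a 20 μm cell ≈ 32 px), default composition 1–3 CTCs
and 40–60 WBCs per 300-px field; per-patch counts for real data are not
published, so these are modeling choices. Placement rejects a cell when box
overlap exceeds 20% of the smaller cell's box area (bounded retries, then a
placement error reporting achieved counts). The `easy` preset (used for the
desk study) is 150-px fields, 1–2 CTCs, 8–15 WBCs, higher contrast, lower
noise, and no overlap.

What the simulator does **not** emulate: optics (point-spread function,
defocus), red-blood-cell debris and staining artifacts, illumination
gradients, cell adherence and clumping beyond mild overlap, and the
long-tailed morphology of real tumor cells. Passing the synthetic study
therefore demonstrates that the pipeline is implemented correctly and can
learn a size/texture-separable two-class detection task end to end — not
that it reaches any particular accuracy on real microscopy data.

## Desk-scale study

`ctcdet.study.run_desk_study` is the package's validation experiment, sized
for minutes on one CPU: quarter-width backbone on 150-px inputs, trained
from scratch on 200 easy synthetic images (30 validation, 40 held-out test)
for up to 30 epochs with early stopping (patience 8), batch size 8, all
seeds derived from one integer. It reports held-out per-class AP over the
full PR sweep, CTC recall both as the sweep endpoint (every scored detection
considered, the convention detection toolkits print next to AP) and at the
0.5 operating threshold, the fraction of explained detections whose
fused Grad-CAM heat averages higher inside the predicted box than outside
(up to 30 detections), and the silhouette coefficient of the t-SNE
embedding of up to 240 truth-box crops. `scripts/acceptance.py` runs exactly
this study and writes the numbers as JSON.

## Numerical choices and limitations

- The network core is a package-authored numpy autodiff engine: float32
  throughout, im2col/col2im convolution lowering onto BLAS GEMMs,
  non-overlapping max pooling with ceil-mode -inf padding, first-argmax
  gradient routing for max operations. Every primitive is checked against
  central finite differences in the tests.
- He-normal initialization for convolution and linear weights, zero biases;
  loss additivity holds to float32 resolution (the tests check relative
  1e-6).
- Checkpoints are `.npz` files with the network configuration embedded as
  JSON; loading reconstructs the architecture and restores weights exactly.
- Determinism: fixed seeds give identical synthetic data, splits, training
  curves and heatmaps on a given platform; bitwise reproducibility across
  BLAS implementations is not guaranteed.
- Batched multi-image inference, GPU execution, and the comparison
  detectors (two-stage and other one-stage families) are out of scope; FPS
  benchmarking is hardware-bound and deliberately not measured.
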