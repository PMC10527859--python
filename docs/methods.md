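# Methods

## Problem and model

Dermoscopic attributes are localized morphological patterns inside a skin
lesion whose presence informs the diagnosis of melanoma and other lesion
types.  Five attributes are modelled (pigment network, negative network,
milia-like cysts, globules, streaks), each by its **own binary
segmentation model**: the image-level prevalence and pixel-level geometry
of the attributes differ so much that a shared multi-class head would be
dominated by the common classes.

Each model is an encoder–decoder network.  The encoder is the canonical
50-layer residual network: a 7×7 stride-2 stem (64 channels), a 3×3
stride-2 max-pool, and four bottleneck stages with repeats (3, 4, 6, 3)
and channel triples (64,64,256), (128,128,512), (256,256,1024),
(512,512,2048).  Down-sampling bottlenecks carry their stride on the first
1×1 convolution (the original placement — the FLOP accounting is sensitive
to this choice), and 1×1 projection shortcuts are instantiated wherever a
block changes shape.  The decoder mirrors a UNet expansive path: five
stages of ×2 nearest-neighbour up-sampling, channel concatenation with the
matching-resolution encoder activation (four skips: the stem ReLU and the
outputs of stages 1–3), then two CONV_BLOCKs (3×3 convolution without bias
→ batch-norm → ReLU).  A 1×1 convolution with bias plus sigmoid yields one
foreground-probability channel at the input resolution.  Inputs must be
divisible by 32; optional zero-padding (`pad_input`) relaxes this.

Decoder filter widths default to (256, 128, 64, 32, 16), halving per
stage.  With the frozen canonical encoder this puts the trainable
(decoder + head) budget at 9,012,945 parameters and the total at
32,520,977 — within 0.2% of the published Dermo-Seg accounting
(32,561,114 total / 9,058,644 trainable), whose exact encoder
modifications are not enumerated anywhere; we therefore assert the
accounting identity and proximity, not equality.

The encoder is frozen by default (transfer-learning setup): its
parameters are excluded from optimisation and its batch-norms always run
in inference mode.  `build_dermoseg(pretrained=...)` accepts an `.npz`
weights file; absent one, weights are He-initialised.  ImageNet encoder
weights are not bundled; the freezing contract is independent of where
the weights came from, and training from a frozen *random* encoder is not
recommended — the desk profile (below) trains its encoder instead.

## Loss

The hybrid loss is the unweighted sum of two overlap losses, both pooled
over all pixels of the batch (batch-global reduction; `per_image` is
available):

* **Focal Tversky**: `(1 − TI)^(1/γ)` with
  `TI = (Σpg + ε)/(Σpg + αΣ(1−p)g + βΣp(1−g) + ε)`.  α = 0.7, β = 0.3 by
  default — the canonical focal-Tversky weighting, putting the heavier
  penalty on false negatives, which is the failure mode of interest for
  sparse foreground.  γ = 4/3 (the value reported to perform best for this
  task; valid range [1, 3], exponent applied as 1/γ).  ε = 1e−6 smooths
  empty-mask ratios; probabilities are never clamped.
* **Soft IoU**: `1 − I/U` with `I = Σxy`, `U = Σ(x + y − xy)`; on binary
  inputs this equals `1 − TP/(TP+FP+FN)` exactly.  When both masks are
  identically zero the loss is 0 (a perfectly predicted absence); the
  gradient, undefined there, raises instead.

For the binary per-attribute models the focal-Tversky class sum collapses
to the single foreground term; multi-class use is possible by summing per
class channel.

Gradients are closed-form.  The soft-IoU gradient is `−1/U` on positive
pixels and `I/U²` elsewhere; the focal-Tversky gradient chains the focal
exponent through the Tversky quotient.  Near a perfect batch the focal
factor `(1−TI)^(1/γ−1)` diverges for γ > 1; ε keeps TI < 1 and the factor
is additionally capped at 1e6 for numerical safety (the cap is orders of
magnitude above anything reached in practice).  Both closed forms are
validated against central finite differences in the test suite.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e−3, batch 8, inputs resized
to 512×512 (images bilinearly, masks nearest-neighbour so they stay
binary), at most 60 epochs.  Early stopping monitors validation loss:
improvement means strictly lower loss, the run stops once `patience = 20`
epochs pass without improvement, and the best-epoch weights are restored.
The learning rate follows the tabulated protocol value (1e−3); a
conflicting prose value (1e−2) exists in the source description and is
not used.

Data preparation per attribute: **balance, then split**.  Balancing keeps
every image with a non-empty mask for the attribute plus an equally sized
seeded subsample of blank-mask images.  The split is 80% train+validation
/ 20% test, with 10% of train+validation held out for early stopping —
the stated 80:20 three-way split is ambiguous, so this reading is the
package's choice and both fractions are configurable.  Splits are
stratified by each image's attribute-positivity pattern and fully
deterministic under a seed.

## Evaluation

Predictions are thresholded at 0.5 (configurable) and scored with integer
confusion counts.  "Mean IoU" for a binary model averages the foreground
and background class IoUs; the foreground-only Jaccard is reported
alongside, since published baselines for this task often quote it alone.
Default aggregation pools confusion counts over the whole evaluation set
before computing IoU (stable under empty masks); a per-image-mean mode
exists, in which an image empty in both truth and prediction scores 1.
ROC points sweep all distinct predicted values (scikit-learn's
`roc_curve` with no intermediate dropping) with trapezoid-rule AUC;
pooled pixels beyond 2×10⁶ are stride-subsampled deterministically.

## Synthetic data

The generator emits lesion-like images and per-attribute masks in the
exact ISIC Task-2 file layout.  It reproduces the two statistics that the
method's design responds to: the image-level attribute prevalences of the
ISIC 2018 Task 2 composition (0.587 / 0.263 / 0.232 / 0.073 / 0.039 for
pigment network / milia / globules / negative network / streaks — the
streaks count 100/2594 implies 3.9%, which is used, over an inconsistent
printed 2.9%), and foreground sparsity (painted area a configurable
0.2–5% of the lesion by default).  Geometry is stylised per attribute:
line lattice (pigment network), scattered discs (globules), radial border
segments (streaks), persistent-random-walk tracks (negative network),
tiny dots (milia).  Structures are painted into the RGB image — dark for
pigmented patterns, bright for hypopigmented ones — so masks are
learnable from pixels.  Attribute draws are independent Bernoulli per
image; a shared-latent-factor (Gaussian copula, ρ = 0.5) option provides
correlated co-occurrence.  Masks are rasterised without anti-aliasing and
are binary by construction; every draw descends from one `SeedSequence`.

What the generator does **not** emulate: real dermoscopic texture and
colour statistics, annotation noise, superpixel-shaped labels, attribute
co-occurrence structure of the real data, and the visual ambiguity that
makes real attributes hard.  Tests passing on synthetic data therefore
demonstrate the correctness and imbalance behaviour of the pipeline, not
clinical-grade accuracy; the published real-data IoU scores (0.53–0.67
per attribute) require the ISIC download and GPU-scale training and are
out of scope here.

"Easy mode" (`SynthConfig.easy_mode`) enlarges structures to 4–9% of the
lesion (≈1–2% of the image) and raises contrast, giving a regime where a
small CPU model can learn in minutes while remaining sparse enough that
per-pixel cross-entropy collapses to the background class — the property
the hybrid loss exists to fix, restated at desk scale.

## Desk profile and problem sizes

`TrainConfig.desk_profile()` is the package's CPU-scale configuration:
96×96 inputs, batch 4, ≤10 epochs, patience 5, a reduced encoder (16-
channel stem, one bottleneck stage of width 8 and one of width 16,
downsample ×8) with matching three-stage decoder (32, 16, 8), encoder
trained rather than frozen.  The desk-scale learning check trains on 200
easy-mode 96×96 globule images (≈160 train+val / 40 test after
balancing and splitting), 8 epochs, 3 seeds, hybrid versus matched
binary-cross-entropy; these sizes are the package's chosen desk-scale
study conditions.  Representative outcome: hybrid reaches held-out
foreground IoU ≈ 0.9 where BCE stays below 0.1.

## Numerical choices

* All loss mathematics in float64; network training in float32 with
  float64 master weights.
* Batch-norm: momentum 0.9, eps 1e−5; frozen encoders run batch-norm on
  running statistics even during training.
* Up-sampling is nearest-neighbour ×2 (the interpolation mode is not
  specified in the source description; nearest keeps the backward pass a
  block sum).
* Convolutions before batch-norm carry no bias.
* FLOP accounting counts one multiply-add per FLOP over convolutions and
  the classifier's fully-connected layer; pooling, batch-norm and
  activations count zero.  The two-significant-figure presentation
  truncates toward zero, matching the published stage table's own figures
  for the 18/34/50-layer configurations (exact counts: 1.814, 3.664,
  3.858 ×10⁹ at 224×224; the printed 101/152-layer figures differ from
  either rounding convention by one final-digit step).
* Parameter counting excludes batch-norm running statistics (they are
  estimated, not learned).

## Known limitations

* No bundled pretrained encoder weights; transfer-learning results
  depend on supplying a weights file.
* The numpy core is single-device and unoptimised beyond im2col/GEMM
  lowering and pointwise fast paths; the full 512×512 protocol is
  functional but intended for correctness checks, not large-scale runs.
* Real-data reproduction of per-attribute IoU scores is out of scope
  (external dataset, GPU-scale compute).
* Boundary-distance metrics (Hausdorff, ASSD) and calibration metrics are
  not implemented.
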